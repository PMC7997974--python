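"""Candidate segmentation, engineered spectral features and active learning.

Cell detection is a two-stage pipeline: a deterministic 3D segmentation
(smooth, local background subtraction, threshold, seeded splitting) proposes
candidate regions, and a small ensemble classifier (fully connected nets with
12 hidden units) decides which candidates belong to the population of
interest.  Engineered features exploit simultaneous multi-channel
acquisition: background-subtracted unit-norm spectra with the pre-norm
magnitude, intensity-weighted center-of-mass dispersion across channels, and
inter-channel correlations.  A spectral-spatial normalized-cut extractor
(NC-ROI) isolates the subregion of a candidate most similar to a reference
spectrum.  Labels are collected by uncertainty sampling: the unlabeled
candidate whose ensemble score is closest to 0.5 is labeled next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import SpectralClustering
from sklearn.metrics import accuracy_score, balanced_accuracy_score

from ._mlp import MLP, fit_mlp

__all__ = [
    "SegParams",
    "CandidateRegion",
    "NcConfig",
    "EnsembleClassifier",
    "segment_candidates",
    "engineer_features",
    "engineer_feature_names",
    "nc_roi",
    "uncertainty_select",
    "make_candidate_pool",
    "simulate_labeling_experiment",
]


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters, all in micrometers (except the threshold)."""

    smoothing_sigma: float = 2.0
    background_radius: float = 15.0
    threshold: float = 0.1
    seed_size: float = 8.0

    def __post_init__(self):
        if min(self.smoothing_sigma, self.background_radius, self.threshold, self.seed_size) <= 0:
            raise ValueError("all segmentation parameters must be positive")


@dataclass
class CandidateRegion:
    """A segmented voxel set with its label state."""

    voxels: np.ndarray  # (n, 3) integer (z, y, x) indices
    label_state: str = "unlabeled"  # unlabeled | positive | negative

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if len(self.voxels) == 0:
            raise ValueError("candidate region must be non-empty")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def segment_candidates(
    volume: np.ndarray,
    params: SegParams | None = None,
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0),
) -> list[CandidateRegion]:
    """Deterministic candidate segmentation of a single reference channel.

    Gaussian smoothing, then a grey-opening local background estimate is
    subtracted, a global threshold binarizes, connected components are found,
    and touching cells are split by a watershed from distance-transform seed
    maxima of the configured seed size.
    """
    params = params or SegParams()
    vol = np.asarray(volume, dtype=float)
    if vol.size == 0 or not np.any(vol):
        return []
    sp = np.asarray(spacing, dtype=float)
    sigma_vox = params.smoothing_sigma / sp
    smoothed = ndimage.gaussian_filter(vol, sigma_vox)
    size_vox = np.maximum((2 * params.background_radius / sp).astype(int) | 1, 3)
    background = ndimage.grey_opening(smoothed, size=tuple(size_vox))
    signal = np.clip(smoothed - background, 0.0, None)
    mask = signal > params.threshold
    if not np.any(mask):
        return []
    dist = ndimage.distance_transform_edt(mask, sampling=sp)
    min_dist_vox = max(int(round(params.seed_size / sp.min())), 1)
    peaks = peak_local_max(dist, min_distance=min_dist_vox, labels=mask, exclude_border=False)
    markers = np.zeros(vol.shape, dtype=int)
    for k, p in enumerate(peaks, start=1):
        markers[tuple(p)] = k
    if markers.max() == 0:
        labels, _ = ndimage.label(mask)
    else:
        labels = watershed(-dist, markers, mask=mask)
    regions = []
    for lab in range(1, labels.max() + 1):
        vox = np.argwhere(labels == lab)
        if len(vox):
            regions.append(CandidateRegion(voxels=vox))
    return regions


def engineer_feature_names(n_channels: int = 6) -> list[str]:
    names = [f"spec_{c}" for c in range(n_channels)]
    names += ["spec_magnitude"]
    names += [f"com_dist_{i}_{j}" for i in range(n_channels) for j in range(i + 1, n_channels)]
    names += [f"com_to_centroid_{c}" for c in range(n_channels)]
    names += [f"corr_{i}_{j}" for i in range(n_channels) for j in range(i + 1, n_channels)]
    names += [f"mean_{c}" for c in range(n_channels)]
    names += [f"sd_{c}" for c in range(n_channels)]
    names += [f"min_{c}" for c in range(n_channels)]
    names += [f"max_{c}" for c in range(n_channels)]
    names += ["volume_um3", "bbox_z", "bbox_y", "bbox_x", "zero_spectrum_flag"]
    return names


def engineer_features(
    region: CandidateRegion,
    volume: np.ndarray,
    backgrounds: np.ndarray,
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0),
) -> np.ndarray:
    """Engineered feature vector for one candidate region.

    ``volume`` is (channels, z, y, x); ``backgrounds`` the per-channel
    background pixel value.  See :func:`engineer_feature_names` for the fixed
    output order.
    """
    vol = np.asarray(volume, dtype=float)
    bg = np.asarray(backgrounds, dtype=float)
    C = vol.shape[0]
    vox = region.voxels
    sp = np.asarray(spacing, dtype=float)
    intens = vol[:, vox[:, 0], vox[:, 1], vox[:, 2]]  # (C, n)

    means = intens.mean(axis=1)
    sds = intens.std(axis=1)
    mins = intens.min(axis=1)
    maxs = intens.max(axis=1)

    spec = means - bg
    mag = float(np.linalg.norm(spec))
    flag = 0.0
    if mag == 0.0:
        unit = np.zeros(C)
        flag = 1.0
    else:
        unit = spec / mag

    pos_um = vox * sp  # (n, 3)
    centroid = pos_um.mean(axis=0)
    coms = np.empty((C, 3))
    w = np.clip(intens - bg[:, None], 0.0, None)
    for c in range(C):
        if w[c].sum() > 0:
            coms[c] = (pos_um * w[c][:, None]).sum(axis=0) / w[c].sum()
        else:
            coms[c] = centroid
    iu = np.triu_indices(C, k=1)
    com_pair = np.linalg.norm(coms[iu[0]] - coms[iu[1]], axis=1)
    com_centroid = np.linalg.norm(coms - centroid, axis=1)

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Degrees of freedom")
        corr = np.corrcoef(intens)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    corr_pair = corr[iu]

    vol_um3 = len(vox) * float(np.prod(sp))
    bbox = (vox.max(axis=0) - vox.min(axis=0) + 1) * sp
    return np.concatenate(
        [unit, [mag], com_pair, com_centroid, corr_pair, means, sds, mins, maxs, [vol_um3], bbox, [flag]]
    )


@dataclass(frozen=True)
class NcConfig:
    """Spectral-spatial normalized-cut parameters."""

    alpha: float = 0.01   # spatial weight, 1/um^2
    beta: float = 4.0     # spectral weight, dimensionless
    n_clusters: int = 2
    literal_formula: bool = False  # keep the similarity-increases-distance form

    def __post_init__(self):
        if self.alpha < 0 or self.n_clusters < 2:
            raise ValueError("require alpha >= 0 and n_clusters >= 2")


def _pairwise_distance(positions_um, unit_spectra, config: NcConfig) -> np.ndarray:
    r = np.asarray(positions_um, dtype=float)
    s = np.asarray(unit_spectra, dtype=float)
    sq = ((r[:, None, :] - r[None, :, :]) ** 2).sum(-1)
    dots = s @ s.T
    if config.literal_formula:
        spectral = dots
    else:
        # similar spectra -> small distance -> large adjacency
        spectral = 1.0 - dots
    return config.alpha * sq + config.beta * spectral


def nc_adjacency(positions_um, unit_spectra, config: NcConfig) -> np.ndarray:
    """Adjacency w_ij = exp(-d_ij) over the spatial+spectral distance."""
    return np.exp(-_pairwise_distance(positions_um, unit_spectra, config))


def nc_roi(
    region: CandidateRegion,
    volume: np.ndarray,
    reference_spectrum: np.ndarray,
    config: NcConfig | None = None,
    backgrounds: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0),
    random_state: int = 0,
) -> np.ndarray:
    """Voxels of the normalized-cut subregion most similar to a reference spectrum.

    The candidate's voxels are clustered by normalized-cut spectral clustering
    on the spectral-spatial adjacency; the cluster whose mean unit spectrum
    has the highest dot product with the reference is returned (ties go to
    the larger cluster).
    """
    config = config or NcConfig()
    vol = np.asarray(volume, dtype=float)
    vox = region.voxels
    if len(vox) < config.n_clusters:
        raise ValueError("region smaller than the number of clusters")
    bg = np.zeros(vol.shape[0]) if backgrounds is None else np.asarray(backgrounds, dtype=float)
    intens = vol[:, vox[:, 0], vox[:, 1], vox[:, 2]].T - bg  # (n, C)
    norms = np.linalg.norm(intens, axis=1, keepdims=True)
    unit = np.where(norms > 0, intens / np.where(norms == 0, 1.0, norms), 0.0)
    pos = vox * np.asarray(spacing, dtype=float)
    W = nc_adjacency(pos, unit, config)
    clusterer = SpectralClustering(
        n_clusters=config.n_clusters, affinity="precomputed", random_state=random_state,
        assign_labels="kmeans",
    )
    labels = clusterer.fit_predict(W)
    ref = np.asarray(reference_spectrum, dtype=float)
    ref = ref / np.linalg.norm(ref)
    best_lab, best_score, best_size = None, -np.inf, -1
    for lab in np.unique(labels):
        m = labels == lab
        mean_spec = unit[m].mean(axis=0)
        nrm = np.linalg.norm(mean_spec)
        score = float(mean_spec @ ref / nrm) if nrm > 0 else -np.inf
        size = int(m.sum())
        if score > best_score + 1e-12 or (abs(score - best_score) <= 1e-12 and size > best_size):
            best_lab, best_score, best_size = lab, score, size
    return vox[labels == best_lab]


class EnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Averaged ensemble of small fully connected classifiers.

    Each member is a single-hidden-layer network (12 hidden units) with a
    sigmoid output trained on the logistic loss; the ensemble score is the
    mean member output, in [0, 1].  Three members are used while labels are
    being collected; the final prediction pass typically averages 100.
    """

    def __init__(
        self,
        n_members: int = 3,
        hidden: int = 12,
        lr: float = 0.01,
        max_epochs: int = 250,
        patience: int = 25,
        seed: int = 0,
    ):
        self.n_members = n_members
        self.hidden = hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least one positive and one negative label")
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.mean_, self.scale_ = mu, sd
        Z = (X - mu) / sd

        from scipy.special import expit

        def loss_grad(out, yb):
            p = expit(out)
            eps = 1e-9
            loss = float(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
            return loss, (p - yb) / len(out)

        self.members_ = []
        for k in range(self.n_members):
            net = MLP([X.shape[1], self.hidden, 1], seed=self.seed + 1000 * k)
            fit_mlp(
                net, Z, y, loss_grad,
                batch_size=len(Z), lr=self.lr, max_epochs=self.max_epochs,
                patience=self.patience, val_fraction=0.0, dropout=0.0,
                seed=self.seed + 1000 * k,
            )
            self.members_.append(net)
        self.classes_ = np.array([0, 1])
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Mean member sigmoid output in [0, 1] (certainty of the positive class)."""
        from scipy.special import expit

        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        outs = [expit(net.forward(Z)) for net in self.members_]
        return np.mean(outs, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        return np.column_stack([1 - s, s])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def uncertainty_select(scores: np.ndarray) -> int:
    """Index of the unlabeled example with score closest to 0.5 (lowest index wins ties)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty pool")
    return int(np.argmin(np.abs(s - 0.5)))


def make_candidate_pool(
    n: int = 4000,
    prevalence: float = 0.005,
    seed: int = 0,
    n_channels: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic labeled candidate pool emulating engineered-feature geometry.

    Positives carry the reference fluorophore's spectral signature; negatives
    are a mixture of broad-spectrum autofluorescence, a spectrally distinct
    second fluorophore, and bleed-through composites that sit near the
    decision boundary.  Features: unit spectrum, log magnitude, and three
    morphology dimensions.  Returns ``(features, labels)``.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(int(round(n * prevalence)), 1)
    n_neg = n - n_pos
    ref = np.array([0.10, 0.15, 1.00, 0.25, 0.10, 0.05])[:n_channels]
    auto = np.array([0.8, 1.0, 0.9, 1.0, 0.8, 0.6])[:n_channels]
    other = np.array([0.05, 0.10, 0.20, 0.30, 1.00, 0.40])[:n_channels]

    def draw(base, count, noise):
        s = base[None, :] + rng.normal(0, noise, size=(count, n_channels))
        s = np.clip(s, 0.0, None) + 1e-6
        return s / np.linalg.norm(s, axis=1, keepdims=True)

    pos_spec = draw(ref, n_pos, 0.12)
    n_auto = int(0.7 * n_neg)
    n_other = int(0.2 * n_neg)
    n_bleed = n_neg - n_auto - n_other
    mix = rng.uniform(0.35, 0.65, size=(n_bleed, 1))
    bleed_base = mix * ref[None, :] + (1 - mix) * other[None, :]
    bleed = np.clip(bleed_base + rng.normal(0, 0.10, size=(n_bleed, n_channels)), 0, None) + 1e-6
    bleed = bleed / np.linalg.norm(bleed, axis=1, keepdims=True)
    neg_spec = np.vstack([draw(auto, n_auto, 0.15), draw(other, n_other, 0.12), bleed])
    spec = np.vstack([pos_spec, neg_spec])
    logmag = np.concatenate(
        [rng.normal(2.0, 0.4, n_pos), rng.normal(1.6, 0.6, n_neg)]
    )
    morph = rng.normal(0.0, 1.0, size=(n, 3))
    X = np.column_stack([spec, logmag, morph])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(n)
    return X[perm], y[perm]


def simulate_labeling_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    strategy: str = "uncertainty",
    max_labels: int = 120,
    seed: int = 0,
    n_members: int = 3,
) -> pd.DataFrame:
    """Simulated labeling session drawing labels from a ground-truth pool.

    Starts from one randomly chosen positive and one negative, then iterates
    select -> label -> retrain, recording accuracy and balanced accuracy on
    the remaining unlabeled examples after each retraining.  ``strategy`` is
    ``"uncertainty"`` (closest to 0.5) or ``"random"``.
    """
    if strategy not in ("uncertainty", "random"):
        raise ValueError("strategy must be 'uncertainty' or 'random'")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    labeled = [
        int(rng.choice(np.flatnonzero(y == 1))),
        int(rng.choice(np.flatnonzero(y == 0))),
    ]
    unlabeled = [i for i in range(len(y)) if i not in labeled]
    rows = []
    while len(labeled) <= max_labels and unlabeled:
        clf = EnsembleClassifier(n_members=n_members, seed=seed).fit(X[labeled], y[labeled])
        scores = clf.scores(X[unlabeled])
        pred = (scores >= 0.5).astype(int)
        rows.append(
            {
                "n_labels": len(labeled),
                "accuracy": accuracy_score(y[unlabeled], pred),
                "balanced_accuracy": balanced_accuracy_score(y[unlabeled], pred)
                if len(np.unique(y[unlabeled])) > 1
                else accuracy_score(y[unlabeled], pred),
            }
        )
        if len(labeled) == max_labels:
            break
        if strategy == "uncertainty":
            pick = uncertainty_select(scores)
        else:
            pick = int(rng.integers(len(unlabeled)))
        labeled.append(unlabeled.pop(pick))
    return pd.DataFrame(rows)
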