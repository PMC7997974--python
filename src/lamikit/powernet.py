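"""The LAMI learner: EOM calibration, standardization and power prediction.

The predictor is a single-hidden-layer network (default 200 units) mapping a
15-element feature vector (mean candle brightness, XY field position, 12-bin
ray-distance histogram) to an EOM voltage.  Training minimizes squared error
in *power* space: predicted and recorded voltages are both pushed through the
fitted sinusoidal voltage-to-power calibration before the loss, so the loss
is invariant to how the voltage axis is parameterized.  At inference the
brightness element is a user-chosen z-score of the training brightness
distribution (0 targets the training-mean brightness) and the output voltage
is clipped to the calibrated range.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from ._mlp import MLP, fit_mlp
from .surface import ShapeFeatureConfig, SurfaceMap, featurize_points

__all__ = ["EomCalibration", "Standardizer", "PowerRegressor"]


class EomCalibration(BaseEstimator):
    """Sinusoidal EOM voltage-to-power calibration on [0, v_max] volts.

    Model: ``power(V) = a * sin(omega * V + phase) + offset`` with the
    constraint ``power(0) = 0`` (offset = -a*sin(phase)) and a strictly
    increasing branch over the valid voltage range.
    """

    def __init__(self, v_max: float = 1.2):
        self.v_max = v_max

    def fit(self, voltages: np.ndarray, powers: np.ndarray) -> "EomCalibration":
        v = np.asarray(voltages, dtype=float)
        p = np.asarray(powers, dtype=float)
        if len(np.unique(v)) < 4:
            raise ValueError("need measurements at >= 4 distinct voltages")

        def model(v, a, omega, phase):
            return a * (np.sin(omega * v + phase) - np.sin(phase))

        p_span = p.max() - p.min()
        guess = (p_span / 2 if p_span > 0 else 1.0, np.pi / self.v_max, -np.pi / 2 + 1e-9)
        # phase bounded to the rising branch so power cannot dip below 0 V off
        params, _ = curve_fit(
            model, v, p, p0=guess, maxfev=20000,
            bounds=([1e-12, 1e-12, -np.pi / 2], [np.inf, np.inf, np.pi / 2]),
        )
        self.amplitude_, self.omega_, self.phase_ = (float(x) for x in params)
        self.offset_ = -self.amplitude_ * np.sin(self.phase_)
        self.residual_rms_ = float(np.sqrt(np.mean((model(v, *params) - p) ** 2)))
        self._check_monotone()
        self._build_inverse()
        return self

    @classmethod
    def default(cls, v_max: float = 1.2) -> "EomCalibration":
        """Canonical half-wave calibration power(V) = (1 - cos(pi V / v_max)) / 2."""
        cal = cls(v_max=v_max)
        cal.amplitude_ = 0.5
        cal.omega_ = np.pi / v_max
        cal.phase_ = -np.pi / 2
        cal.offset_ = 0.5
        cal.residual_rms_ = 0.0
        cal._check_monotone()
        cal._build_inverse()
        return cal

    def _check_monotone(self):
        v = np.linspace(0.0, self.v_max, 257)
        p = self.amplitude_ * np.sin(self.omega_ * v + self.phase_)
        diffs = np.diff(p)
        # the half-wave branch has zero slope exactly at the rails; only a
        # genuine decrease anywhere on the range is an error
        if np.any(diffs < -1e-9 * max(abs(p).max(), 1e-30)):
            raise ValueError("fitted sinusoid is not strictly increasing on the voltage range")

    def _build_inverse(self):
        self._v_grid = np.linspace(0.0, self.v_max, 4097)
        self._p_grid = self.power(self._v_grid)

    def power(self, voltage) -> np.ndarray:
        v = np.asarray(voltage, dtype=float)
        return self.amplitude_ * np.sin(self.omega_ * v + self.phase_) + self.offset_

    def power_deriv(self, voltage) -> np.ndarray:
        v = np.asarray(voltage, dtype=float)
        return self.amplitude_ * self.omega_ * np.cos(self.omega_ * v + self.phase_)

    def voltage(self, power) -> np.ndarray:
        """Inverse on the monotone branch, clipped to the calibrated range."""
        p = np.clip(np.asarray(power, dtype=float), self._p_grid[0], self._p_grid[-1])
        return np.interp(p, self._p_grid, self._v_grid)

    @property
    def max_power(self) -> float:
        return float(self.power(self.v_max))

    def to_dict(self) -> dict:
        return {
            "v_max": self.v_max,
            "amplitude": self.amplitude_,
            "omega": self.omega_,
            "phase": self.phase_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EomCalibration":
        cal = cls(v_max=d["v_max"])
        cal.amplitude_ = d["amplitude"]
        cal.omega_ = d["omega"]
        cal.phase_ = d["phase"]
        cal.offset_ = -cal.amplitude_ * np.sin(cal.phase_)
        cal.residual_rms_ = 0.0
        cal._check_monotone()
        cal._build_inverse()
        return cal


class Standardizer(BaseEstimator, TransformerMixin):
    """Element-wise (x - mean) / std feature standardization."""

    def fit(self, X: np.ndarray, y=None, names: list[str] | None = None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            labels = [names[i] if names else f"column {i}" for i in zero]
            raise ValueError(f"zero-variance feature column(s): {', '.join(map(str, labels))}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


class PowerRegressor(BaseEstimator, RegressorMixin):
    """Single-hidden-layer voltage predictor trained with a power-space loss.

    Parameters
    ----------
    hidden : hidden units (200)
    dropout : dropout probability during training only (0.5)
    batch_size, lr, max_epochs : Adam optimizer schedule
    patience : early-stopping patience in epochs on the validation loss
    val_fraction : validation split fraction
    calibration : EomCalibration; the default half-wave curve if None
    tag : laser/channel label carried with the model (one predictor per laser)
    """

    def __init__(
        self,
        hidden: int = 200,
        dropout: float = 0.5,
        batch_size: int = 1000,
        lr: float = 3e-3,
        max_epochs: int = 2000,
        patience: int = 10,
        val_fraction: float = 0.1,
        seed: int = 0,
        calibration: EomCalibration | None = None,
        feature_config: ShapeFeatureConfig | None = None,
        tag: str | None = None,
    ):
        self.hidden = hidden
        self.dropout = dropout
        self.batch_size = batch_size
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.calibration = calibration
        self.feature_config = feature_config
        self.tag = tag

    def fit(self, X: np.ndarray, voltages: np.ndarray) -> "PowerRegressor":
        X = np.asarray(X, dtype=float)
        v = np.asarray(voltages, dtype=float)
        if len(X) < 100:
            raise ValueError("need >= 100 training records")
        cal = self.calibration or EomCalibration.default()
        self.calibration_ = cal
        self.scaler_ = Standardizer().fit(X)
        Z = self.scaler_.transform(X)
        net = MLP([X.shape[1], self.hidden, 1], seed=self.seed)
        p_true_all = cal.power(v)
        # the sinusoid is flat at both voltage rails, so gradients vanish for
        # out-of-range outputs: start the output layer small, biased at the
        # mean-power voltage, and clamp the loss path just inside the rails
        net.W[-1] *= 0.01
        net.b[-1][:] = float(cal.voltage(p_true_all.mean()))
        eps_v = 0.01 * cal.v_max

        def loss_grad(out, y_batch):
            # y_batch holds true powers; loss in power space through the sinusoid
            v_eff = np.clip(out, eps_v, cal.v_max - eps_v)
            p_pred = cal.power(v_eff)
            diff = p_pred - y_batch
            loss = float(np.mean(diff**2))
            # straight-through gradient across the clamp
            dout = 2.0 * diff * cal.power_deriv(v_eff) / len(out)
            return loss, dout

        self.history_ = fit_mlp(
            net,
            Z,
            p_true_all,
            loss_grad,
            batch_size=self.batch_size,
            lr=self.lr,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            dropout=self.dropout,
            seed=self.seed,
            lr_decay_steps=3,
        )
        if self.dropout > 0:
            # dropout noise passes through the curved sinusoid in the loss, so
            # the dropout-trained weights are biased for deterministic
            # inference; a short dropout-free fine-tune closes that gap
            self.history_finetune_ = fit_mlp(
                net,
                Z,
                p_true_all,
                loss_grad,
                batch_size=self.batch_size,
                lr=self.lr / 6.0,
                max_epochs=self.max_epochs,
                patience=self.patience,
                val_fraction=self.val_fraction,
                dropout=0.0,
                seed=self.seed + 1,
                lr_decay_steps=2,
            )
        self.net_ = net
        return self

    # -- raw-feature interface -------------------------------------------------
    def predict_voltage(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.atleast_2d(X))
        return self._voltage_from_standardized(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Relative power (through the calibration) for raw feature rows."""
        return self.calibration_.power(self.predict_voltage(X))

    def _voltage_from_standardized(self, Z: np.ndarray) -> np.ndarray:
        out = self.net_.forward(Z)
        return np.clip(out, 0.0, self.calibration_.v_max)

    # -- surface-map interface -------------------------------------------------
    def predict_at(
        self,
        surface: SurfaceMap,
        points: np.ndarray,
        field_xy: np.ndarray,
        target_z: float = 0.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(voltage, relative power) for focal points at a target brightness z-score.

        The brightness feature is supplied directly in standardized units:
        ``target_z = 0`` requests the power that yields the training-mean
        brightness, -1 one standard deviation dimmer, and so on.
        """
        config = self.feature_config or ShapeFeatureConfig()
        p = np.atleast_2d(np.asarray(points, dtype=float))
        feats = featurize_points(surface, p, np.zeros(len(p)), np.atleast_2d(field_xy), config)
        Z = self.scaler_.transform(feats)
        Z[:, 0] = target_z
        volts = self._voltage_from_standardized(Z)
        return volts, self.calibration_.power(volts)

    def predict_grid(
        self,
        surface: SurfaceMap,
        fov_origin: tuple[float, float],
        z: float,
        fov: float = 220.0,
        grid: int = 8,
        target_z: float = 0.0,
    ):
        """8x8 modulation pattern (voltage fractions of full scale) for one FoV."""
        from .trslm import ModulationPattern

        ox, oy = fov_origin
        u = np.linspace(0.0, 1.0, grid)
        gx, gy = np.meshgrid(ox + u * fov, oy + u * fov, indexing="xy")
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(grid * grid, z)])
        h = np.atleast_1d(surface.height(pts[:, 0], pts[:, 1]))
        valid = ~np.isnan(h) & (pts[:, 2] > h)
        if not np.any(valid):
            raise ValueError("entire field of view lies outside the surface hull")
        field = np.column_stack([(gx.ravel() - ox), (gy.ravel() - oy)])
        volts = np.zeros(grid * grid)
        v_valid, _ = self.predict_at(surface, pts[valid], field[valid], target_z)
        volts[valid] = v_valid
        if np.any(~valid):
            # nearest in-hull node value for undefined/above-surface nodes
            bad = np.flatnonzero(~valid)
            good = np.flatnonzero(valid)
            for i in bad:
                j = good[np.argmin((gx.ravel()[good] - gx.ravel()[i]) ** 2 + (gy.ravel()[good] - gy.ravel()[i]) ** 2)]
                volts[i] = volts[j]
        values = (volts / self.calibration_.v_max).reshape(grid, grid)
        return ModulationPattern(values=np.clip(values, 0.0, 1.0))

    # -- serialization ---------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "tag": self.tag,
            "hidden": self.hidden,
            "calibration": self.calibration_.to_dict(),
            "scaler": {"mean": self.scaler_.mean_.tolist(), "scale": self.scaler_.scale_.tolist()},
            "weights": [w.tolist() for w in self.net_.W],
            "biases": [b.tolist() for b in self.net_.b],
            "feature_config": asdict(self.feature_config) if self.feature_config else None,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PowerRegressor":
        d = json.loads(text)
        model = cls(hidden=d["hidden"], tag=d.get("tag"))
        model.calibration_ = EomCalibration.from_dict(d["calibration"])
        model.scaler_ = Standardizer()
        model.scaler_.mean_ = np.asarray(d["scaler"]["mean"])
        model.scaler_.scale_ = np.asarray(d["scaler"]["scale"])
        sizes = [len(d["weights"][0])] + [len(b) for b in d["biases"]]
        model.net_ = MLP(sizes)
        model.net_.W = [np.asarray(w) for w in d["weights"]]
        model.net_.b = [np.asarray(b) for b in d["biases"]]
        if d.get("feature_config"):
            model.feature_config = ShapeFeatureConfig(**d["feature_config"])
        model.history_ = {}
        return model
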