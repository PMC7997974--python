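"""Three-stage registration/stitching and the online Z-drift estimator.

Stage 1 removes breathing-induced per-plane XY jitter inside each Z-stack by
gradient-based MAP estimation: the loss is the sum of pixel-wise squared
differences between consecutive resampled planes, normalized by the total
squared intensity, plus a quadratic penalty ``lambda * (||x||^2 + ||y||^2)``
on the shifts (default lambda 8e-3).  Stage 2 aligns consecutive time points
with integer 3D cross-correlation shifts accumulated over time.  Stage 3
stitches adjacent Z-stacks by maximizing the mean correlation coefficient
over their overlap regions with a trust-region optimizer, three translation
parameters per stack, the first stack pinned.  The drift estimator extracts
a sub-plane Z offset from per-slice cross-correlation maxima through a cubic
spline and tracks the drift rate with an exponential moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline

__all__ = [
    "DriftState",
    "align_slices",
    "align_time",
    "cumulative_time_shifts",
    "stitch_stacks",
    "estimate_z_drift",
    "min_over_channels",
    "average_time",
]


def _shift_plane(plane: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Sample plane at (row + dy, col + dx), bilinear, zero-padded."""
    rows, cols = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]].astype(float)
    return ndimage.map_coordinates(plane, [rows + dy, cols + dx], order=1, mode="constant", cval=0.0)


def _shift_plane_fourier(plane: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Subpixel translation by Fourier phase ramp (energy preserving).

    Unlike bilinear resampling, a Fourier shift does not attenuate high
    spatial frequencies at fractional offsets, so the stage-1 loss cannot be
    lowered by "blurring" a plane instead of aligning it.  Boundaries wrap
    circularly; the border mask excludes the affected pixels.
    """
    f = np.fft.fft2(plane)
    ky = np.fft.fftfreq(plane.shape[0])[:, None]
    kx = np.fft.fftfreq(plane.shape[1])[None, :]
    return np.fft.ifft2(f * np.exp(2j * np.pi * (ky * dy + kx * dx))).real


def align_slices(
    volume: np.ndarray,
    lam: float = 8e-3,
    lr: float = 1.0,
    patience: int = 10,
    max_iter: int = 400,
    exclude_channels: tuple[int, ...] = (),
    border_fraction: float = 0.05,
    min_lr: float = 1.0 / 16.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and remove per-plane XY shifts within one Z-stack.

    Parameters
    ----------
    volume : (z, y, x) or (channels, z, y, x); excluded channels (e.g. SHG)
        do not contribute to the loss but are resampled in the output.
    lam : quadratic shift penalty weight.
    lr : initial Adam learning rate (pixels); halved whenever the loss fails
        to decrease for ``patience`` iterations, until below ``min_lr``.

    Returns
    -------
    shifts : (n_planes, 2) array of (dx, dy) corrections applied to each plane
    corrected : resampled volume with the estimated shifts applied
    """
    vol = np.asarray(volume, dtype=float)
    single = vol.ndim == 3
    if single:
        vol = vol[None]
    chans = [c for c in range(vol.shape[0]) if c not in exclude_channels]
    if not chans:
        raise ValueError("no channels left to drive the alignment")
    data = vol[chans]
    nz = data.shape[1]
    if nz < 2:
        raise ValueError("need at least 2 planes")
    norm = float(np.sum(data**2))
    if norm == 0:
        raise ValueError("all-zero image: loss normalizer vanishes")

    h, w = data.shape[2], data.shape[3]
    by, bx = int(border_fraction * h), int(border_fraction * w)
    mask = np.zeros((h, w))
    mask[by : h - by or None, bx : w - bx or None] = 1.0

    # exact spectral derivatives of every plane, reused each iteration
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    grad_x = np.empty_like(data)
    grad_y = np.empty_like(data)
    for ci in range(data.shape[0]):
        for j in range(nz):
            f = np.fft.fft2(data[ci, j])
            grad_x[ci, j] = np.fft.ifft2(2j * np.pi * kx * f).real
            grad_y[ci, j] = np.fft.ifft2(2j * np.pi * ky * f).real

    shifts = np.zeros((nz, 2))  # (dx, dy)

    def loss_and_grad(s):
        shifted = np.empty_like(data)
        gxs = np.empty_like(data)
        gys = np.empty_like(data)
        for j in range(nz):
            for ci in range(data.shape[0]):
                shifted[ci, j] = _shift_plane_fourier(data[ci, j], s[j, 0], s[j, 1])
                gxs[ci, j] = _shift_plane_fourier(grad_x[ci, j], s[j, 0], s[j, 1])
                gys[ci, j] = _shift_plane_fourier(grad_y[ci, j], s[j, 0], s[j, 1])
        diff = (shifted[:, :-1] - shifted[:, 1:]) * mask
        loss = float(np.sum(diff**2)) / norm + lam * float(np.sum(s**2))
        g = np.zeros_like(s)
        for j in range(nz):
            acc_x = 0.0
            acc_y = 0.0
            if j < nz - 1:
                acc_x += np.sum(diff[:, j] * gxs[:, j])
                acc_y += np.sum(diff[:, j] * gys[:, j])
            if j > 0:
                acc_x -= np.sum(diff[:, j - 1] * gxs[:, j])
                acc_y -= np.sum(diff[:, j - 1] * gys[:, j])
            g[j, 0] = 2.0 * acc_x / norm + 2.0 * lam * s[j, 0]
            g[j, 1] = 2.0 * acc_y / norm + 2.0 * lam * s[j, 1]
        return loss, g

    m = np.zeros_like(shifts)
    v = np.zeros_like(shifts)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_loss = np.inf
    best_shifts = shifts.copy()
    stall = 0
    cur_lr = lr
    for _ in range(max_iter):
        loss, g = loss_and_grad(shifts)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_shifts = shifts.copy()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                # plateau: restore the best iterate and refine at a smaller step
                shifts = best_shifts.copy()
                m[:] = 0
                v[:] = 0
                t = 0
                cur_lr *= 0.5
                stall = 0
                if cur_lr < min_lr:
                    break
                continue
        t += 1
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        shifts = shifts - cur_lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)

    shifts = best_shifts
    corrected = np.empty_like(vol)
    for c in range(vol.shape[0]):
        for j in range(nz):
            corrected[c, j] = _shift_plane_fourier(vol[c, j], shifts[j, 0], shifts[j, 1])
    return shifts, corrected[0] if single else corrected


def _xcorr_nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation (mean removed) via FFT; peak at the shift s
    with ``b == roll(a_prev, s)`` when called as (current, previous)."""
    fa = np.fft.fftn(a - a.mean())
    fb = np.fft.fftn(b - b.mean())
    return np.fft.ifftn(fa * np.conj(fb)).real


def align_time(current: np.ndarray, previous: np.ndarray) -> tuple[int, ...]:
    """Integer 3D shift of `current` relative to `previous` (cross-correlation argmax)."""
    a = np.asarray(current, dtype=float)
    b = np.asarray(previous, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must have the same shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("flat (zero-variance) stack; cannot register")
    c = _xcorr_nd(a, b)
    peak = np.unravel_index(np.argmax(c), c.shape)
    return tuple(int(p - n if p > n // 2 else p) for p, n in zip(peak, c.shape))


def cumulative_time_shifts(stacks: list[np.ndarray]) -> np.ndarray:
    """Absolute shift of each time point (cumulative sum of pairwise shifts)."""
    shifts = [np.zeros(stacks[0].ndim, dtype=int)]
    for t in range(1, len(stacks)):
        shifts.append(np.asarray(align_time(stacks[t], stacks[t - 1])))
    return np.cumsum(shifts, axis=0)


def average_time(stacks_over_time: list[np.ndarray]) -> np.ndarray:
    """Time-averaged stack used as the stitching input."""
    return np.mean(np.stack(stacks_over_time), axis=0)


def min_over_channels(volume: np.ndarray, channels: list[int]) -> np.ndarray:
    """Autofluorescence proxy: minimum pixel value over several channels."""
    return np.min(np.asarray(volume)[list(channels)], axis=0)


def _overlap_correlation(stack_i, origin_i, stack_j, origin_j):
    lo = np.maximum(origin_i, origin_j)
    hi = np.minimum(origin_i + np.asarray(stack_i.shape), origin_j + np.asarray(stack_j.shape))
    if np.any(hi - lo < 2):
        return None
    axes = [np.arange(l, h) for l, h in zip(lo, hi)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords_i = [g - o for g, o in zip(grid, origin_i)]
    coords_j = [g - o for g, o in zip(grid, origin_j)]
    a = ndimage.map_coordinates(stack_i, coords_i, order=1, mode="constant", cval=0.0)
    b = ndimage.map_coordinates(stack_j, coords_j, order=1, mode="constant", cval=0.0)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def stitch_stacks(
    stacks: list[np.ndarray],
    nominal_origins: np.ndarray,
    max_shift: float = 6.0,
) -> np.ndarray:
    """Per-stack 3D offsets maximizing the mean overlap correlation.

    Parameters
    ----------
    stacks : single-channel (z, y, x) arrays (pass a fiducial channel or the
        min-over-channels pseudo-channel; average time points first).
    nominal_origins : (n, 3) voxel origins of each stack in a shared frame.

    Returns
    -------
    (n, 3) offsets to *add* to the nominal origins; the first stack is pinned
    at zero.
    """
    origins = np.asarray(nominal_origins, dtype=float)
    n = len(stacks)
    if n < 2:
        return np.zeros((n, 3))
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if _overlap_correlation(stacks[i], origins[i], stacks[j], origins[j]) is not None:
                pairs.append((i, j))
    if not pairs:
        raise ValueError("no usable overlapping pairs (all flat or disjoint)")

    def objective(theta):
        offs = np.vstack([np.zeros(3), theta.reshape(n - 1, 3)])
        cors = []
        for i, j in pairs:
            c = _overlap_correlation(
                stacks[i], origins[i] + offs[i], stacks[j], origins[j] + offs[j]
            )
            if c is not None:
                cors.append(c)
        if not cors:
            return 1.0
        return -float(np.mean(cors))

    x0 = np.zeros(3 * (n - 1))
    bounds = [(-max_shift, max_shift)] * len(x0)
    with warnings.catch_warnings():
        # the BFGS Hessian update inside trust-constr reports flat-gradient
        # steps on the piecewise-smooth resampled objective; harmless here
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res = optimize.minimize(
            objective,
            x0,
            method="trust-constr",
            bounds=bounds,
            options={"maxiter": 120, "finite_diff_rel_step": None, "gtol": 1e-8},
        )
    return np.vstack([np.zeros(3), res.x.reshape(n - 1, 3)])


@dataclass
class DriftState:
    """Exponential-moving-average estimate of the Z-drift rate."""

    rate: float = 0.0          # planes (or um) per step
    last_offset: float = 0.0
    weight: float = 0.5

    def updated(self, offset: float) -> "DriftState":
        new_rate = self.weight * offset + (1.0 - self.weight) * self.rate
        return DriftState(rate=new_rate, last_offset=offset, weight=self.weight)

    @property
    def predicted_next(self) -> float:
        return self.rate


def estimate_z_drift(
    volume_t: np.ndarray,
    volume_prev: np.ndarray,
    state: DriftState | None = None,
    ema_weight: float = 0.5,
) -> tuple[float, DriftState]:
    """Sub-plane Z offset between consecutive time points, with EMA update.

    The 3D cross-correlation of the two volumes (use the SHG-like fiducial
    channel) is reduced to a curve by taking, for every Z lag, the maximum
    over the corresponding 2D slice; a cubic spline through these maxima is
    maximized to give the Z offset with sub-plane accuracy.
    """
    a = np.asarray(volume_t, dtype=float)
    b = np.asarray(volume_prev, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must have the same shape")
    if a.shape[0] < 4:
        raise ValueError("need >= 4 planes for the spline fit")
    c = _xcorr_nd(a, b)
    per_slice_max = c.reshape(c.shape[0], -1).max(axis=1)
    nz = c.shape[0]
    lags = np.arange(nz)
    lags = np.where(lags > nz // 2, lags - nz, lags)
    order = np.argsort(lags)
    lags_s = lags[order].astype(float)
    vals_s = per_slice_max[order]
    if np.ptp(vals_s) <= 1e-12 * max(abs(vals_s).max(), 1e-30):
        warnings.warn("flat cross-correlation maxima; Z offset set to 0")
        offset = 0.0
    else:
        spline = CubicSpline(lags_s, vals_s)
        fine = np.linspace(lags_s[0], lags_s[-1], 4001)
        offset = float(fine[np.argmax(spline(fine))])
    if state is None:
        state = DriftState(rate=offset, last_offset=offset, weight=ema_weight)
    else:
        state = state.updated(offset)
    return offset, state
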