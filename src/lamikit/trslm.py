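"""Software model of the time-realized spatial light modulator (TR-SLM).

An 8x8 modulation pattern is bilinearly interpolated across the field, and
the EOM voltage follows the raster scan: the resonant X mirror imposes an
inverse-cosine time-to-position map, the galvo Y mirror advances linearly per
line, the DAC quantizes the commanded voltage to 12 bits of the 1.2 V full
scale, and the voltage is held between update ticks, which smears sharp
transitions along the fast (horizontal) axis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModulationPattern", "ScanModel", "interpolate_pattern", "scan_position", "apply_pattern"]


@dataclass(frozen=True)
class ModulationPattern:
    """Square low-resolution grid of relative modulation values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.size == 0:
            raise ValueError("pattern must be a non-empty square 2D grid")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("pattern values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ScanModel:
    """Raster-scan timing for one field of view."""

    line_period: float = 63e-6   # s per line (resonant half period)
    n_lines: int = 512
    update_interval: float = 0.5e-6  # s between EOM voltage updates
    dac_bits: int = 12
    v_full_scale: float = 1.2

    def __post_init__(self):
        if self.dac_bits < 1:
            raise ValueError("need at least 1 DAC bit")
        if self.update_interval <= 0:
            raise ValueError("update interval must be positive")

    @property
    def frame_period(self) -> float:
        return self.line_period * self.n_lines

    @property
    def quantization_step(self) -> float:
        return self.v_full_scale / 2**self.dac_bits


def interpolate_pattern(pattern: ModulationPattern, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear interpolation of the pattern onto a pixel grid.

    Pattern nodes are pinned to the image corners, so node-aligned pixels
    reproduce the pattern exactly and every value stays within the pattern's
    range.  Bilinear interpolation reproduces affine ramps exactly, which is
    what makes smooth gradients (the realistic use case) faithful.
    """
    h, w = shape
    if h < 2 or w < 2:
        raise ValueError("pixel grid must be at least 2x2")
    n = pattern.n
    rows = np.arange(h) * (n - 1) / (h - 1)
    cols = np.arange(w) * (n - 1) / (w - 1)
    r0 = np.clip(np.floor(rows).astype(int), 0, n - 2)
    c0 = np.clip(np.floor(cols).astype(int), 0, n - 2)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    v = pattern.values
    return (
        v[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + v[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + v[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + v[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )


def scan_position(t, model: ScanModel) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (x, y) in [0, 1]^2 at elapsed frame time t (seconds).

    X follows the resonant mirror's sinusoidal sweep, so position is the
    inverse-cosine map of elapsed line time; Y advances linearly per line.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= model.frame_period):
        raise ValueError("t must lie within [0, frame period)")
    # tolerate float rounding at exact line boundaries
    line = np.floor(t / model.line_period + 1e-9)
    t_line = t - line * model.line_period
    x = 0.5 * (1.0 - np.cos(np.pi * t_line / model.line_period))
    y = line / max(model.n_lines - 1, 1)
    return x, y


def apply_pattern(
    pattern: ModulationPattern,
    model: ScanModel,
    calibration=None,
    shape: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the power actually applied per pixel plus the voltage trace.

    The commanded voltage is the bilinear pattern value times full scale,
    quantized to the DAC resolution and held constant between update ticks.
    With ``calibration=None`` power is reported as the fraction of full-power
    voltage (identity calibration); otherwise the calibration's sinusoid maps
    held voltage to power.

    Returns ``(power_image, update_times, voltage_trace)``.
    """
    h, w = shape
    vmax_pattern = float(pattern.values.max()) * model.v_full_scale
    step = model.quantization_step

    # the line-sync interrupt restarts the update timer at every line, so
    # ticks are identical within each line and never carry across lines
    u = np.arange(0.0, model.line_period, model.update_interval)
    x_tick = 0.5 * (1.0 - np.cos(np.pi * u / model.line_period))
    y_line = np.arange(model.n_lines) / max(model.n_lines - 1, 1)

    n = pattern.n
    rr = np.clip(y_line * (n - 1), 0, n - 1)
    cc = np.clip(x_tick * (n - 1), 0, n - 1)
    r0 = np.clip(np.floor(rr).astype(int), 0, n - 2)
    c0 = np.clip(np.floor(cc).astype(int), 0, n - 2)
    fr = (rr - r0)[:, None]
    fc = (cc - c0)[None, :]
    v = pattern.values
    val = (
        v[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + v[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + v[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + v[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )  # (n_lines, n_ticks)
    volts = np.round(val * model.v_full_scale / step) * step
    # rounding may poke at most half a step above the commanded maximum;
    # clamp so the applied power never exceeds the pattern's own ceiling
    volts = np.minimum(volts, vmax_pattern)

    # per-pixel applied voltage: pixel (row, col) is visited at a known
    # intra-line time; the voltage is the one latched at the preceding tick
    lines_of_rows = np.round(np.arange(h) * (model.n_lines - 1) / max(h - 1, 1)).astype(int)
    x_pix = np.arange(w) / max(w - 1, 1)
    t_in_line = model.line_period / np.pi * np.arccos(1.0 - 2.0 * np.clip(x_pix, 0, 1))
    idx = np.clip(np.searchsorted(u, t_in_line + 1e-12, side="right") - 1, 0, len(u) - 1)
    applied_v = volts[np.ix_(lines_of_rows, idx)]
    ticks = (np.arange(model.n_lines)[:, None] * model.line_period + u[None, :]).ravel()
    volts = volts.ravel()

    if calibration is None:
        power = applied_v / model.v_full_scale
    else:
        power = calibration.power(applied_v)
    return power, ticks, volts
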