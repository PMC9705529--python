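"""Sliding-window weighted phase lag index (WPLI) connectivity.

The WPLI measures phase-lagged coupling between two signals using only the
imaginary part of their cross-spectrum,

    WPLI = | mean_t Im S_xy(t) | / mean_t | Im S_xy(t) |,

with S_xy(t) = x_a(t) * conj(y_a(t)) the per-sample cross-spectral term of
the analytic (Hilbert) signals of the band-limited inputs.  Because the
imaginary part vanishes for zero-lag (volume-conducted) coupling, WPLI is
blind to instantaneous mixing and ranges from 0 (no consistently lagged
interaction) to 1 (constant-sign lag).  When the denominator is zero
(identical, zero-lag or null signals) the index is defined as 0: zero
evidence of lagged interaction.

A trial is cut into short overlapping windows (default 300 ms, 50% overlap,
so a 2 s trial at 500 Hz yields 12 windows); the per-window WPLI matrices
form the intralayer weights of the trial's multilayer graph.  The analytic
signal is computed once on the full analysis segment and then windowed,
avoiding per-window Hilbert edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (length in ms, fractional overlap)."""

    window_ms: float = 300.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ConnectivityError("overlap_fraction must be in [0, 1)")
        if self.window_ms <= 0:
            raise ConnectivityError("window_ms must be positive")

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_ms * fs / 1000.0))
        if n < 2:
            raise ConnectivityError("window must contain at least 2 samples")
        return n

    def step_samples(self, fs: float) -> int:
        w = self.window_samples(fs)
        step = int(round(w * (1.0 - self.overlap_fraction)))
        return max(step, 1)

    def n_windows(self, n_samples: int, fs: float) -> int:
        w = self.window_samples(fs)
        if w > n_samples:
            raise ConnectivityError(
                f"window of {w} samples longer than trial of {n_samples} samples"
            )
        return (n_samples - w) // self.step_samples(fs) + 1


def make_windows(n_samples: int, fs: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, stop) sample intervals of the sliding windows.

    Trailing samples not covered by a full window are dropped.
    """
    w = spec.window_samples(fs)
    step = spec.step_samples(fs)
    count = spec.n_windows(n_samples, fs)
    return [(i * step, i * step + w) for i in range(count)]


@dataclass(frozen=True)
class ConnectivityStack:
    """Layer-indexed stack of symmetric WPLI matrices for one trial."""

    values: np.ndarray             # (n_windows, n_nodes, n_nodes)
    spec: WindowSpec
    fs: float
    node_labels: tuple[str, ...] = ()
    trial_id: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ConnectivityError("values must have shape (n_windows, n_nodes, n_nodes)")
        if not np.isfinite(v).all():
            raise ConnectivityError("connectivity values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def band_filter(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ConnectivityError(f"band {band} invalid for fs={fs}")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def analytic_signal(x: np.ndarray, fs: float, band: tuple[float, float] | None = (8.0, 13.0)) -> np.ndarray:
    """Analytic (Hilbert) signal of band-filtered input, last axis = time.

    ``band=None`` skips filtering for inputs that are already band-limited.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ConnectivityError("input signal contains non-finite values")
    if band is not None:
        x = band_filter(x, fs, band)
    return hilbert(x, axis=-1)


#: Relative floor below which the summed |Im| is treated as exactly zero
#: (zero-lag or null signals leave only floating-point residue).
_ZERO_LAG_RTOL = 1e-10


def _wpli_from_analytic(zx: np.ndarray, zy: np.ndarray, debiased: bool = False) -> float:
    """WPLI from two equal-length analytic-signal windows."""
    im = np.imag(zx * np.conj(zy))
    scale = np.sum(np.abs(zx) * np.abs(zy))
    den = np.sum(np.abs(im))
    if den <= _ZERO_LAG_RTOL * scale:
        return 0.0
    if debiased:
        num = np.sum(im) ** 2 - np.sum(im**2)
        den2 = den**2 - np.sum(im**2)
        return float(num / den2) if den2 > 0 else 0.0
    return float(np.abs(np.sum(im)) / den)


def wpli_pairwise(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = (8.0, 13.0),
    debiased: bool = False,
) -> float:
    """WPLI between two signals, computed over the full given segment.

    The inputs are band-filtered (unless ``band`` is None), converted to
    analytic signals, and the per-sample imaginary cross-spectral terms are
    averaged.  ``debiased`` selects the debiased squared estimator instead
    of the plain index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConnectivityError("x and y must be equal-length 1-D signals")
    if x.size < 2:
        raise ConnectivityError("need at least 2 samples")
    zx = analytic_signal(x, fs, band)
    zy = analytic_signal(y, fs, band)
    return _wpli_from_analytic(zx, zy, debiased=debiased)


def connectivity_stack(
    trial: np.ndarray,
    fs: float,
    spec: WindowSpec = WindowSpec(),
    band: tuple[float, float] | None = (8.0, 13.0),
    debiased: bool = False,
    node_labels: Sequence[str] = (),
    trial_id: int | None = None,
) -> ConnectivityStack:
    """Per-window WPLI matrices for one trial (nodes x samples).

    The analytic signal is computed once over the whole trial, then sliced
    per window; every unordered node pair gets one WPLI value per window
    (symmetric layers, zero diagonal, values in [0, 1]).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ConnectivityError("trial must have shape (n_nodes, n_samples)")
    n_nodes, n_samples = trial.shape
    windows = make_windows(n_samples, fs, spec)
    z = analytic_signal(trial, fs, band)          # (n_nodes, n_samples) complex

    out = np.zeros((len(windows), n_nodes, n_nodes))
    for w, (a, b) in enumerate(windows):
        zw = z[:, a:b]
        re, im = np.real(zw), np.imag(zw)
        # Im(x * conj(y)) summed over samples, for all pairs at once
        cross_im = im @ re.T - re @ im.T          # (n_nodes, n_nodes), antisymmetric
        # per-sample |Im| cannot be factored into matrix products; build it explicitly
        per_sample = im[:, None, :] * re[None, :, :] - re[:, None, :] * im[None, :, :]
        mag = np.abs(zw)
        zero_floor = _ZERO_LAG_RTOL * (mag @ mag.T)
        den = np.sum(np.abs(per_sample), axis=-1)
        nonzero = den > zero_floor
        if debiased:
            sq = np.sum(per_sample**2, axis=-1)
            num = cross_im**2 - sq
            den2 = den**2 - sq
            with np.errstate(invalid="ignore", divide="ignore"):
                layer = np.where(nonzero & (den2 > 0), num / den2, 0.0)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                layer = np.where(nonzero, np.abs(cross_im) / den, 0.0)
        np.fill_diagonal(layer, 0.0)
        layer = np.clip(0.5 * (layer + layer.T), 0.0, 1.0)  # symmetrize roundoff
        out[w] = layer

    return ConnectivityStack(
        values=out,
        spec=spec,
        fs=fs,
        node_labels=tuple(node_labels),
        trial_id=trial_id,
    )
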