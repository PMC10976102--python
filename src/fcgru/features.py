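"""Frequency-spatial feature extraction: PLV connectivity + FFT band power.

For a window of ``n`` samples over ``NC`` channels the phase-locking
value between channels x and y is the modulus of the time-averaged unit
phasor of their instantaneous phase difference,

    PLV = | (1/n) * sum_t exp(i (phi_x(t) - phi_y(t))) |  in [0, 1],

where the instantaneous phase is taken from the analytic signal (Hilbert
transform) of each channel.  The full pairwise matrix is symmetric with
unit diagonal, carrying NC(NC+1)/2 unique functional-connectivity values.

Band features come from the discrete Fourier transform: per channel, the
mean squared FFT magnitude over the bins of each canonical EEG band
(delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz), giving
an NC x 5 matrix.

The two are fused column-wise into an NC x (NC + 5) frequency-spatial
matrix; a sequence of such matrices over sliding sub-windows of one
sample is the tensor consumed by the convolutional-recurrent network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .datasets import Sample

__all__ = [
    "BAND_NAMES",
    "DEFAULT_BANDS",
    "PhaseSeries",
    "PLVMatrix",
    "BandFeatures",
    "FusedFeatureTensor",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "band_features",
    "fuse",
    "sample_to_tensor",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: canonical EEG band edges in Hz; the gamma upper edge of 45 Hz keeps
#: clear of the 64 Hz Nyquist limit at fs=128 and of mains interference
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class PhaseSeries:
    """Instantaneous phase per sample and channel, radians.

    ``degenerate`` flags channels whose phase is undefined (all-zero
    input); their phases are reported as zero.
    """

    phases: np.ndarray  # samples x channels
    degenerate: np.ndarray  # bool per channel


@dataclass
class PLVMatrix:
    """Symmetric NC x NC phase-locking matrix, entries in [0, 1], diag 1."""

    values: np.ndarray
    degenerate: np.ndarray


@dataclass
class BandFeatures:
    """NC x 5 non-negative band powers, column order delta..gamma."""

    values: np.ndarray
    band_edges: dict[str, tuple[float, float]]


@dataclass
class FusedFeatureTensor:
    """steps x NC x (NC+5) sequence of fused frequency-spatial matrices."""

    values: np.ndarray
    subwindow_len: int
    subwindow_step: int


def instantaneous_phase(window: np.ndarray) -> PhaseSeries:
    """Per-channel instantaneous phase of a samples x channels window.

    Computed as the angle of the analytic signal, so it is invariant to
    positive amplitude scaling.  All-zero channels are flagged and given
    zero phase.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("window must be samples x channels")
    if window.shape[0] < 8:
        raise ValueError(f"need >= 8 samples, got {window.shape[0]}")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    degenerate = np.all(window == 0.0, axis=0)
    phases = np.angle(hilbert(window, axis=0))
    phases[:, degenerate] = 0.0
    return PhaseSeries(phases=phases, degenerate=degenerate)


def plv(x_phase: np.ndarray, y_phase: np.ndarray) -> float:
    """Phase-locking value of two equal-length phase series.

    Returns 1 exactly when the phase difference is constant over the
    window and approaches 0 for uniformly sweeping differences.
    """
    x_phase = np.asarray(x_phase, dtype=np.float64)
    y_phase = np.asarray(y_phase, dtype=np.float64)
    if x_phase.shape != y_phase.shape:
        raise ValueError(f"phase length mismatch: {x_phase.shape} vs {y_phase.shape}")
    if x_phase.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(np.exp(1j * (x_phase - y_phase)))))


def plv_matrix(
    window: np.ndarray,
    band: tuple[float, float] | None = None,
    fs: float | None = None,
) -> PLVMatrix:
    """All-pairs PLV of a samples x channels window.

    Vectorized over the Gram matrix of unit phasors; exploits symmetry
    (only the upper triangle is independent) and pins the diagonal to 1.

    By default the phase is broadband.  Passing ``band=(lo, hi)`` with
    ``fs`` band-filters the window (4th-order zero-phase Butterworth)
    before phase extraction, giving per-band phase locking.
    """
    window = np.asarray(window, dtype=np.float64)
    if band is not None:
        if fs is None:
            raise ValueError("band-limited PLV requires fs")
        from scipy.signal import butter, filtfilt

        b, a = butter(4, band, btype="bandpass", fs=fs)
        window = filtfilt(b, a, window, axis=0)
    ps = instantaneous_phase(window)
    n, nc = ps.phases.shape
    if nc < 2:
        raise ValueError(f"need >= 2 channels, got {nc}")
    z = np.exp(1j * ps.phases)  # n x NC
    m = np.abs(z.conj().T @ z) / n
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    np.clip(m, 0.0, 1.0, out=m)
    return PLVMatrix(values=m, degenerate=ps.degenerate)


def band_features(
    window: np.ndarray,
    fs: float,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> BandFeatures:
    """Mean squared FFT magnitude per channel and canonical band.

    Bins with frequency in the half-open interval [low, high) contribute
    to a band.  A band whose edges exceed the Nyquist frequency is an
    error; a band too narrow to contain any bin at this window length
    yields 0 with a resolution warning.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("window must be samples x channels")
    bands = dict(band_edges) if band_edges is not None else dict(DEFAULT_BANDS)
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq or lo < 0 or lo >= hi:
            raise ValueError(f"band {name} [{lo}, {hi}) outside (0, Nyquist={nyq}]")
    n = window.shape[0]
    spec = np.abs(np.fft.rfft(window, axis=0)) ** 2  # |H(k)|^2, bins x channels
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    cols = []
    for name in bands:
        lo, hi = bands[name]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            warnings.warn(
                f"window of {n} samples has no FFT bin in band {name} [{lo}, {hi}) Hz",
                stacklevel=2,
            )
            cols.append(np.zeros(window.shape[1]))
        else:
            cols.append(spec[mask].mean(axis=0))
    return BandFeatures(values=np.column_stack(cols), band_edges=bands)


def fuse(plv_mat: PLVMatrix, bands: BandFeatures) -> np.ndarray:
    """Column-concatenate [PLV | band powers] into an NC x (NC+5) matrix.

    The full symmetric PLV matrix is kept (not the packed triangle) so
    each row stays aligned with one channel and 2-D convolutions see
    spatially coherent structure.
    """
    p = plv_mat.values
    b = bands.values
    if p.shape[0] != b.shape[0]:
        raise ValueError(f"channel mismatch: PLV {p.shape[0]} vs bands {b.shape[0]}")
    return np.hstack([p, b])


def sample_to_tensor(
    sample: Sample,
    fs: float,
    subwindow_len: int = 64,
    subwindow_step: int = 16,
    band_edges: dict[str, tuple[float, float]] | None = None,
    use_plv: bool = True,
) -> FusedFeatureTensor:
    """Sequence of fused matrices over sliding sub-windows of one sample.

    Sub-window s covers samples [s*step, s*step + len); the defaults
    (64-sample sub-windows, 16-sample step) turn a 1 s window at 128 Hz
    into a 5-step sequence, giving the recurrent stage a temporal axis
    within the sample.  With ``use_plv=False`` only the NC x 5 band
    matrix is emitted per step (for connectivity-free model variants).
    """
    win = np.asarray(sample.window, dtype=np.float64)
    n = win.shape[0]
    if subwindow_len > n:
        raise ValueError(f"sub-window {subwindow_len} longer than sample {n}")
    if subwindow_len < 8 or subwindow_step < 1:
        raise ValueError("sub-window must be >= 8 samples with step >= 1")
    steps = (n - subwindow_len) // subwindow_step + 1
    mats = []
    for s in range(steps):
        lo = s * subwindow_step
        sub = win[lo : lo + subwindow_len]
        bf = band_features(sub, fs, band_edges)
        if use_plv:
            mats.append(fuse(plv_matrix(sub), bf))
        else:
            mats.append(bf.values)
    return FusedFeatureTensor(
        values=np.stack(mats),
        subwindow_len=subwindow_len,
        subwindow_step=subwindow_step,
    )
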