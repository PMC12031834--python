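"""Quantitative EEG features: band energies, amplitude entropy, Higuchi fractal
dimension, and per-record summaries with baseline normalization.

Band energies are integrals of the power spectral density over the clinical
bands delta [2, 4] Hz, theta [4, 8] Hz, alpha [8, 14] Hz and beta [14, 30] Hz.
The composite slowing index DTAR = (E_delta + E_theta) / E_alpha rises with
diffuse background slowing. Features are computed per 2-second window and
channel, summarized as the median over all (window, channel) pairs, and —
for post-infusion records — expressed as ratios to the patient's own
pre-infusion baseline so that patients are comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, DataError, NormalizationError, SizeError
from .records import WindowSet

#: Clinical frequency bands (Hz), closed intervals.
BANDS = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
}

#: Broadband interval retained by the preprocessing band-pass.
TOTAL_BAND = (0.5, 40.0)


def psd(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD (µV²/Hz) of a single-channel window via the FFT.

    A Hann taper controls spectral leakage (relevant because assembled epochs
    may contain concatenation seams). The density scaling is Parseval
    consistent: the integral of the PSD over [0, Nyquist] matches the window
    variance (exactly in expectation for stationary signals).
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise DataError("window contains non-finite samples")
    freqs, pxx = sps.periodogram(window, fs=fs, window="hann", detrend="constant")
    return freqs, pxx


def band_energy(freqs: np.ndarray, pxx: np.ndarray,
                bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, float]:
    """Integrate a PSD over each band (trapezoid, band edges interpolated)."""
    return {name: _integrate(freqs, pxx, lo, hi) for name, (lo, hi) in bands.items()}


def total_energy(freqs: np.ndarray, pxx: np.ndarray) -> float:
    """PSD integral over the full retained band (0.5-40 Hz)."""
    return _integrate(freqs, pxx, *TOTAL_BAND)


def _integrate(freqs: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    if lo < freqs[0] or hi > freqs[-1]:
        raise ConfigError(
            f"PSD grid [{freqs[0]:g}, {freqs[-1]:g}] Hz does not cover [{lo:g}, {hi:g}] Hz")
    grid = freqs[(freqs > lo) & (freqs < hi)]
    xs = np.concatenate(([lo], grid, [hi]))
    ys = np.interp(xs, freqs, pxx)
    return float(np.trapezoid(ys, xs))


def dtar(energies: dict[str, float]) -> float:
    """Delta+theta over alpha energy ratio — the composite slowing index."""
    if energies["alpha"] <= 0:
        raise DataError("DTAR undefined: alpha energy is not positive")
    return (energies["delta"] + energies["theta"]) / energies["alpha"]


def signal_entropy(window: np.ndarray) -> float:
    """Differential entropy (nats) of the sample-amplitude distribution.

    Histogram estimator with Freedman-Diaconis bin width: shift-invariant, and
    obeys H(aX) = H(X) + ln|a| up to estimator noise. A constant window has no
    amplitude spread; it returns ``-inf`` with a degeneracy warning.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 64:
        raise SizeError("entropy needs at least 64 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("window contains non-finite samples")
    q75, q25 = np.percentile(x, [75, 25])
    width = 2.0 * (q75 - q25) * x.size ** (-1.0 / 3.0)
    if width <= 0:
        warnings.warn("degenerate (constant) signal: entropy is -inf", RuntimeWarning)
        return float("-inf")
    n_bins = max(1, int(np.ceil((x.max() - x.min()) / width)))
    counts, edges = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    h = float(-(p * np.log(p)).sum() + np.log(edges[1] - edges[0]))
    return h


def higuchi_fd(window: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a single-channel window.

    For each scale k = 1..kmax and offset m, the normalized curve length
    L_m(k) = [(N-1) / (floor((N-m)/k) k)] * sum |x[m+ik] - x[m+(i-1)k]| / k
    is averaged over offsets; F is minus the least-squares slope of
    log L(k) vs log k. F lies in [1, 2] — 1 for smooth curves, 2 in the
    white-noise limit — and is invariant to amplitude scaling.
    """
    x = np.asarray(window, dtype=float)
    n = x.size
    if n < 100:
        raise SizeError("Higuchi FD needs at least 100 samples")
    if kmax < 2:
        raise ConfigError("kmax must be >= 2")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    logs_k = np.log(np.arange(1, kmax + 1))
    with np.errstate(divide="ignore"):
        logs_l = np.log(lk)
    if not np.all(np.isfinite(logs_l)):  # flat signal: zero curve length
        return 1.0
    slope = np.polyfit(logs_k, logs_l, 1)[0]
    fd = float(-slope)
    if not 1.0 <= fd <= 2.0:
        warnings.warn(f"Higuchi FD {fd:.3f} outside [1, 2]; clipping", RuntimeWarning)
        fd = float(np.clip(fd, 1.0, 2.0))
    return fd


@dataclass
class RecordFeatures:
    """Per-record quantitative summary: medians over all (window, channel) pairs.

    Energies in µV² (or dimensionless ratios once ``normalized``); ``dtar`` is
    computed from the summarized band energies. ``connectivity`` carries
    channel-median graph summaries (in/out-degree, centralities, ...) when the
    connectivity stage has run.
    """

    med_e_delta: float
    med_e_theta: float
    med_e_alpha: float
    med_e_beta: float
    dtar: float
    med_entropy: float
    med_fractal: float
    connectivity: dict[str, float] = field(default_factory=dict)
    normalized: bool = False

    _SCALAR_FIELDS = ("med_e_delta", "med_e_theta", "med_e_alpha", "med_e_beta",
                      "dtar", "med_entropy", "med_fractal")

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in self._SCALAR_FIELDS}
        out.update(self.connectivity)
        return out


def window_band_energies(wset: WindowSet) -> dict[str, np.ndarray]:
    """Band energies for every (window, channel) pair of a window set.

    Returns arrays of shape (n_windows, n_channels) per band plus 'total'.
    """
    n_w, n_ch, _ = wset.windows.shape
    out = {name: np.empty((n_w, n_ch)) for name in BANDS}
    out["total"] = np.empty((n_w, n_ch))
    for w in range(n_w):
        for c in range(n_ch):
            freqs, pxx = psd(wset.windows[w, c], wset.fs)
            for name, e in band_energy(freqs, pxx).items():
                out[name][w, c] = e
            out["total"][w, c] = total_energy(freqs, pxx)
    return out


def summarize_record(wset: WindowSet, kmax: int = 10) -> RecordFeatures:
    """Compute all window×channel features of a record and take medians.

    The median is pooled jointly over windows and channels (one scalar per
    feature per record); DTAR is formed from the pooled median energies.
    """
    if wset.n_windows < 1:
        raise SizeError("empty window set")
    energies = window_band_energies(wset)
    n_w, n_ch, _ = wset.windows.shape
    ent = np.empty((n_w, n_ch))
    fd = np.empty((n_w, n_ch))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for w in range(n_w):
            for c in range(n_ch):
                ent[w, c] = signal_entropy(wset.windows[w, c])
                fd[w, c] = higuchi_fd(wset.windows[w, c], kmax=kmax)
    med = {name: float(np.median(energies[name])) for name in BANDS}
    return RecordFeatures(
        med_e_delta=med["delta"], med_e_theta=med["theta"],
        med_e_alpha=med["alpha"], med_e_beta=med["beta"],
        dtar=dtar(med),
        med_entropy=float(np.median(ent)),
        med_fractal=float(np.median(fd)),
    )


def normalize_to_baseline(post: RecordFeatures, baseline: RecordFeatures) -> RecordFeatures:
    """Express a post-infusion record's features as ratios to the baseline record.

    Both inputs must be unnormalized; every baseline feature entering a ratio
    must be strictly positive.
    """
    if post.normalized or baseline.normalized:
        raise DataError("normalize_to_baseline expects unnormalized inputs")
    values = {}
    base_conn = baseline.connectivity
    for name in RecordFeatures._SCALAR_FIELDS:
        b = getattr(baseline, name)
        if not np.isfinite(b) or b <= 0:
            raise NormalizationError(name)
        values[name] = getattr(post, name) / b
    conn = {}
    for name, v in post.connectivity.items():
        b = base_conn.get(name)
        if b is None or not np.isfinite(b) or b <= 0:
            raise NormalizationError(name)
        conn[name] = v / b
    return replace(post, connectivity=conn, normalized=True, **values)
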