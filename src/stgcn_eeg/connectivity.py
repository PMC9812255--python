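"""Pairwise functional-connectivity measures and adjacency matrices.

Six measures quantify coupling between channel pairs, each on its own
footing:

* **PC** — Pearson correlation: instantaneous linear amplitude dependence.
* **MSC** — magnitude squared coherence: band-averaged normalised
  cross-spectrum from Welch sub-segment averaging.
* **IPC** — imaginary part of coherency: discards the real (zero-lag)
  component that volume conduction inflates.
* **WC** — wavelet coherence: Morlet cross-spectra smoothed over time,
  resolving coupling in time and frequency.
* **PLV** — phase locking value: magnitude of the mean complex phase
  difference (Hilbert phases).
* **PLI** — phase lag index: absolute mean sign of the phase difference,
  blind to zero-lag coupling.

``adjacency`` assembles the symmetric 23 x 23 coupling matrix W of one
mini-epoch with zero diagonal and no thresholding; signed measures (PC, and
IPC before the modulus) are rectified by absolute value so that the graph
operators' degree normalisation stays real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .bands import FULL, BandSpec
from .preprocess import MiniEpoch

FC_METHODS = ("PC", "MSC", "IPC", "WC", "PLV", "PLI")


class DegenerateEstimateError(ValueError):
    """The estimator configuration makes the measure trivially degenerate."""


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel (radians, in (-pi, pi])."""

    phi: np.ndarray
    analytic_imag: np.ndarray
    dt: float


@dataclass
class SpectralParams:
    """Welch configuration for the coherence measures.

    Sub-segments of 12 samples with 50% overlap give three averaged
    sub-segments within a 25-sample mini-epoch — the minimum averaging that
    avoids the single-segment degeneracy where coherence is identically 1.
    """

    nperseg: int = 12
    noverlap: int = 6
    window: str = "hann"
    detrend: str = "constant"

    def n_subsegments(self, n: int) -> int:
        step = self.nperseg - self.noverlap
        if n < self.nperseg:
            return 0
        return (n - self.noverlap) // step


@dataclass
class WaveletSpec:
    """Morlet continuous-wavelet configuration for wavelet coherence.

    Cross-spectra are smoothed over a time span proportional to scale
    (``smooth_periods`` oscillation periods, at least ``smooth_len`` samples,
    capped at the segment length), the standard practice for wavelet
    coherence: smoothing much shorter than one period leaves the estimate
    biased to 1 at that scale.
    """

    family: str = "morlet"
    center_freq_param: float = 6.0
    n_freqs: int = 8
    smooth_len: int = 7
    smooth_periods: float = 2.0
    freqs: np.ndarray | None = None

    def min_resolvable_hz(self, n_samples: int, fs: float) -> float:
        """Lowest frequency whose smoothing window fits twice in the segment.

        Below this the segment yields a single smoothed cross-spectral
        estimate and the coherence is 1 by construction (the wavelet
        analogue of the cone of influence); such scales carry no
        information and are excluded from band averaging when possible.
        """
        return 2.0 * self.smooth_periods * fs / n_samples

    def band_freqs(self, band: BandSpec, n_samples: int | None = None,
                   fs: float | None = None) -> np.ndarray:
        if self.freqs is not None:
            return np.atleast_1d(np.asarray(self.freqs, dtype=float))
        low = max(band.low_hz, 1e-3)
        if n_samples is not None and fs is not None:
            f_min = self.min_resolvable_hz(n_samples, fs)
            if f_min < band.high_hz:
                low = max(low, f_min)
        return np.geomspace(low, band.high_hz, self.n_freqs)

    def smooth_samples(self, freq_hz: float, fs: float, n: int) -> int:
        """Smoothing-window length at one frequency, in samples."""
        by_scale = int(np.ceil(self.smooth_periods * fs / freq_hz))
        return int(np.clip(max(self.smooth_len, by_scale), 1, n))


# ---------------------------------------------------------------------------
# scalar / stack estimators


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must share a length >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero-variance input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _welch_matrix(stack: np.ndarray, fs: float, spec: SpectralParams):
    """Welch auto/cross spectra for a [C, T] channel stack.

    Returns (freqs, S) with S[i, j, f] the cross PSD of channels i and j.
    """
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    n = stack.shape[-1]
    if spec.n_subsegments(n) < 2:
        raise DegenerateEstimateError(
            f"need >= 2 Welch sub-segments (length {n}, nperseg "
            f"{spec.nperseg}); single-segment coherence is identically 1"
        )
    freqs, S = scipy.signal.csd(
        stack[:, None, :], stack[None, :, :], fs=fs, window=spec.window,
        nperseg=spec.nperseg, noverlap=spec.noverlap, detrend=spec.detrend,
        axis=-1,
    )
    return freqs, S


def band_bin_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    """Frequency bins used for band averaging.

    Bins whose center lies inside the band, DC excluded; if the grid is too
    coarse to place any center inside a narrow band, the single non-DC bin
    nearest the band center is used.
    """
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz) & (freqs > 0)
    if not mask.any():
        candidates = np.flatnonzero(freqs > 0)
        nearest = candidates[np.argmin(np.abs(freqs[candidates] - band.center_hz))]
        mask = np.zeros_like(mask)
        mask[nearest] = True
    return mask


def _coherency_matrix(stack: np.ndarray, fs: float, spec: SpectralParams):
    freqs, S = _welch_matrix(stack, fs, spec)
    auto = np.real(np.einsum("iif->if", S))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    denom = np.where(denom > 0, denom, np.inf)
    return freqs, S / denom


def msc(x: np.ndarray, y: np.ndarray, band: BandSpec = FULL,
        fs: float = 100.0, spec: SpectralParams | None = None) -> float:
    """Band-mean magnitude squared coherence in [0, 1]."""
    spec = spec or SpectralParams()
    freqs, C = _coherency_matrix(np.stack([x, y]), fs, spec)
    m = band_bin_mask(freqs, band)
    return float(np.mean(np.abs(C[0, 1, m]) ** 2))


def ipc(x: np.ndarray, y: np.ndarray, band: BandSpec = FULL,
        fs: float = 100.0, spec: SpectralParams | None = None) -> float:
    """Band-mean |imaginary part of coherency| in [0, 1]."""
    spec = spec or SpectralParams()
    freqs, C = _coherency_matrix(np.stack([x, y]), fs, spec)
    m = band_bin_mask(freqs, band)
    return float(np.mean(np.abs(np.imag(C[0, 1, m]))))


def morlet_cwt(stack: np.ndarray, freqs: np.ndarray, fs: float,
               w0: float = 6.0) -> np.ndarray:
    """Morlet continuous wavelet transform of a [C, T] stack.

    Returns complex coefficients [C, F, T].  The analysis kernel at
    frequency f has scale ``s = w0 / (2 pi f)``; edges use zero padding.
    """
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    C, T = stack.shape
    dt = 1.0 / fs
    out = np.empty((C, len(freqs), T), dtype=complex)
    for fi, f in enumerate(np.asarray(freqs, dtype=float)):
        s = w0 / (2 * np.pi * f)
        # kernel support: +-4 scales, capped at the signal length
        half = min(int(np.ceil(4 * s / dt)), T - 1)
        tau = np.arange(-half, half + 1) * dt
        psi = (np.pi ** -0.25) * np.exp(1j * w0 * tau / s - (tau / s) ** 2 / 2)
        kernel = np.conj(psi) * dt / np.sqrt(s)
        for c in range(C):
            # W(t) = sum_m x[t + m] kernel[m + half]; full correlation then
            # center slice (kernel may be longer than the signal)
            full = np.correlate(stack[c], np.conj(kernel), mode="full")
            out[c, fi] = full[half:half + T]
    return out


def _moving_average(z: np.ndarray, win: int) -> np.ndarray:
    """Moving average over the last axis, valid region only."""
    cs = np.cumsum(z, axis=-1)
    head = cs[..., win - 1:win]
    body = cs[..., win:] - cs[..., :-win]
    return np.concatenate([head, body], axis=-1) / win


def _wc_matrix(stack: np.ndarray, band: BandSpec, fs: float,
               wspec: WaveletSpec) -> np.ndarray:
    """Wavelet-coherence matrix [C, C] for a channel stack."""
    if wspec.smooth_len < 3:
        raise DegenerateEstimateError(
            "wavelet coherence needs time smoothing (smooth_len >= 3); "
            "unsmoothed coherence is identically 1"
        )
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    T = stack.shape[-1]
    if T < wspec.smooth_len:
        raise ValueError("segment shorter than the smoothing window")
    freqs = wspec.band_freqs(band, T, fs)
    Wx = morlet_cwt(stack, freqs, fs, wspec.center_freq_param)  # [C, F, T]
    cross = Wx[:, None] * np.conj(Wx[None, :])                  # [C, C, F, T]
    per_freq = []
    for fi, f in enumerate(freqs):
        win = wspec.smooth_samples(f, fs, T)
        sm = _moving_average(cross[:, :, fi], win)              # [C, C, Tv]
        auto = np.real(np.einsum("iit->it", sm))
        denom = np.sqrt(auto[:, None] * auto[None, :])
        wc = np.abs(sm) / np.where(denom > 0, denom, np.inf)
        per_freq.append(wc.mean(axis=-1))
    return np.mean(per_freq, axis=0)


def wavelet_coherence(x: np.ndarray, y: np.ndarray,
                      wspec: WaveletSpec | None = None,
                      band: BandSpec = FULL, fs: float = 100.0) -> float:
    """Time- and band-averaged Morlet wavelet coherence in [0, 1]."""
    wspec = wspec or WaveletSpec()
    return float(_wc_matrix(np.stack([x, y]), band, fs, wspec)[0, 1])


def instantaneous_phase(x: np.ndarray, dt: float) -> PhaseSeries:
    """Hilbert-transform instantaneous phase, ``atan2(hilbert(x), x)``."""
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("undefined phase: input is identically zero")
    analytic = scipy.signal.hilbert(x)
    return PhaseSeries(phi=np.angle(analytic),
                       analytic_imag=np.imag(analytic), dt=dt)


def _as_phi(p) -> np.ndarray:
    return p.phi if isinstance(p, PhaseSeries) else np.asarray(p, dtype=float)


def plv(phix, phiy) -> float:
    """Phase locking value: |mean exp(i (phi_x - phi_y))| in [0, 1]."""
    a, b = _as_phi(phix), _as_phi(phiy)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("phase series must share a length >= 2")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def pli(phix, phiy) -> float:
    """Phase lag index: |mean sign(phi_x - phi_y)| in [0, 1]."""
    a, b = _as_phi(phix), _as_phi(phiy)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("phase series must share a length >= 2")
    return float(np.abs(np.mean(np.sign(a - b))))


# ---------------------------------------------------------------------------
# adjacency assembly


@dataclass
class AdjacencyMatrix:
    """Nonnegative symmetric coupling matrix of one mini-epoch."""

    W: np.ndarray
    method: str
    band: BandSpec | None = None
    signed_raw: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")


def _phase_stack(X: np.ndarray, dt: float, phases: np.ndarray | None,
                 start: int) -> np.ndarray:
    """Per-channel phases for a window: sliced from full-epoch phases when
    available (Hilbert edges then fall outside the window), otherwise
    computed on the window itself."""
    if phases is not None:
        phases = np.asarray(phases, dtype=float)
        return phases[:, start:start + X.shape[1]]
    analytic = scipy.signal.hilbert(X, axis=1)
    return np.angle(analytic)


def adjacency(mini: MiniEpoch | np.ndarray, method: str,
              fs: float = 100.0, band: BandSpec | None = None,
              phases: np.ndarray | None = None,
              spec: SpectralParams | None = None,
              wspec: WaveletSpec | None = None) -> AdjacencyMatrix:
    """Adjacency matrix W of one mini-epoch under one FC method.

    ``W[i, j]`` is the measure between channels i and j for i != j, the
    diagonal is 0, and no threshold is applied.  For PC (and the signed
    coherency under IPC) the rectified |value| enters W while the signed
    matrix is retained in ``signed_raw``.  For PLV/PLI, ``phases`` may carry
    full-epoch instantaneous phases [n_channels, n_epoch_samples] to be
    sliced at the window offset, avoiding Hilbert edge effects on short
    windows.
    """
    method = method.upper()
    if method not in FC_METHODS:
        raise ValueError(f"unknown FC method {method!r}; known: {FC_METHODS}")
    if isinstance(mini, MiniEpoch):
        X = mini.X
        band = band or mini.band or FULL
        start = mini.start
    else:
        X = np.asarray(mini, dtype=float)
        band = band or FULL
        start = 0
    C = X.shape[0]
    signed = None

    if method == "PC":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = [i for i in range(C) if sd[i] == 0]
            raise ValueError(f"zero-variance channel(s) {bad}: PC undefined")
        signed = np.corrcoef(X)
        W = np.abs(signed)
    elif method in ("MSC", "IPC"):
        spec = spec or SpectralParams()
        try:
            freqs, Cxy = _coherency_matrix(X, fs, spec)
        except DegenerateEstimateError:
            raise
        m = band_bin_mask(freqs, band)
        if method == "MSC":
            W = np.mean(np.abs(Cxy[:, :, m]) ** 2, axis=-1)
        else:
            signed = np.mean(np.imag(Cxy[:, :, m]), axis=-1)
            W = np.mean(np.abs(np.imag(Cxy[:, :, m])), axis=-1)
    elif method == "WC":
        W = _wc_matrix(X, band, fs, wspec or WaveletSpec())
    else:  # PLV / PLI on instantaneous phases
        phi = _phase_stack(X, 1.0 / fs, phases, start)
        if method == "PLV":
            z = np.exp(1j * phi)
            W = np.abs(z @ np.conj(z).T) / phi.shape[1]
        else:
            diff = phi[:, None, :] - phi[None, :, :]
            W = np.abs(np.mean(np.sign(diff), axis=-1))

    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)  # exact symmetry against floating-point asymmetry
    if signed is not None:
        signed = np.array(signed, dtype=float)
    return AdjacencyMatrix(W=W, method=method, band=band, signed_raw=signed)


def epoch_adjacencies(rec_samples: np.ndarray, starts, window: int,
                      method: str, fs: float = 100.0,
                      band: BandSpec | None = None,
                      spec: SpectralParams | None = None,
                      wspec: WaveletSpec | None = None) -> np.ndarray:
    """Adjacency matrices for many windows of one epoch, stacked [n, C, C].

    For the phase measures the Hilbert transform runs once over the full
    epoch and per-window phases are sliced out, matching ``adjacency`` with
    a ``phases`` context.
    """
    method = method.upper()
    phases = None
    if method in ("PLV", "PLI"):
        phases = np.angle(scipy.signal.hilbert(rec_samples, axis=1))
    out = []
    for s in starts:
        Xw = rec_samples[:, s:s + window]
        out.append(adjacency(Xw, method, fs=fs, band=band,
                             phases=None if phases is None else phases[:, s:s + window],
                             spec=spec, wspec=wspec).W)
    return np.stack(out)
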