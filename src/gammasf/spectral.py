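"""Multitaper spectral estimation and spike-field coherence.

Power spectra are estimated with Slepian (DPSS) tapers, default
time-bandwidth product 3 with 5 tapers, over the 300–2000 ms post-onset
stimulus window.  Coherence pools cross- and auto-spectra over tapers and
trials; a trial-shuffle control (spike trains permuted against LFPs within
each stimulus condition) separates genuine phase consistency from power
effects.  Phase-locking profiles bin spikes by the instantaneous phase of
the band-passed LFP (Hilbert transform) and report the modulation index
(max rate - mean rate) / mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, hilbert
from scipy.signal.windows import dpss

DEFAULT_NW = 3.0
DEFAULT_K = 5
#: Analysis window, seconds relative to stimulus onset.
DEFAULT_WINDOW = (0.3, 2.0)


@dataclass
class SpectrumGrid:
    """Trial-averaged power over the SF x frequency grid.

    ``power`` is (n_sfs, n_freqs); ``blank_power`` is the mean spectrum of
    blank (no-stimulus) trials; ``per_trial_power`` optionally keeps the
    single-trial spectra, shape (n_sfs, n_trials, n_freqs).
    """

    frequencies: np.ndarray
    sfs: np.ndarray
    power: np.ndarray
    blank_power: np.ndarray | None = None
    per_trial_power: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.sfs = np.asarray(self.sfs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.sfs.size, self.frequencies.size):
            raise ValueError("power must be (n_sfs, n_freqs)")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")


@dataclass
class CoherenceResult:
    frequencies: np.ndarray
    coherence: np.ndarray
    shuffle_coherence: np.ndarray | None
    n_trials: int
    nw: float
    k: int
    n_excluded: int = 0


def _window_slice(n_samples: int, rate: float, window: tuple[float, float] | None):
    if window is None:
        return slice(0, n_samples)
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate))
    if i0 < 0 or i1 > n_samples or i1 <= i0:
        raise ValueError(f"window {window} outside the trial")
    return slice(i0, i1)


def _taper_ffts(x: np.ndarray, rate: float, nw: float, k: int):
    """Tapered FFTs of demeaned trials: returns (freqs, Y[trial, taper, freq])."""
    if k > 2 * nw - 1:
        raise ValueError(f"k={k} exceeds 2*nw-1={2 * nw - 1}")
    n = x.shape[-1]
    tapers = dpss(n, nw, Kmax=k)  # unit-energy Slepian sequences
    xd = x - x.mean(axis=-1, keepdims=True)
    y = np.fft.rfft(xd[:, None, :] * tapers[None, :, :], axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, y


def multitaper_psd(
    x: np.ndarray,
    rate: float,
    window: tuple[float, float] | None = None,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
):
    """Multitaper PSD of each trial and the trial mean.

    Parameters
    ----------
    x : (n_trials, n_samples) array
    rate : sampling rate, Hz
    window : (t0, t1) seconds relative to the start of ``x``; None = all.

    Returns ``(frequencies, per_trial_psd, mean_psd)``; one-sided density so
    that ``sum(psd) * df`` approximates the signal variance in the window.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sl = _window_slice(x.shape[-1], rate, window)
    freqs, y = _taper_ffts(x[:, sl], rate, nw, k)
    n = sl.stop - sl.start
    s = (np.abs(y) ** 2) / rate
    s *= 2.0
    s[..., 0] /= 2.0
    if n % 2 == 0:
        s[..., -1] /= 2.0
    per_trial = s.mean(axis=1)
    return freqs, per_trial, per_trial.mean(axis=0)


def _pooled_coherence(yx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    sxy = np.sum(yx * np.conj(yy), axis=(0, 1))
    sxx = np.sum(np.abs(yx) ** 2, axis=(0, 1))
    syy = np.sum(np.abs(yy) ** 2, axis=(0, 1))
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / denom
    return np.where(denom > 0, coh, 0.0)


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    window: tuple[float, float] | None = None,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> CoherenceResult:
    """Field-field coherence |S_xy| / sqrt(S_xx S_yy), pooled over tapers
    and trials.  A single trial with a single taper is degenerate
    (coherence identically 1) and rejected."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have identical (trials, samples) shapes")
    if x.shape[0] * k < 2:
        raise ValueError("coherence needs more than one trial-taper product")
    sl = _window_slice(x.shape[-1], rate, window)
    freqs, yx = _taper_ffts(x[:, sl], rate, nw, k)
    _, yy = _taper_ffts(y[:, sl], rate, nw, k)
    coh = _pooled_coherence(yx, yy)
    return CoherenceResult(freqs, coh, None, x.shape[0], nw, k)


def bin_spikes(
    spikes: Sequence[Sequence[float]], n_samples: int, rate: float
) -> np.ndarray:
    """Binarize per-trial spike-time lists at the LFP sampling rate."""
    out = np.zeros((len(spikes), n_samples))
    for i, tr in enumerate(spikes):
        idx = np.floor(np.asarray(tr, dtype=float) * rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_samples)]
        np.add.at(out[i], idx, 1.0)
    return out


def spike_field_coherence(
    spikes: Sequence[Sequence[float]],
    lfp: np.ndarray,
    rate: float,
    window: tuple[float, float] | None = None,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> CoherenceResult:
    """Coherence between the binned spike point process and the LFP.

    Trials with no spikes inside the window are excluded (their spike
    spectrum is undefined after mean subtraction); the exclusion count is
    recorded on the result.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if len(spikes) != lfp.shape[0]:
        raise ValueError("spike trial count does not match LFP trial count")
    binned = bin_spikes(spikes, lfp.shape[-1], rate)
    sl = _window_slice(lfp.shape[-1], rate, window)
    keep = binned[:, sl].sum(axis=-1) > 0
    if not np.any(keep):
        raise ValueError("no trials with spikes inside the analysis window")
    res = coherence(binned[keep], lfp[keep], rate, window, nw, k)
    res.n_excluded = int(np.sum(~keep))
    return res


def shuffle_control(
    spikes: Sequence[Sequence[float]],
    lfp: np.ndarray,
    conditions: Sequence,
    rate: float,
    n_shuffles: int = 10,
    seed: int = 0,
    window: tuple[float, float] | None = None,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> np.ndarray:
    """Mean SFC over ``n_shuffles`` permutations of spike-trial identity
    within each stimulus condition (LFP trials stay in place)."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    conditions = np.asarray(conditions, dtype=object)
    groups = [np.flatnonzero(conditions == c) for c in dict.fromkeys(conditions.tolist())]
    for g in groups:
        if g.size < 2:
            raise ValueError("each condition needs >= 2 trials to permute")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_shuffles):
        perm = np.arange(len(spikes))
        for g in groups:
            perm[g] = g[rng.permutation(g.size)]
        res = spike_field_coherence([spikes[i] for i in perm], lfp, rate, window, nw, k)
        acc = res.coherence if acc is None else acc + res.coherence
    return acc / n_shuffles


def band_phase(
    lfp: np.ndarray, rate: float, center: float, half_width: float = 4.0
) -> np.ndarray:
    """Instantaneous phase of the LFP band-passed around ``center`` Hz
    (zero-phase Butterworth, then analytic-signal angle)."""
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    lo = max(center - half_width, 0.5)
    hi = min(center + half_width, rate / 2 - 0.5)
    b, a = butter(3, [lo / (rate / 2), hi / (rate / 2)], btype="band")
    filtered = filtfilt(b, a, lfp, axis=-1)
    return np.angle(hilbert(filtered, axis=-1))


def phase_locking_profile(
    lfp: np.ndarray,
    spikes: Sequence[Sequence[float]],
    rate: float,
    band_centers: Sequence[float],
    half_width: float = 4.0,
    n_bins: int = 16,
    window: tuple[float, float] | None = None,
):
    """Firing rate as a function of LFP phase, per frequency band.

    For each band center: band-pass the LFP, take the Hilbert phase, bin
    spike phases into ``n_bins`` equal bins over (-pi, pi], and normalize
    each bin's spike count by its phase occupancy.  Returns
    ``(phase_at_peak_rate, locking_index)`` arrays over bands, where the
    locking index is (max rate - mean rate) / mean rate — zero iff the rate
    is identical in every phase bin, and equal to the modulation depth m for
    a rate r0 (1 + m cos phi).
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    binned = bin_spikes(spikes, lfp.shape[-1], rate)
    sl = _window_slice(lfp.shape[-1], rate, window)
    if binned[:, sl].sum() == 0:
        raise ValueError("no spikes inside the analysis window")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    peak_phase = np.empty(len(band_centers))
    index = np.empty(len(band_centers))
    for bi, center in enumerate(band_centers):
        phase = band_phase(lfp, rate, center, half_width)[:, sl]
        counts = binned[:, sl]
        which = np.clip(np.digitize(phase.ravel(), edges) - 1, 0, n_bins - 1)
        spk = np.bincount(which, weights=counts.ravel(), minlength=n_bins)
        occ = np.bincount(which, minlength=n_bins) / rate
        with np.errstate(invalid="ignore", divide="ignore"):
            rate_by_phase = np.where(occ > 0, spk / np.maximum(occ, 1e-300), 0.0)
        mean_rate = float(rate_by_phase.mean())
        if mean_rate == 0:
            raise ValueError("zero mean firing rate")
        index[bi] = (rate_by_phase.max() - mean_rate) / mean_rate
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak_phase[bi] = centers[int(np.argmax(rate_by_phase))]
    return peak_phase, index


def spectrum_grid(
    recording,
    window: tuple[float, float] = DEFAULT_WINDOW,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
    keep_trials: bool = False,
) -> SpectrumGrid:
    """Build a :class:`SpectrumGrid` from a grating-SF recording.

    ``window`` is relative to stimulus onset; the recording's pre-stimulus
    epoch length shifts it to trace time.  Blank trials (condition
    ``"blank"``) supply the blank spectrum over the same-length window.
    """
    abs_window = (recording.pre + window[0], recording.pre + window[1])
    sf_vals = sorted({c for c in recording.conditions if not isinstance(c, str)})
    if not sf_vals:
        raise ValueError("recording has no spatial-frequency conditions")
    conds = np.asarray(recording.conditions, dtype=object)
    per_sf = []
    per_trial_all = []
    freqs = None
    for sf in sf_vals:
        idx = np.flatnonzero(conds == sf)
        freqs, per_trial, mean_psd = multitaper_psd(
            recording.lfp[idx], recording.rate, abs_window, nw, k
        )
        per_sf.append(mean_psd)
        per_trial_all.append(per_trial)
    blank_idx = np.flatnonzero(conds == "blank")
    blank = None
    if blank_idx.size:
        _, _, blank = multitaper_psd(recording.lfp[blank_idx], recording.rate, abs_window, nw, k)
    keep = freqs > 0  # DC is meaningless after per-trial demeaning
    return SpectrumGrid(
        frequencies=freqs[keep],
        sfs=np.asarray(sf_vals, dtype=float),
        power=np.asarray(per_sf)[:, keep],
        blank_power=None if blank is None else blank[keep],
        per_trial_power=np.asarray(per_trial_all)[:, :, keep] if keep_trials else None,
    )
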