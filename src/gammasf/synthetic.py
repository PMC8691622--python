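"""Synthetic recordings with known ground truth.

Every downstream stage of the pipeline (spectral decomposition, tuning
metrics, laminar localization, edge/surface decoding) is exercised against
data generated here, so each has a recoverable answer.

LFP traces are synthesized in the frequency domain — complex-Gaussian
coefficients scaled so the expected one-sided PSD equals the descriptive
model spectrum — which guarantees that the multitaper estimate of many
trials converges to the generating model, the property the fitting stage
assumes.  Spikes are inhomogeneous Poisson processes whose rate is
modulated by the instantaneous phase of a chosen gamma component,
``r(t) = r0 (1 + m cos phi(t))`` with modulation depth ``m`` in [0, 1].

The default ground truth mirrors the reported physiology: the low-gamma
(LG) component is band-pass in SF and prefers high SF (cutoff ~0.68 cpd,
selectivity ~0.77), the medium gamma (MG) is intermediate (~0.33, ~0.54),
and the high gamma (HG) is low-pass (~0.09, selectivity near 0); LG's peak
frequency declines from 35 to 25 Hz with increasing SF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    BaselineParams,
    COMPONENT_LABELS,
    ComponentParams,
    DEFAULT_BAND_WINDOWS,
    ModelParams,
    eval_baseline,
    eval_model,
    eval_weight,
    scale_amplitudes,
)
from .spectral import band_phase

PRESETS = ("three_gamma_default", "lg_only", "no_gamma", "laminar", "edge_surface")

#: Default SF sampling: 10 grating conditions, log-spaced (cycles/degree).
DEFAULT_SFS = tuple(np.geomspace(0.03, 2.5, 10).round(4))

DEFAULT_RATE = 500.0
DEFAULT_EPOCHS = (0.4, 2.0, 0.4)  # pre, stimulus, post (seconds)


@dataclass
class Recording:
    """Multi-trial recording from one site.

    ``conditions`` holds one label per trial: a float SF in cycles/degree
    for grating trials, or one of the strings ``"blank"``, ``"edge"``,
    ``"surface"``.
    """

    lfp: np.ndarray  # (n_trials, n_samples), microvolts
    rate: float
    conditions: list
    spikes: list | None = None
    pre: float = DEFAULT_EPOCHS[0]
    stim: float = DEFAULT_EPOCHS[1]
    post: float = DEFAULT_EPOCHS[2]
    site_id: str = "site0"
    depth_mm: float | None = None
    region: str = "V1"

    def __post_init__(self) -> None:
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=float))
        expected = int(round(self.rate * (self.pre + self.stim + self.post)))
        if self.lfp.shape[1] != expected:
            raise ValueError(
                f"sample count {self.lfp.shape[1]} != rate x duration = {expected}"
            )
        if len(self.conditions) != self.lfp.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.spikes is not None:
            if len(self.spikes) != self.lfp.shape[0]:
                raise ValueError("one spike list per trial required")
            dur = self.pre + self.stim + self.post
            for tr in self.spikes:
                t = np.asarray(tr, dtype=float)
                if t.size and (t.min() < 0 or t.max() > dur):
                    raise ValueError("spike times outside trial bounds")

    @property
    def duration(self) -> float:
        return self.pre + self.stim + self.post


@dataclass
class GroundTruth:
    """Known generating parameters for the synthetic world."""

    model_params: ModelParams
    lock_targets: dict = field(
        default_factory=lambda: {"LG": 0.8, "MG": 0.8, "HG": 0.8}
    )
    laminar_profiles: dict = field(
        default_factory=lambda: {
            "LG": (0.2, 0.12, 1.0),
            "MG": (0.4, 0.12, 1.0),
            "HG": (0.5, 0.12, 1.0),
        }
    )
    edge_surface_effects: dict = field(
        default_factory=lambda: {
            "gamma_diff": {"LG": 1.0, "MG": -1.0, "HG": -1.0},
            "gamma_sd": 1.0,
            "mua_diff": 1.5,
            "mua_sd": 5.0,
            "mua_base_rate": 20.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for lab, m in self.lock_targets.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"lock target m for {lab} must be in [0, 1]")
        if self.edge_surface_effects["gamma_sd"] <= 0 or self.edge_surface_effects["mua_sd"] <= 0:
            raise ValueError("trial noise SDs must be positive")
        for lab, (peak, width, _) in self.laminar_profiles.items():
            if not 0.0 <= peak <= 1.0:
                raise ValueError(f"laminar profile for {lab} peaks outside [0, 1] ReD")
            if width <= 0:
                raise ValueError("laminar profile width must be positive")


# Difference-of-Gaussians SF-profile shapes (A1-normalized) solved so that
# the tuning metrics at the default SF sampling match the reported values:
# cutoff SF 0.68 / 0.33 / 0.09 cpd, SF selectivity 0.77 / 0.54 / ~0.
_SHAPES = {
    "LG": dict(sigma1=0.4716, a2_frac=0.8522, sigma2=0.15),
    "MG": dict(sigma1=0.2014, a2_frac=0.7864, sigma2=0.10),
    "HG": dict(sigma1=0.0764, a2_frac=0.0, sigma2=0.01),
}
# Peak-frequency sigmoids: LG declines 35 -> 25 Hz with SF; MG and HG sit
# inside their band windows.
_MU = {
    "LG": dict(K0=35.0, K=-10.0, n=2.0),
    "MG": dict(K0=50.0, K=8.0, n=2.0),
    "HG": dict(K0=72.0, K=8.0, n=2.0),
}
_SIGMA_F = {"LG": 4.0, "MG": 5.0, "HG": 6.0}
_BASELINE = BaselineParams(k=2.0e4, a=2.0, b=0.0, c=0.5)
_SF0 = 0.3


def _component(label: str, amplitude: float) -> ComponentParams:
    s = _SHAPES[label]
    return ComponentParams(
        label=label,
        sigma=_SIGMA_F[label],
        A1=amplitude,
        sigma1=s["sigma1"],
        A2=amplitude * s["a2_frac"],
        sigma2=s["sigma2"],
        **_MU[label],
    )


def _default_model(active: Sequence[str], target_snr: float) -> ModelParams:
    """Model with active components' amplitudes scaled to a per-component
    SNR (max weight over SF / mean blank-band baseline power) of
    ``target_snr``."""
    comps = tuple(
        _component(lab, 1.0 if lab in active else 0.0) for lab in COMPONENT_LABELS
    )
    params = ModelParams(baseline=_BASELINE, components=comps, sf0=_SF0)
    sf_grid = np.linspace(0.0, 2.5, 2001)
    factors = []
    for comp in params.components:
        if comp.A1 == 0:
            factors.append(1.0)
            continue
        lo, hi = params.band_windows[comp.label]
        f_band = np.linspace(lo, hi, 200)
        blank_mean = float(np.mean(eval_baseline(params.baseline, f_band)))
        max_w = float(np.max(eval_weight(comp, sf_grid)))
        factors.append(target_snr * blank_mean / max_w)
    return scale_amplitudes(params, factors)


def make_ground_truth(preset: str, seed: int = 0, target_snr: float = 6.0) -> GroundTruth:
    """Ground truth for a named preset.

    Presets: ``three_gamma_default`` (all three components at component SNR
    ``target_snr``), ``lg_only``, ``no_gamma`` (baseline only),
    ``laminar`` (adds depth profiles peaking at ReD 0.2/0.4/0.5 for
    LG/MG/HG), ``edge_surface`` (adds class contrasts: LG log-power higher
    at the edge, MG/HG higher on the surface, MUA contrast smaller).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    active = {
        "three_gamma_default": ("LG", "MG", "HG"),
        "lg_only": ("LG",),
        "no_gamma": (),
        "laminar": ("LG", "MG", "HG"),
        "edge_surface": ("LG", "MG", "HG"),
    }[preset]
    return GroundTruth(model_params=_default_model(active, target_snr), seed=seed)


def _colored_noise(rng: np.random.Generator, psd: np.ndarray, n: int, rate: float) -> np.ndarray:
    """One real trace of length n whose expected one-sided PSD is ``psd``
    (given at the rfft frequencies)."""
    scale = np.sqrt(psd * rate * n / 4.0)
    x = scale * (rng.standard_normal(psd.size) + 1j * rng.standard_normal(psd.size))
    x[0] = 0.0
    if n % 2 == 0:
        x[-1] = np.sqrt(psd[-1] * rate * n / 2.0) * rng.standard_normal()
    return np.fft.irfft(x, n)


def _target_psd(gt: GroundTruth, sf, freqs: np.ndarray) -> np.ndarray:
    """Model PSD at the rfft frequency grid (DC excluded -> zero)."""
    psd = np.zeros_like(freqs)
    if sf is None:  # blank: baseline only
        psd[1:] = eval_baseline(gt.model_params.baseline, freqs[1:])
    else:
        psd[1:] = eval_model(gt.model_params, float(sf), freqs[1:])[0]
    return psd


def simulate_lfp_trial(
    gt: GroundTruth,
    sf: float | None,
    duration: float = 2.0,
    rate: float = DEFAULT_RATE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One stationary LFP trace whose expected multitaper PSD equals the
    model spectrum at ``sf`` (baseline only for ``sf=None``)."""
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if rng is None:
        rng = np.random.default_rng(gt.seed if seed is None else seed)
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return _colored_noise(rng, _target_psd(gt, sf, freqs), n, rate)


def simulate_recording(
    gt: GroundTruth,
    sfs: Sequence[float] = DEFAULT_SFS,
    n_trials: int = 20,
    n_blank: int = 20,
    rate: float = DEFAULT_RATE,
    epochs: tuple[float, float, float] = DEFAULT_EPOCHS,
    seed: int = 0,
    site_id: str = "site0",
) -> Recording:
    """A full grating-SF session: ``n_trials`` trials per SF condition plus
    ``n_blank`` blank trials, each pre/stimulus/post structured (baseline
    statistics outside the stimulus epoch)."""
    rng = np.random.default_rng(seed)
    pre, stim, post = epochs
    n_pre, n_stim, n_post = (int(round(e * rate)) for e in epochs)
    f_pre = np.fft.rfftfreq(n_pre, d=1.0 / rate) if n_pre else None
    f_stim = np.fft.rfftfreq(n_stim, d=1.0 / rate)
    f_post = np.fft.rfftfreq(n_post, d=1.0 / rate) if n_post else None
    base_pre = _target_psd(gt, None, f_pre) if n_pre else None
    base_post = _target_psd(gt, None, f_post) if n_post else None

    traces, conditions = [], []
    for sf in sfs:
        psd = _target_psd(gt, sf, f_stim)
        for _ in range(n_trials):
            parts = []
            if n_pre:
                parts.append(_colored_noise(rng, base_pre, n_pre, rate))
            parts.append(_colored_noise(rng, psd, n_stim, rate))
            if n_post:
                parts.append(_colored_noise(rng, base_post, n_post, rate))
            traces.append(np.concatenate(parts))
            conditions.append(float(sf))
    psd_blank = _target_psd(gt, None, np.fft.rfftfreq(n_pre + n_stim + n_post, d=1.0 / rate))
    for _ in range(n_blank):
        traces.append(_colored_noise(rng, psd_blank, n_pre + n_stim + n_post, rate))
        conditions.append("blank")
    return Recording(
        lfp=np.asarray(traces), rate=rate, conditions=conditions,
        pre=pre, stim=stim, post=post, site_id=site_id,
    )


def simulate_spikes(
    gt: GroundTruth,
    lfp: np.ndarray,
    component: str,
    base_rate: float = 20.0,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    m: float | None = None,
    sf: float | None = None,
    half_width: float = 4.0,
) -> list[np.ndarray]:
    """Inhomogeneous Poisson spikes phase-locked to one gamma component.

    Each LFP trial is band-passed around the component's peak frequency
    (its value at stimulus spatial frequency ``sf`` when given, else the
    band-window midpoint; ``half_width`` Hz to each side, matching the
    phase-locking measurement convention), the Hilbert phase phi(t)
    extracted, and spikes drawn by thinning at rate
    ``base_rate * (1 + m cos phi(t))`` with ``m = gt.lock_targets[component]``
    unless overridden.
    """
    from .model import eval_mu

    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if component not in COMPONENT_LABELS:
        raise ValueError(f"unknown component {component!r}")
    m = gt.lock_targets[component] if m is None else m
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation depth m must be in [0, 1]")
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    lo, hi = gt.model_params.band_windows[component]
    if sf is None:
        center = 0.5 * (lo + hi)
    else:
        center = eval_mu(gt.model_params.component(component), gt.model_params.sf0, sf)
    phase = band_phase(lfp, rate, center, half_width)
    rng = np.random.default_rng(seed)
    duration = lfp.shape[1] / rate
    lam_max = base_rate * (1.0 + m)
    out = []
    for ph in phase:
        n_cand = rng.poisson(lam_max * duration)
        t = np.sort(rng.uniform(0.0, duration, n_cand))
        idx = np.minimum((t * rate).astype(int), lfp.shape[1] - 1)
        r = base_rate * (1.0 + m * np.cos(ph[idx]))
        out.append(t[rng.uniform(0.0, lam_max, n_cand) < r])
    return out


@dataclass
class LaminarSession:
    """One linear-array penetration: channel geometry plus the per-channel
    statistics the laminar alignment consumes."""

    session_id: str
    depths_mm: np.ndarray  # increasing with channel index (shallow -> deep)
    true_red: np.ndarray
    mua_snr: np.ndarray
    sf_selectivity: np.ndarray
    band_power: np.ndarray  # (3, n_channels), LG/MG/HG order
    recordings: list[Recording] | None = None
    true_anchors: tuple[int, int, int] | None = None


def _laminar_gain(gt: GroundTruth, label: str, red: float) -> float:
    peak, width, amp = gt.laminar_profiles[label]
    return amp * float(np.exp(-((red - peak) ** 2) / (2 * width**2)))


def simulate_laminar_session(
    gt: GroundTruth,
    n_channels: int = 24,
    spacing: float = 0.1,
    seed: int = 0,
    noise_sd: float = 0.1,
    with_lfp: bool = False,
    n_trials: int = 10,
    sfs: Sequence[float] | None = None,
    session_id: str = "session0",
) -> LaminarSession:
    """One laminar penetration with known depth structure.

    Channels 1 .. n-2 (0-based) lie inside cortex with MUA SNR > 3; the
    first and last channels are outside.  Band powers follow the ground
    truth's Gaussian ReD profiles with multiplicative log-normal noise of
    SD ``noise_sd`` (0 = noiseless).  ``with_lfp=True`` additionally
    simulates per-channel Recordings whose component amplitudes are scaled
    by the laminar gain at that channel's true ReD.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    depths = 0.05 + spacing * np.arange(n_channels)
    cha2, cha3 = 1, n_channels - 2
    surface = depths[cha2] - 0.05
    wm = depths[cha3] + 0.05
    true_red = np.clip((depths - surface) / (wm - surface), 0.0, 1.0)

    in_cortex = np.zeros(n_channels, dtype=bool)
    in_cortex[cha2 : cha3 + 1] = True
    mua_snr = np.where(in_cortex, 6.0, 1.0) + 0.3 * rng.standard_normal(n_channels)
    mua_snr = np.clip(mua_snr, 0.1, None)
    mua_snr[~in_cortex] = np.minimum(mua_snr[~in_cortex], 2.5)
    mua_snr[in_cortex] = np.maximum(mua_snr[in_cortex], 3.5)

    sf_selectivity = 0.1 + 1.5 * np.abs(true_red - 0.5) + 0.02 * rng.standard_normal(n_channels)
    cha1 = int(np.argmin(np.abs(true_red - 0.5)))
    sf_selectivity[cha1] = min(sf_selectivity.min() - 0.05, 0.05)

    band_power = np.empty((3, n_channels))
    for bi, lab in enumerate(COMPONENT_LABELS):
        clean = np.array([_laminar_gain(gt, lab, r) for r in true_red]) + 0.05
        band_power[bi] = clean * np.exp(noise_sd * rng.standard_normal(n_channels))

    recordings = None
    if with_lfp:
        if sfs is None:
            sfs = DEFAULT_SFS
        recordings = []
        for ch in range(n_channels):
            gains = [max(_laminar_gain(gt, lab, true_red[ch]), 1e-3) for lab in COMPONENT_LABELS]
            gt_ch = GroundTruth(
                model_params=scale_amplitudes(gt.model_params, gains),
                lock_targets=gt.lock_targets,
                laminar_profiles=gt.laminar_profiles,
                edge_surface_effects=gt.edge_surface_effects,
                seed=gt.seed,
            )
            rec = simulate_recording(
                gt_ch, sfs=sfs, n_trials=n_trials, n_blank=n_trials,
                seed=int(rng.integers(2**31)), site_id=f"{session_id}-ch{ch}",
            )
            rec.depth_mm = float(depths[ch])
            recordings.append(rec)

    return LaminarSession(
        session_id=session_id, depths_mm=depths, true_red=true_red,
        mua_snr=mua_snr, sf_selectivity=sf_selectivity, band_power=band_power,
        recordings=recordings, true_anchors=(cha1, cha2, cha3),
    )


def simulate_edge_surface(
    gt: GroundTruth, n_sites: int = 1, n_trials: int = 1000, seed: int = 0
):
    """Edge-vs-surface feature matrices for the decoder.

    Returns a (gamma, mua) pair of :class:`~gammasf.decoder.DecodeDataset`.
    Gamma features are per-site log band powers drawn Gaussian in log space
    with the configured edge - surface mean differences (LG positive,
    MG/HG negative); MUA features are three time-binned mean rates with a
    smaller class contrast.  Classes are exactly balanced.
    """
    from .decoder import DecodeDataset  # local import to avoid a cycle

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_trials % 2:
        raise ValueError("n_trials must be even (balanced classes)")
    eff = gt.edge_surface_effects
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    y = np.concatenate([np.ones(half), np.zeros(half)])  # edge=1, surface=0
    sign = np.where(y == 1, 0.5, -0.5)

    # log mean power per band at each band's preferred SF, as feature offsets
    sf_grid = np.linspace(0.0, 2.5, 501)
    base_log = []
    for comp in gt.model_params.components:
        w = np.max(eval_weight(comp, sf_grid))
        lo, hi = gt.model_params.band_windows[comp.label]
        b = np.mean(eval_baseline(gt.model_params.baseline, np.linspace(lo, hi, 50)))
        base_log.append(np.log(w + b + 1e-12))

    xg = np.empty((n_trials, 3 * n_sites))
    xm = np.empty((n_trials, 3 * n_sites))
    for s in range(n_sites):
        for bi, lab in enumerate(COMPONENT_LABELS):
            col = 3 * s + bi
            diff = eff["gamma_diff"][lab] * eff["gamma_sd"]
            xg[:, col] = (
                base_log[bi] + sign * diff
                + eff["gamma_sd"] * rng.standard_normal(n_trials)
            )
        for bi in range(3):
            col = 3 * s + bi
            diff = eff["mua_diff"]
            xm[:, col] = (
                eff["mua_base_rate"] + sign * diff
                + eff["mua_sd"] * rng.standard_normal(n_trials)
            )
    perm = rng.permutation(n_trials)
    sites = [f"site{s}" for s in range(n_sites)]
    return (
        DecodeDataset(X=xg[perm], y=y[perm], feature_kind="gamma", site_ids=sites),
        DecodeDataset(X=xm[perm], y=y[perm], feature_kind="mua", site_ids=sites),
    )
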