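"""Two-dimensional descriptive model of stimulus-driven LFP power spectra.

The power spectrum recorded at one site, as a function of stimulus spatial
frequency (SF, cycles/degree) and oscillatory frequency (f, Hz), is modeled
as an aperiodic 1/f-like baseline plus three narrowband gamma components
(low/medium/high gamma, LG/MG/HG)::

    Power(SF, f) = Baseline(f) + sum_i W_i(SF) * exp(-(f - mu_i(SF))^2 / (2 sigma_i^2))

with

* ``Baseline(f) = k / (f^a + b) + c`` — monotonically decreasing in f,
* ``mu_i(SF) = K0_i + K_i * SF^n_i / (SF^n_i + SF0^n_i)`` — a Naka–Rushton
  (sigmoid) dependence of each component's peak frequency on SF,
* ``W_i(SF) = A1_i exp(-SF^2/(2 s1_i^2)) - A2_i exp(-SF^2/(2 s2_i^2))`` —
  a difference-of-Gaussians SF amplitude profile, floored at zero.

Fitting is bounded nonlinear least squares on the trial-averaged SF x f
power grid, with multiple seeded restarts.  Components whose fitted peak
weight exceeds three times the mean blank-condition power in their band are
counted as present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

COMPONENT_LABELS = ("LG", "MG", "HG")

#: Default component band windows in Hz (low, medium, high gamma).
DEFAULT_BAND_WINDOWS: dict[str, tuple[float, float]] = {
    "LG": (25.0, 45.0),
    "MG": (45.0, 65.0),
    "HG": (65.0, 100.0),
}

DEFAULT_SNR_THRESHOLD = 3.0


@dataclass(frozen=True)
class BaselineParams:
    """Aperiodic baseline ``k / (f^a + b) + c``."""

    k: float
    a: float
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.a <= 0 or self.b < 0 or self.c < 0:
            raise ValueError(
                "baseline requires k >= 0, a > 0, b >= 0, c >= 0 "
                f"(got k={self.k}, a={self.a}, b={self.b}, c={self.c})"
            )


@dataclass(frozen=True)
class ComponentParams:
    """One narrowband gamma component.

    ``sigma`` is the spectral (Hz) bandwidth of the Gaussian bump; ``K0``
    and ``K`` place the peak-frequency sigmoid (value K0 at SF=0, K0+K in
    the high-SF limit); ``n`` is the Hill exponent; ``A1, sigma1, A2,
    sigma2`` parameterize the difference-of-Gaussians SF amplitude profile.
    """

    label: str
    sigma: float
    K0: float
    K: float
    n: float
    A1: float
    sigma1: float
    A2: float = 0.0
    sigma2: float = 1e-2

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise ValueError(f"unknown component label {self.label!r}")
        if self.sigma <= 0 or self.n <= 0 or self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma, n, sigma1, sigma2 must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("component amplitudes A1, A2 must be non-negative")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: baseline, three components, shared SF0."""

    baseline: BaselineParams
    components: tuple[ComponentParams, ComponentParams, ComponentParams]
    sf0: float
    band_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WINDOWS)
    )

    def __post_init__(self) -> None:
        if len(self.components) != 3:
            raise ValueError("exactly three components (LG, MG, HG) required")
        if tuple(c.label for c in self.components) != COMPONENT_LABELS:
            raise ValueError("components must be ordered (LG, MG, HG)")
        if self.sf0 <= 0:
            raise ValueError("sf0 must be positive")
        edges = [self.band_windows[lab] for lab in COMPONENT_LABELS]
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            if lo1 >= hi1 or lo2 >= hi2 or hi1 > lo2 + 1e-9:
                raise ValueError("band windows must be ordered and non-overlapping")

    def component(self, label: str) -> ComponentParams:
        return self.components[COMPONENT_LABELS.index(label)]


def eval_baseline(p: BaselineParams, f) -> np.ndarray | float:
    """Baseline power ``k / (f^a + b) + c`` at frequency ``f`` (Hz, > 0)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("baseline is defined for f > 0 only")
    out = p.k / (np.power(f, p.a) + p.b) + p.c
    return out if out.ndim else float(out)


def eval_mu(comp: ComponentParams, sf0: float, sf) -> np.ndarray | float:
    """Peak frequency (Hz) of a component at spatial frequency ``sf``."""
    sf = np.asarray(sf, dtype=float)
    if np.any(sf < 0):
        raise ValueError("spatial frequency must be non-negative")
    sfn = np.power(sf, comp.n)
    out = comp.K0 + comp.K * sfn / (sfn + sf0**comp.n)
    return out if out.ndim else float(out)


def eval_weight(comp: ComponentParams, sf, floor: bool = True) -> np.ndarray | float:
    """Difference-of-Gaussians SF amplitude profile of a component.

    Floored at zero by default: a negative spectral bump is unphysical, but
    the raw (unfloored) value is available for diagnostics via
    ``floor=False``.
    """
    sf = np.asarray(sf, dtype=float)
    if np.any(sf < 0):
        raise ValueError("spatial frequency must be non-negative")
    out = comp.A1 * np.exp(-(sf**2) / (2 * comp.sigma1**2)) - comp.A2 * np.exp(
        -(sf**2) / (2 * comp.sigma2**2)
    )
    if floor:
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def eval_model(p: ModelParams, sf, f) -> np.ndarray:
    """Model power on the outer grid of ``sf`` (rows) x ``f`` (columns)."""
    sf = np.atleast_1d(np.asarray(sf, dtype=float))
    f = np.atleast_1d(np.asarray(f, dtype=float))
    out = np.broadcast_to(eval_baseline(p.baseline, f), (sf.size, f.size)).copy()
    for comp in p.components:
        w = np.asarray(eval_weight(comp, sf))[:, None]
        mu = np.asarray(eval_mu(comp, p.sf0, sf))[:, None]
        out += w * np.exp(-((f[None, :] - mu) ** 2) / (2 * comp.sigma**2))
    return out


def goodness_of_fit(data, prediction) -> float:
    """``1 - SS_res / SS_tot`` over the flattened grid (<= 1; 1 iff exact)."""
    data = np.asarray(data, dtype=float).ravel()
    prediction = np.asarray(prediction, dtype=float).ravel()
    if data.shape != prediction.shape:
        raise ValueError("data and prediction shapes differ")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("goodness of fit undefined for constant data")
    return 1.0 - float(np.sum((data - prediction) ** 2)) / ss_tot


def component_snr(
    params: ModelParams,
    blank_frequencies: Sequence[float],
    blank_power: Sequence[float],
    sfs: Sequence[float],
) -> np.ndarray:
    """Per-component SNR: max fitted weight over the sampled SFs, divided by
    the mean blank-condition power inside that component's band window."""
    bf = np.asarray(blank_frequencies, dtype=float)
    bp = np.asarray(blank_power, dtype=float)
    sfs = np.asarray(sfs, dtype=float)
    out = np.empty(3)
    for i, comp in enumerate(params.components):
        lo, hi = params.band_windows[comp.label]
        in_band = (bf >= lo) & (bf <= hi)
        if not np.any(in_band):
            raise ValueError(f"blank spectrum has no samples in {comp.label} band")
        out[i] = np.max(eval_weight(comp, sfs)) / float(np.mean(bp[in_band]))
    return out


def count_components(snrs, threshold: float = DEFAULT_SNR_THRESHOLD) -> int:
    """Number of components with SNR strictly greater than ``threshold``."""
    snrs = np.asarray(snrs, dtype=float)
    if np.any(snrs < 0):
        raise ValueError("SNR values must be non-negative")
    return int(np.sum(snrs > threshold))


class SiteSnr(NamedTuple):
    value: float
    included: bool
    degenerate: bool


def site_snr(stim_response, blank_response, threshold: float = DEFAULT_SNR_THRESHOLD) -> SiteSnr:
    """Site-selection SNR: SD of the per-trial response under stimulation
    divided by the SD under the blank condition.

    A zero blank SD is flagged degenerate and the site excluded rather than
    reported as infinite.
    """
    stim = np.asarray(stim_response, dtype=float)
    blank = np.asarray(blank_response, dtype=float)
    if stim.size < 2 or blank.size < 2:
        raise ValueError("need at least two trials per condition")
    sd_blank = float(np.std(blank, ddof=1))
    if sd_blank == 0.0:
        return SiteSnr(np.nan, False, True)
    value = float(np.std(stim, ddof=1)) / sd_blank
    return SiteSnr(value, value > threshold, False)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    params: ModelParams
    gof: float
    component_snr: np.ndarray | None
    n_components: int | None
    residual: np.ndarray
    mse: float
    n_restarts: int
    converged: bool
    best_restart: int


def _pack_bounds(power_max: float, band_windows: Mapping[str, tuple[float, float]], sf_max: float):
    """Lower/upper bounds for the free-parameter vector.

    Layout: [k, a, b, c] + per component [sigma, mu_lo, mu_hi, n, A1, s1, A2, s2]
    + [sf0], where (mu_lo, mu_hi) are the sigmoid's endpoint frequencies
    mu(0) and mu(inf), both box-bounded inside the component's band window —
    the sigmoid is monotone, so the whole mu(SF) path stays inside the band.
    """
    lo = [0.0, 0.3, 0.0, 0.0]
    hi = [1e9, 6.0, 1e4, 2.0 * power_max]
    for lab in COMPONENT_LABELS:
        b_lo, b_hi = band_windows[lab]
        lo += [1.0, b_lo, b_lo, 0.3, 0.0, 0.01, 0.0, 0.005]
        hi += [20.0, b_hi, b_hi, 8.0, 5.0 * power_max, 2.0 * sf_max, 5.0 * power_max, 2.0 * sf_max]
    lo += [0.005]
    hi += [2.0 * sf_max]
    return np.array(lo), np.array(hi)


def _unpack(x: np.ndarray, band_windows: Mapping[str, tuple[float, float]]) -> ModelParams:
    baseline = BaselineParams(k=x[0], a=x[1], b=x[2], c=x[3])
    comps = []
    for i, lab in enumerate(COMPONENT_LABELS):
        s = 4 + 8 * i
        sigma, mu_lo, mu_hi, n, a1, s1, a2, s2 = x[s : s + 8]
        comps.append(
            ComponentParams(
                label=lab, sigma=sigma, K0=mu_lo, K=mu_hi - mu_lo, n=n,
                A1=a1, sigma1=s1, A2=a2, sigma2=s2,
            )
        )
    return ModelParams(
        baseline=baseline, components=tuple(comps), sf0=x[-1],
        band_windows=dict(band_windows),
    )


def _model_on_grid(x: np.ndarray, sfs: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vectorized model evaluation from the raw parameter vector."""
    out = np.broadcast_to(x[0] / (freqs ** x[1] + x[2]) + x[3], (sfs.size, freqs.size)).copy()
    sf0 = x[-1]
    for i in range(3):
        s = 4 + 8 * i
        sigma, mu_lo, mu_hi, n, a1, s1, a2, s2 = x[s : s + 8]
        sfn = sfs**n
        mu = mu_lo + (mu_hi - mu_lo) * sfn / (sfn + sf0**n)
        w = np.maximum(a1 * np.exp(-(sfs**2) / (2 * s1**2)) - a2 * np.exp(-(sfs**2) / (2 * s2**2)), 0.0)
        out += w[:, None] * np.exp(-((freqs[None, :] - mu[:, None]) ** 2) / (2 * sigma**2))
    return out


def _initial_guess(
    rng: np.random.Generator,
    sfs: np.ndarray,
    freqs: np.ndarray,
    power: np.ndarray,
    band_windows: Mapping[str, tuple[float, float]],
    lo: np.ndarray,
    hi: np.ndarray,
    data_driven: bool,
) -> np.ndarray:
    """One starting point; the first restart is fully data-driven, the rest
    jitter around data-derived scales inside the bounds."""
    f_lo = freqs[0]
    p_floor = float(np.percentile(power, 5))
    a0 = 2.0 if data_driven else rng.uniform(0.8, 3.5)
    c0 = max(0.5 * p_floor, 1e-6)
    k0 = max(float(np.median(power[:, 0]) - c0), 1e-6) * f_lo**a0
    x = [k0, a0, 0.0 if data_driven else rng.uniform(0.0, 5.0), c0]
    base0 = k0 / (freqs**a0) + c0
    excess = np.maximum(power - base0[None, :], 0.0)
    for lab in COMPONENT_LABELS:
        b_lo, b_hi = band_windows[lab]
        in_band = (freqs >= b_lo) & (freqs <= b_hi)
        band_exc = excess[:, in_band]
        amp = float(band_exc.max()) if band_exc.size else 1.0
        i_sf, i_f = np.unravel_index(np.argmax(band_exc), band_exc.shape)
        mu_peak = float(freqs[in_band][i_f])
        sf_peak = float(sfs[i_sf])
        if not data_driven:
            amp *= rng.uniform(0.4, 1.6)
            mu_peak = rng.uniform(b_lo, b_hi)
        sigma0 = 5.0 if data_driven else rng.uniform(2.0, 10.0)
        s1 = max(sf_peak, 2.0 * sfs[0]) * (1.5 if data_driven else rng.uniform(0.5, 3.0))
        a2_frac = 0.0 if data_driven else rng.uniform(0.0, 0.8)
        x += [sigma0, mu_peak, np.clip(mu_peak + rng.uniform(-5, 5), b_lo, b_hi),
              rng.uniform(1.0, 3.0), amp, s1, a2_frac * amp, 0.3 * s1]
    x += [rng.uniform(0.1, 1.0) if not data_driven else 0.3]
    return np.clip(np.array(x), lo, hi)


def fit_model(
    grid,
    seed: int = 0,
    restarts: int = 20,
    band_windows: Mapping[str, tuple[float, float]] | None = None,
    freq_range: tuple[float, float] = (20.0, 120.0),
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    max_nfev: int | None = 400,
) -> FitResult:
    """Fit the full 2-D model to a :class:`~gammasf.spectral.SpectrumGrid`.

    Bounded trust-region least squares (MSE objective) with ``restarts``
    seeded starting points; the best (lowest-MSE) solution is kept.  If the
    grid carries a blank-condition spectrum, per-component SNRs and the
    resulting component count are attached to the result.
    """
    band_windows = dict(band_windows or DEFAULT_BAND_WINDOWS)
    freqs = np.asarray(grid.frequencies, dtype=float)
    sfs = np.asarray(grid.sfs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("spectrum grid contains non-positive frequencies")
    if sfs.size < 5:
        raise ValueError("need at least 5 spatial-frequency conditions")
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    freqs = freqs[sel]
    power = np.asarray(grid.power, dtype=float)[:, sel]

    lo, hi = _pack_bounds(float(power.max()), band_windows, float(sfs.max()))
    rng = np.random.default_rng(seed)

    def residual(x):
        return (_model_on_grid(x, sfs, freqs) - power).ravel()

    best = None
    best_cost = np.inf
    best_idx = -1
    any_success = False
    for r in range(restarts):
        x0 = _initial_guess(rng, sfs, freqs, power, band_windows, lo, hi, data_driven=(r == 0))
        try:
            sol = least_squares(
                residual, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                max_nfev=max_nfev,
            )
        except Exception:  # noqa: BLE001 - a failed restart is not fatal
            continue
        any_success = any_success or sol.success
        if sol.cost < best_cost:
            best, best_cost, best_idx = sol, sol.cost, r
    if best is None:
        raise RuntimeError("model fit failed on all restarts")

    params = _unpack(best.x, band_windows)
    pred = _model_on_grid(best.x, sfs, freqs)
    resid = power - pred
    gof = goodness_of_fit(power, pred)

    snrs = None
    n_comp = None
    if getattr(grid, "blank_power", None) is not None:
        blank = np.asarray(grid.blank_power, dtype=float)[sel]
        snrs = component_snr(params, freqs, blank, sfs)
        n_comp = count_components(snrs, snr_threshold)

    return FitResult(
        params=params, gof=gof, component_snr=snrs, n_components=n_comp,
        residual=resid, mse=float(np.mean(resid**2)), n_restarts=restarts,
        converged=any_success, best_restart=best_idx,
    )


def scale_amplitudes(params: ModelParams, factors: Sequence[float]) -> ModelParams:
    """Return a copy with each component's (A1, A2) scaled by ``factors``."""
    comps = tuple(
        replace(c, A1=c.A1 * f, A2=c.A2 * f) for c, f in zip(params.components, factors)
    )
    return replace(params, components=comps)
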