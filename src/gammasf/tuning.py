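"""Spatial-frequency tuning metrics and curve fits.

Two scalar metrics summarize a tuning curve:

* **cutoff SF** — the largest SF at which the response equals 50% of its
  peak, read off a fitted continuous curve (difference-of-Gaussians by
  default) over a dense grid spanning the sampled range; curves that never
  fall to half-maximum are censored at the largest sampled SF.
* **SF selectivity** — ``1 - response(lowest sampled SF) / response(optimal
  SF)``, clipped to [0, 1].

Both are invariant to positive scaling of the response.  Receptive-field
marginals are fitted with a 1-D Gaussian (amplitude, center, sigma,
offset); the center and sigma give the RF position and radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .model import goodness_of_fit

DENSE_GRID_POINTS = 10_000


@dataclass
class TuningCurve:
    sfs: np.ndarray
    response: np.ndarray
    source: str = "LG"  # {LG, MG, HG, MUA, baseline-band}

    def __post_init__(self) -> None:
        self.sfs = np.asarray(self.sfs, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.sfs.size < 5:
            raise ValueError("need at least 5 SF samples")
        if self.sfs.size != self.response.size:
            raise ValueError("sfs and response length mismatch")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        order = np.argsort(self.sfs)
        self.sfs = self.sfs[order]
        self.response = self.response[order]


class DogFit(NamedTuple):
    A1: float
    sigma1: float
    A2: float
    sigma2: float
    gof: float | None  # None when the data are constant (gof undefined)


class CutoffResult(NamedTuple):
    sf: float
    censored: bool


@dataclass
class RFEstimate:
    center: float  # degrees
    radius: float  # Gaussian sigma, degrees
    amplitude: float
    offset: float


def _dog(sf, a1, s1, a2, s2):
    return a1 * np.exp(-(sf**2) / (2 * s1**2)) - a2 * np.exp(-(sf**2) / (2 * s2**2))


def fit_dog(curve: TuningCurve, seed: int = 0, restarts: int = 10) -> DogFit:
    """Bounded least-squares difference-of-Gaussians fit of a tuning curve,
    with seeded multi-start."""
    sfs, resp = curve.sfs, curve.response
    if np.ptp(resp) == 0:
        if np.all(resp == 0):
            return DogFit(0.0, 1.0, 0.0, 1.0, None)
        # constant nonzero curve: flat DoG fits exactly but gof is undefined
        return DogFit(float(resp[0]), 1e3, 0.0, 1.0, None)
    amp = float(resp.max())
    sf_hi = float(sfs.max())
    lo = np.array([0.0, 1e-3, 0.0, 5e-4])
    hi = np.array([10 * amp, 4 * sf_hi, 10 * amp, 4 * sf_hi])
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for r in range(restarts):
        if r == 0:
            s1 = max(float(sfs[np.argmax(resp)]), 2 * sfs[0])
            x0 = np.array([amp, 1.5 * s1, 0.3 * amp, 0.4 * s1])
        else:
            s1 = rng.uniform(sfs[0], sf_hi)
            x0 = np.array([amp * rng.uniform(0.5, 2), s1, amp * rng.uniform(0, 1), s1 * rng.uniform(0.1, 0.8)])
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(lambda x: _dog(sfs, *x) - resp, x0, bounds=(lo, hi), x_scale="jac")
        except Exception:  # noqa: BLE001
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        raise RuntimeError("DoG fit failed on all restarts")
    pred = _dog(sfs, *best.x)
    return DogFit(*best.x, gof=goodness_of_fit(resp, pred))


def _dense_curve(curve: TuningCurve, fitted: DogFit | None):
    """Continuous response on a dense SF grid: the DoG fit when it is good,
    else a shape-preserving monotone-segment interpolant of the samples."""
    grid = np.linspace(curve.sfs[0], curve.sfs[-1], DENSE_GRID_POINTS)
    if fitted is None:
        fitted = fit_dog(curve)
    if fitted.gof is not None and fitted.gof > 0.5:
        return grid, np.maximum(_dog(grid, fitted.A1, fitted.sigma1, fitted.A2, fitted.sigma2), 0.0)
    interp = PchipInterpolator(curve.sfs, curve.response)
    return grid, np.maximum(interp(grid), 0.0)


def cutoff_sf(curve: TuningCurve, fitted: DogFit | None = None) -> CutoffResult:
    """Largest SF at 50% of the peak response, on the fitted curve.

    Censored (at the largest sampled SF) when the response never falls to
    half-maximum inside the sampled range.
    """
    grid, resp = _dense_curve(curve, fitted)
    peak = float(resp.max())
    if peak <= 0:
        raise ValueError("cutoff undefined for an all-zero curve")
    above = resp >= 0.5 * peak
    last = int(np.max(np.nonzero(above)))
    if last == resp.size - 1:
        return CutoffResult(float(grid[-1]), True)
    # linear interpolation across the crossing
    x0, x1 = grid[last], grid[last + 1]
    y0, y1 = resp[last], resp[last + 1]
    t = (0.5 * peak - y0) / (y1 - y0)
    return CutoffResult(float(x0 + t * (x1 - x0)), False)


def sf_selectivity(curve: TuningCurve, fitted: DogFit | None = None) -> float:
    """``1 - response(lowest sampled SF) / response(optimal SF)`` on the
    fitted curve, clipped to [0, 1]."""
    grid, resp = _dense_curve(curve, fitted)
    peak = float(resp.max())
    if peak <= 0:
        raise ValueError("selectivity undefined for an all-zero curve")
    return float(np.clip(1.0 - resp[0] / peak, 0.0, 1.0))


def fit_rf_gaussian(positions, response) -> RFEstimate:
    """1-D Gaussian fit (amplitude, center, sigma, offset) of a
    receptive-field marginal."""
    positions = np.asarray(positions, dtype=float)
    response = np.asarray(response, dtype=float)
    if positions.size < 5:
        raise ValueError("need at least 5 positions")
    if np.ptp(response) == 0:
        raise ValueError("flat map: RF fit undefined")

    def fun(x):
        a, c, s, o = x
        return a * np.exp(-((positions - c) ** 2) / (2 * s**2)) + o - response

    span = float(np.ptp(positions))
    x0 = np.array([
        float(response.max() - response.min()),
        float(positions[np.argmax(response)]),
        span / 4,
        float(response.min()),
    ])
    lo = np.array([0.0, positions.min() - span, 1e-4, -np.inf])
    hi = np.array([np.inf, positions.max() + span, 10 * span, np.inf])
    sol = least_squares(fun, x0, bounds=(lo, hi), x_scale="jac")
    a, c, s, o = sol.x
    return RFEstimate(center=float(c), radius=float(s), amplitude=float(a), offset=float(o))


def component_tuning(fit_params, label: str, sfs) -> TuningCurve:
    """Tuning curve of one fitted gamma component's weight over ``sfs``."""
    from .model import eval_weight

    comp = fit_params.component(label)
    return TuningCurve(sfs=np.asarray(sfs, dtype=float), response=eval_weight(comp, np.asarray(sfs, dtype=float)), source=label)
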