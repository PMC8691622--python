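"""L1-regularized logistic decoding of edge vs surface from gamma power.

Each trial is represented by 3N features (N sites x three gamma-band
powers, or three time-binned MUA rates as a control) and a binary label
(edge = 1, surface = 0).  The decoder is logistic regression in the
as-published sign convention::

    P(edge | X) = 1 / (1 + exp(X.W + w0))

(so a more negative linear score means a higher edge probability; the
conventional form differs only in the sign of the learned weights), with
the objective::

    J = -(1/m) sum_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ] + lambda/(2m) * sum_j |W_j|

The intercept is not penalized.  The L1 term is handled exactly by the
positive/negative split W = W+ - W- (both box-constrained at zero), which
keeps the objective smooth and convex for L-BFGS-B.  Data are split
60/15/25 into train/validation/test; lambda is chosen on the validation
MSE between predicted probability and label over a 20-point log grid in
[0.001, 40], then the model is refit on train+validation before test
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import train_test_split

DEFAULT_LAMBDA_GRID = tuple(np.geomspace(0.001, 40.0, 20))
DEFAULT_SPLIT = (0.60, 0.15, 0.25)
_CLIP = 30.0  # |linear score| cap before exponentiation


@dataclass
class DecodeDataset:
    X: np.ndarray  # (n_trials, 3N)
    y: np.ndarray  # binary, edge=1 / surface=0
    feature_kind: str = "gamma"
    site_ids: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[1] % 3:
            raise ValueError("feature count must be divisible by 3 (bands/bins per site)")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y trial counts differ")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary (edge=1, surface=0)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing values in feature matrix")

    @property
    def n_sites(self) -> int:
        return self.X.shape[1] // 3

    def subset_sites(self, sites: Sequence[int]) -> "DecodeDataset":
        cols = np.concatenate([[3 * s, 3 * s + 1, 3 * s + 2] for s in sites])
        ids = [self.site_ids[s] for s in sites] if self.site_ids else ()
        return DecodeDataset(self.X[:, cols], self.y, self.feature_kind, ids)


@dataclass
class DecoderModel:
    W: np.ndarray
    w0: float
    lam: float
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    split: dict = field(default_factory=dict)
    test_accuracy: float | None = None
    val_mse: float | None = None
    lambda_grid: tuple | None = None


def _score(X: np.ndarray, w: np.ndarray, w0: float) -> np.ndarray:
    return np.clip(X @ w + w0, -_CLIP, _CLIP)


def predict(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Per-trial P(edge | X) under the published convention; classify edge
    when p >= 0.5."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W.size:
        raise ValueError("feature dimension does not match the model")
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_sd
    return 1.0 / (1.0 + np.exp(_score(X, model.W, model.w0)))


def classify(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    return (predict(model, X) >= 0.5).astype(float)


def loss(model: DecoderModel, X: np.ndarray, y: np.ndarray, lam: float | None = None) -> float:
    """The training objective J at the model's weights (intercept
    unpenalized; probabilities clipped away from 0/1)."""
    lam = model.lam if lam is None else lam
    y = np.asarray(y, dtype=float)
    m = y.size
    if m == 0:
        raise ValueError("empty dataset")
    p = np.clip(predict(model, X), 1e-12, 1 - 1e-12)
    nll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(nll + lam / (2 * m) * np.sum(np.abs(model.W)))


def _fit_fixed_lambda(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Exact L1 logistic fit via the W = W+ - W- smooth reformulation."""
    m, d = X.shape

    def objective(z):
        wp, wn, w0 = z[:d], z[d : 2 * d], z[-1]
        w = wp - wn
        s = _score(X, w, w0)
        # p = sigmoid(-s); stable cross-entropy in terms of s
        nll = np.mean(y * np.logaddexp(0.0, s) + (1 - y) * np.logaddexp(0.0, -s))
        pen = lam / (2 * m) * (np.sum(wp) + np.sum(wn))
        p = 1.0 / (1.0 + np.exp(s))
        ds = (p - y) * (-1.0) / m  # dJ/ds_i = (y_i - p_i)/m
        gw = X.T @ ds
        grad = np.concatenate([gw + lam / (2 * m), -gw + lam / (2 * m), [np.sum(ds)]])
        return nll + pen, grad

    z0 = np.zeros(2 * d + 1)
    bounds = [(0, None)] * (2 * d) + [(None, None)]
    res = minimize(objective, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
    w = res.x[:d] - res.x[d : 2 * d]
    return w, float(res.x[-1])


def train(
    ds: DecodeDataset,
    lam: float | None = None,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
    split: tuple[float, float, float] = DEFAULT_SPLIT,
    standardize: bool = True,
    refit: bool = True,
) -> DecoderModel:
    """Train with a seeded stratified 60/15/25 split.

    With ``lam`` given, that single regularization weight is used;
    otherwise lambda is selected from ``lambda_grid`` (default 20
    log-spaced values in [0.001, 40]) by validation MSE, and the winning
    model is refit on train+validation.  Test accuracy is recorded on the
    model.
    """
    y = ds.y
    if min(np.sum(y == 1), np.sum(y == 0)) < 20:
        raise ValueError("need at least 20 trials per class")
    idx = np.arange(y.size)
    train_idx, rest = train_test_split(
        idx, train_size=split[0], stratify=y, random_state=seed
    )
    val_frac = split[1] / (split[1] + split[2])
    val_idx, test_idx = train_test_split(
        rest, train_size=val_frac, stratify=y[rest], random_state=seed + 1
    )
    for part in (train_idx, val_idx, test_idx):
        if len(np.unique(y[part])) < 2:
            raise ValueError("a split contains a single class")

    if standardize:
        mu = ds.X[train_idx].mean(axis=0)
        sd = ds.X[train_idx].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = None, None

    def _xs(ix):
        x = ds.X[ix]
        return (x - mu) / sd if standardize else x

    grid = (lam,) if lam is not None else tuple(lambda_grid or DEFAULT_LAMBDA_GRID)
    best = None
    for lam_i in grid:
        w, w0 = _fit_fixed_lambda(_xs(train_idx), y[train_idx], lam_i)
        model = DecoderModel(W=w, w0=w0, lam=lam_i, feature_mean=mu, feature_sd=sd)
        p_val = predict(model, ds.X[val_idx])
        mse = float(np.mean((p_val - y[val_idx]) ** 2))
        if best is None or mse < best.val_mse:
            model.val_mse = mse
            best = model
    if refit and len(grid) > 1:
        fit_idx = np.concatenate([train_idx, val_idx])
        if standardize:
            mu = ds.X[fit_idx].mean(axis=0)
            sd = np.where(ds.X[fit_idx].std(axis=0) > 0, ds.X[fit_idx].std(axis=0), 1.0)
        xs = (ds.X[fit_idx] - mu) / sd if standardize else ds.X[fit_idx]
        w, w0 = _fit_fixed_lambda(xs, y[fit_idx], best.lam)
        best = DecoderModel(W=w, w0=w0, lam=best.lam, feature_mean=mu,
                            feature_sd=sd, val_mse=best.val_mse)
    best.lambda_grid = grid
    best.split = {"train": train_idx, "val": val_idx, "test": test_idx}
    best.test_accuracy = float(np.mean(classify(best, ds.X[test_idx]) == y[test_idx]))
    return best


def accuracy_vs_nsites(
    ds: DecodeDataset,
    counts: Sequence[int],
    repeats: int = 10,
    lam: float | None = 0.1,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Mean +/- SE test accuracy as a function of the number of sites.

    For each count, ``repeats`` random site subsets (without replacement)
    are drawn from the pool, a decoder trained on each, and the test
    accuracies aggregated.  The default fixes lambda at 0.1, the setting
    used for the published site-count curves.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for count in counts:
        if count > ds.n_sites:
            raise ValueError(f"count {count} exceeds the {ds.n_sites}-site pool")
        accs = []
        for r in range(repeats):
            sites = rng.choice(ds.n_sites, size=count, replace=False)
            sub = ds.subset_sites(sorted(sites))
            model = train(sub, lam=lam, seed=int(rng.integers(2**31)))
            accs.append(model.test_accuracy)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
        out[int(count)] = (float(accs.mean()), float(se))
    return out
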