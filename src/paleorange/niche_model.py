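"""MaxEnt-style inhomogeneous Poisson point-process niche model.

Presence cells (duplicates kept as counts) and a uniform background
sample define a penalized Poisson point-process likelihood with
intensity ``lambda(x) = exp(alpha + f(x) . w)`` over background
quadrature cells. Profiling out the intercept reduces the objective to
the classic presence/background log-linear form

    g(w) = -sum_presences f(x_i) . w + N log sum_bg exp(f_j . w)
           + beta * sum_j s_j |w_j|

with ``s_j`` the background standard deviation of feature j. The L1
penalty is handled exactly by a positive/negative coefficient split,
which keeps the objective smooth and lets L-BFGS-B do the work.

Predictions are "raw" relative occurrence rates: ``exp(f . w)``
normalized to sum to one over the background cells of the slice being
predicted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .bioclim import VARIABLE_NAMES, BioclimStack
from .grids import LatLonGrid
from .synthetic_data import OccurrenceSet

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product")


class NotFittedError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FeatureSpec:
    """Feature expansion classes and the regularization multiplier."""

    classes: tuple[str, ...] = ("linear", "quadratic")
    beta: float = 2.0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class is required")
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.beta <= 0:
            raise ValueError("regularization multiplier beta must be positive")


def expand_features(X: np.ndarray, classes=("linear", "quadratic")) -> tuple[np.ndarray, list[str]]:
    """Expand an (n, 4) variable matrix into model features.

    linear: x_k; quadratic: x_k^2; product: x_k * x_l for k < l.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    base = list(VARIABLE_NAMES)
    if "linear" in classes:
        for k, name in enumerate(base):
            cols.append(X[:, k])
            names.append(name)
    if "quadratic" in classes:
        for k, name in enumerate(base):
            cols.append(X[:, k] ** 2)
            names.append(f"{name}^2")
    if "product" in classes:
        for k, l in itertools.combinations(range(len(base)), 2):
            cols.append(X[:, k] * X[:, l])
            names.append(f"{base[k]}*{base[l]}")
    return np.column_stack(cols), names


@dataclass
class NicheModel:
    spec: FeatureSpec
    feature_names: list[str]
    coef: np.ndarray  # original feature scale
    intercept: float
    bg_mean: np.ndarray  # background feature means (for conditioning)
    bg_sd: np.ndarray  # background feature SDs (= penalty scales)
    background_rows: np.ndarray
    background_cols: np.ndarray
    grid: LatLonGrid
    fitted: bool = False
    objective_value: float = np.nan

    def linear_predictor(self, X_vars: np.ndarray) -> np.ndarray:
        """f(x) . w (no intercept) for raw bioclim variable rows."""
        F, _ = expand_features(X_vars, self.spec.classes)
        return F @ self.coef


@dataclass
class SuitabilityMap:
    """Raw relative occurrence rate per cell; NaN off the land mask.

    Values are non-negative and sum to one over the background cells
    used for normalization (stored in ``background_rows/cols``).
    """

    grid: LatLonGrid
    values: np.ndarray
    background_rows: np.ndarray
    background_cols: np.ndarray

    @property
    def land_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def at_cells(self, rows, cols) -> np.ndarray:
        return self.values[np.asarray(rows), np.asarray(cols)]


def sample_background(
    mask: np.ndarray, B: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement sample of ``min(B, n_land)`` land
    cells; returns (rows, cols). Presences are never added."""
    if B < 1:
        raise ValueError("B must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("cannot sample background from an empty mask")
    rng = np.random.default_rng(seed)
    take = min(B, rows.size)
    idx = rng.choice(rows.size, size=take, replace=False)
    idx.sort()
    return rows[idx], cols[idx]


def assign_presence_cells(
    occ: OccurrenceSet, grid: LatLonGrid, land_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-cell presence counts. Duplicates are retained as counts; points
    outside the extent or off the land mask are dropped with a logged
    tally."""
    counts = np.zeros(grid.shape, dtype=np.int64)
    if len(occ) == 0:
        return counts
    lons, lats = occ.lons(), occ.lats()
    inside = grid.contains(lons, lats)
    n_outside = int((~inside).sum())
    rows, cols = grid.cell_of(lons[inside], lats[inside])
    if land_mask is not None:
        on_land = np.asarray(land_mask, dtype=bool)[rows, cols]
        n_sea = int((~on_land).sum())
        rows, cols = rows[on_land], cols[on_land]
    else:
        n_sea = 0
    if n_outside or n_sea:
        logger.warning(
            "assign_presence_cells: dropped %d outside extent, %d off land",
            n_outside,
            n_sea,
        )
    np.add.at(counts, (rows, cols), 1)
    return counts


def _prepare_design(
    presence_counts: np.ndarray,
    background: tuple[np.ndarray, np.ndarray],
    stack: BioclimStack,
    spec: FeatureSpec,
):
    brows, bcols = background
    F_bg, names = expand_features(stack.values_at(brows, bcols), spec.classes)
    prow, pcol = np.nonzero(presence_counts)
    y = presence_counts[prow, pcol].astype(float)
    F_pr, _ = expand_features(stack.values_at(prow, pcol), spec.classes)
    if not (np.all(np.isfinite(F_bg)) and np.all(np.isfinite(F_pr))):
        raise ValueError("non-finite feature values at presence or background cells")
    mu = F_bg.mean(axis=0)
    sd = F_bg.std(axis=0)
    active = sd > 0  # constant features carry no information; coef pinned to 0
    sd_safe = np.where(active, sd, 1.0)
    Z_bg = (F_bg - mu) / sd_safe
    Z_pr = (F_pr - mu) / sd_safe
    return Z_bg, Z_pr, y, mu, sd, active, names


def fit_ppm(
    presence_counts: np.ndarray,
    background: tuple[np.ndarray, np.ndarray],
    stack: BioclimStack,
    spec: FeatureSpec,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> NicheModel:
    """Maximize the penalized point-process likelihood.

    In standardized-feature coordinates the penalty ``beta * s_j |w_j|``
    becomes ``beta * |w~_j|``; splitting ``w~ = u - v`` with u, v >= 0
    yields a smooth bound-constrained convex problem.
    """
    brows, bcols = background
    if brows.size < 2:
        raise ValueError("need at least 2 background cells")
    N = presence_counts.sum()
    if N < 1:
        raise ValueError("need at least 1 presence")
    Z_bg, Z_pr, y, mu, sd, active, names = _prepare_design(
        presence_counts, background, stack, spec
    )
    p = Z_bg.shape[1]
    s_pres = (y[:, None] * Z_pr).sum(axis=0)  # sum of presence features
    beta = spec.beta

    def objective(theta):
        u, v = theta[:p], theta[p:]
        w = np.where(active, u - v, 0.0)
        eta = Z_bg @ w
        lse = logsumexp(eta)
        soft = np.exp(eta - lse)
        val = -s_pres @ w + N * lse + beta * np.sum((u + v)[active])
        g_w = -s_pres + N * (Z_bg.T @ soft)
        g_w = np.where(active, g_w, 0.0)
        grad = np.concatenate([g_w + beta * active, -g_w + beta * active])
        return val, grad

    theta0 = np.zeros(2 * p)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={"maxiter": max_iter, "maxfun": 20 * max_iter, "ftol": tol, "gtol": 1e-9},
    )
    # judge convergence by the projected gradient at the solution rather
    # than the solver's status string (L-BFGS-B reports ABNORMAL on some
    # well-converged problems with steep penalties)
    _, grad = objective(res.x)
    proj = np.where((res.x <= 0.0) & (grad > 0.0), 0.0, grad)
    gtol = 1e-4 * max(1.0, float(N))
    if not res.success and np.abs(proj).max() > gtol:
        raise ConvergenceError(
            f"point-process fit did not converge: {res.message} "
            f"(projected gradient {np.abs(proj).max():.3e} > {gtol:.3e})",
            trace=res,
        )
    u, v = res.x[:p], res.x[p:]
    w_std = np.where(active, u - v, 0.0)
    sd_safe = np.where(active, sd, 1.0)
    coef = w_std / sd_safe
    # intercept for lambda = exp(alpha + f.w) with uniform 1/B quadrature
    eta_bg = Z_bg @ w_std
    alpha = float(
        np.log(N) - (logsumexp(eta_bg) - np.log(len(eta_bg))) - mu @ coef
    )
    return NicheModel(
        spec=spec,
        feature_names=names,
        coef=coef,
        intercept=alpha,
        bg_mean=mu,
        bg_sd=sd,
        background_rows=np.asarray(brows),
        background_cols=np.asarray(bcols),
        grid=stack.grid,
        fitted=True,
        objective_value=float(res.fun),
    )


def predict_raw(
    model: NicheModel,
    stack: BioclimStack,
    background: tuple[np.ndarray, np.ndarray] | None = None,
) -> SuitabilityMap:
    """Raw relative occurrence rate over ``stack``.

    Normalization background: the explicit ``background`` argument if
    given; otherwise the model's own background when the stack lives on
    the training grid and those cells are on land; otherwise all land
    cells of the slice (the projection convention: each slice is
    normalized over its own background).
    """
    if not model.fitted:
        raise NotFittedError("niche model is not fitted")
    if background is None:
        if stack.grid == model.grid and np.all(
            stack.land_mask[model.background_rows, model.background_cols]
        ):
            background = (model.background_rows, model.background_cols)
        else:
            background = np.nonzero(stack.land_mask)
    brows, bcols = background
    mask = stack.land_mask
    eta = np.full(stack.grid.shape, np.nan)
    eta[mask] = model.linear_predictor(stack.feature_matrix())
    eta_bg = eta[brows, bcols]
    if not np.all(np.isfinite(eta_bg)):
        raise ValueError("background cells fall off the land mask of this stack")
    log_norm = logsumexp(eta_bg)
    values = np.exp(eta - log_norm)
    return SuitabilityMap(
        grid=stack.grid,
        values=values,
        background_rows=np.asarray(brows),
        background_cols=np.asarray(bcols),
    )


def _auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: probability a presence outranks a background cell
    (ties count half)."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _occurrence_cells(occ: OccurrenceSet, grid: LatLonGrid, land_mask: np.ndarray):
    lons, lats = occ.lons(), occ.lats()
    inside = grid.contains(lons, lats)
    rows, cols = grid.cell_of(lons[inside], lats[inside])
    on_land = np.asarray(land_mask, dtype=bool)[rows, cols]
    return rows[on_land], cols[on_land]


def _counts_from_cells(rows, cols, shape) -> np.ndarray:
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return counts


def _cv_auc(rows, cols, fold_ids, k, background, stack, spec) -> float:
    aucs = []
    for f in range(k):
        test = fold_ids == f
        if not test.any():
            raise ValueError(f"fold {f} contains no presences")
        if not (~test).any():
            raise ValueError(f"fold {f} contains all presences; nothing to train on")
        counts = _counts_from_cells(rows[~test], cols[~test], stack.grid.shape)
        model = fit_ppm(counts, background, stack, spec)
        smap = predict_raw(model, stack, background=background)
        pos = smap.at_cells(rows[test], cols[test])
        neg = smap.at_cells(*background)
        aucs.append(_auc(pos, neg))
    return float(np.mean(aucs))


def kfold_auc(
    occ: OccurrenceSet,
    background: tuple[np.ndarray, np.ndarray],
    stack: BioclimStack,
    spec: FeatureSpec,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean AUC over k random presence folds (background shared)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rows, cols = _occurrence_cells(occ, stack.grid, stack.land_mask)
    n = rows.size
    if n < k:
        raise ValueError(f"{n} presences cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    fold_ids = rng.permutation(np.arange(n) % k)
    return _cv_auc(rows, cols, fold_ids, k, background, stack, spec)


def checkerboard_fold(rows, cols, aggregation: int) -> np.ndarray:
    """Two-scale checkerboard fold id in {0..3} for cell indices.

    Fine parity comes from blocks of ``aggregation`` cells, coarse
    parity from blocks of ``2 * aggregation``; the fold is
    ``2 * coarse + fine``.
    """
    if aggregation < 1:
        raise ValueError("aggregation must be >= 1")
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    fine = (rows // aggregation + cols // aggregation) % 2
    coarse = (rows // (2 * aggregation) + cols // (2 * aggregation)) % 2
    return (2 * coarse + fine).astype(int)


def checkerboard_cv_auc(
    occ: OccurrenceSet,
    background: tuple[np.ndarray, np.ndarray],
    stack: BioclimStack,
    spec: FeatureSpec,
    grid: LatLonGrid | None = None,
    aggregation: int = 2,
    seed: int = 0,
) -> float:
    """Mean AUC over the 4 spatially disjoint checkerboard folds.

    Both presences and background cells are partitioned; each fold
    tests the fold's presences against the fold's background cells and
    trains on everything else.
    """
    grid = grid or stack.grid
    rows, cols = _occurrence_cells(occ, grid, stack.land_mask)
    fold_ids = checkerboard_fold(rows, cols, aggregation)
    occupancy = [int((fold_ids == f).sum()) for f in range(4)]
    if min(occupancy) == 0:
        raise ValueError(
            f"empty checkerboard fold; presence occupancy by fold: {occupancy}"
        )
    brows, bcols = background
    bg_folds = checkerboard_fold(brows, bcols, aggregation)
    aucs = []
    for f in range(4):
        test = fold_ids == f
        counts = _counts_from_cells(rows[~test], cols[~test], stack.grid.shape)
        bg_test = bg_folds == f
        bg_train = (brows[~bg_test], bcols[~bg_test])
        if bg_train[0].size < 2 or bg_test.sum() < 1:
            raise ValueError(f"checkerboard fold {f} has too few background cells")
        model = fit_ppm(counts, bg_train, stack, spec)
        smap = predict_raw(model, stack, background=bg_train)
        pos = smap.at_cells(rows[test], cols[test])
        neg = smap.at_cells(brows[bg_test], bcols[bg_test])
        aucs.append(_auc(pos, neg))
    return float(np.mean(aucs))


@dataclass(frozen=True)
class ThresholdResult:
    t: float
    realized_omission: float
    e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.realized_omission <= self.e <= 1.0):
            raise ValueError(
                "invalid threshold result: requires "
                f"0 <= realized omission ({self.realized_omission}) <= e ({self.e}) <= 1"
            )


def lowest_presence_threshold(presence_suits, e: float) -> ThresholdResult:
    """Modified lowest-presence threshold with omission allowance ``e``.

    t is the largest observed presence suitability such that the
    fraction of presences strictly below t is at most e. The binary
    rule downstream is suitable iff raw >= t, so the realized training
    omission is exactly that fraction.
    """
    suits = np.asarray(presence_suits, dtype=float)
    if suits.size < 1:
        raise ValueError("need at least one presence suitability value")
    if not (0.0 <= e < 1.0):
        raise ValueError("omission allowance e must satisfy 0 <= e < 1")
    n = suits.size
    t = float(suits.min())
    for v in np.unique(suits):
        if (suits < v).sum() / n <= e:
            t = float(v)
        else:
            break
    realized = float((suits < t).sum() / n)
    return ThresholdResult(t=t, realized_omission=realized, e=float(e))


def binarize(smap: SuitabilityMap, t: float) -> np.ndarray:
    """Binary suitable (1.0) / unsuitable (0.0) grid; NaN preserved."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    values = smap.values
    out = np.where(np.isfinite(values), (values >= t).astype(float), np.nan)
    return out
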