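"""Parameter estimation for the lure-recognition mixture model.

The primary estimator, :func:`fit_sse`, follows the nonlinear-regression
approach used with ROC data: it minimises the sum of squared errors between
observed and predicted fROC points *in both the x- and y-dimensions*,
jointly over the three process parameters (R_f, R_r, d') and the K-1
response criteria.  :func:`fit_mle` is the product-multinomial
maximum-likelihood alternative operating on the raw rating counts.
Nested variants (equal-variance SDT, dual-process-style, the linear
two-threshold case, UVSD) are obtained by pinning parameters through
``FitConfig.fixed`` / ``FitConfig.free_variance_ratio``.

Constrained structure is handled by smooth reparameterisation rather than a
constrained optimiser: the simplex constraint R_f + R_r <= 1 via
R_r = (1 - R_f) * b with b in [0, 1], and criterion ordering via a free
first threshold plus box-bounded positive increments.  All remaining
parameters are box-bounded, so SciPy's trust-region-reflective least-squares
and L-BFGS-B do the local work; a deterministic multi-start (seeded jitter
around a method-of-moments guess) guards against the multimodality of
mixture SSE surfaces.

:func:`grid_search_sse` is an intentionally simple, exhaustive
profile-grid search over the process parameters used as an independent
correctness oracle for the optimiser.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize, minimize_scalar
from scipy.special import ndtr, ndtri

from .model import (
    CriteriaVector,
    MixtureParams,
    bin_probabilities,
    lure_acceptance_prob,
    new_acceptance_prob,
    predicted_froc,
    roc_curve,
)
from .roc_data import ConfidenceCounts, FrocPoints, build_froc

__all__ = [
    "FitConfig",
    "FitResult",
    "FitReport",
    "GridSearchResult",
    "fit_sse",
    "fit_mle",
    "fit_constrained",
    "goodness_of_fit",
    "grid_search_sse",
    "MIN_TRIALS_RECOMMENDED",
]

#: Minimum recommended per-class trial count for a stable individual fROC.
MIN_TRIALS_RECOMMENDED = 60

_PROCESS_PARAMS = ("r_false", "r_reject", "d_prime", "variance_ratio")

_DEFAULT_BOUNDS = {
    "r_false": (0.0, 1.0),
    "r_reject": (0.0, 1.0),
    # beyond d' ~ 6 the normal CDF saturates and d' is unidentifiable
    "d_prime": (0.0, 6.0),
    "variance_ratio": (0.25, 4.0),
    "t_first": (-5.0, 5.0),
    # strictly positive increments keep criteria ordered; upper bound is lax
    "t_step": (1e-4, 10.0),
}

_TIE_TOL = 1e-10


@dataclass
class FitConfig:
    """Options controlling a model fit.

    Parameters
    ----------
    method:
        ``"sse"`` (fROC least squares, the default) or ``"mle"``
        (multinomial likelihood on counts).
    n_starts:
        Number of deterministic multi-start local optimisations (>= 1).
    seed:
        Seed for the jittered start points; fits are bit-reproducible for a
        fixed (data, config) pair.
    fixed:
        Map pinning any of ``r_false``, ``r_reject``, ``d_prime``,
        ``variance_ratio`` to a constant, e.g. ``{"r_reject": 0.0}``.
    free_variance_ratio:
        Free the lure-distribution SD (UVSD-style); by default it is fixed
        at 1 (equal variance).
    tolerance:
        Convergence tolerance passed to the local optimiser.
    bounds:
        Optional per-parameter ``(lo, hi)`` overrides of the defaults.
    """

    method: str = "sse"
    n_starts: int = 20
    seed: int = 0
    fixed: dict[str, float] = field(default_factory=dict)
    free_variance_ratio: bool = False
    tolerance: float = 1e-12
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("sse", "mle"):
            raise ValueError(f"method must be 'sse' or 'mle', got {self.method!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name in self.fixed:
            if name not in _PROCESS_PARAMS:
                raise ValueError(f"cannot fix unknown parameter {name!r}")
        rf = self.fixed.get("r_false")
        rr = self.fixed.get("r_reject")
        if rf is not None and not 0.0 <= rf <= 1.0:
            raise ValueError(f"fixed r_false {rf} outside [0, 1]")
        if rr is not None and not 0.0 <= rr <= 1.0:
            raise ValueError(f"fixed r_reject {rr} outside [0, 1]")
        if rf is not None and rr is not None and rf + rr > 1.0:
            raise ValueError(f"fixed r_false + r_reject = {rf + rr} exceeds 1")
        if "d_prime" in self.fixed and self.fixed["d_prime"] < 0:
            raise ValueError("fixed d_prime must be >= 0")
        if "variance_ratio" in self.fixed and self.fixed["variance_ratio"] <= 0:
            raise ValueError("fixed variance_ratio must be > 0")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, _DEFAULT_BOUNDS[name])


class _ParamCodec:
    """Maps the optimiser vector to (MixtureParams, CriteriaVector).

    Layout: [a?, b?, d?, s?, t1, dt_2, ..., dt_{K-1}] where present;
    R_f = (1 - fixed R_r) * a when R_r is pinned else a, and
    R_r = (1 - R_f) * b, so every feasible vector satisfies the simplex
    constraint by construction.  Thresholds are t1 plus cumulative
    positive increments.
    """

    def __init__(self, config: FitConfig, n_thresholds: int) -> None:
        self.config = config
        self.m = n_thresholds
        fixed = config.fixed
        self.free_rf = "r_false" not in fixed
        self.free_rr = "r_reject" not in fixed
        self.free_d = "d_prime" not in fixed
        self.free_s = config.free_variance_ratio and "variance_ratio" not in fixed
        names: list[str] = []
        lo: list[float] = []
        hi: list[float] = []
        if self.free_rf:
            names.append("a")
            lo.append(0.0)
            hi.append(1.0)
        if self.free_rr:
            names.append("b")
            lo.append(0.0)
            hi.append(1.0)
        if self.free_d:
            names.append("d")
            b = config.bound("d_prime")
            lo.append(b[0])
            hi.append(b[1])
        if self.free_s:
            names.append("s")
            b = config.bound("variance_ratio")
            lo.append(b[0])
            hi.append(b[1])
        self.n_process = len(names)
        bt = config.bound("t_first")
        names.append("t1")
        lo.append(bt[0])
        hi.append(bt[1])
        bs = config.bound("t_step")
        for j in range(2, n_thresholds + 1):
            names.append(f"dt{j}")
            lo.append(bs[0])
            hi.append(bs[1])
        self.names = names
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    @property
    def n_free(self) -> int:
        return len(self.names)

    def decode(self, theta: np.ndarray) -> tuple[MixtureParams, CriteriaVector]:
        fixed = self.config.fixed
        i = 0
        if self.free_rf:
            a = theta[i]
            i += 1
            rr_pin = fixed.get("r_reject")
            rf = a if rr_pin is None else (1.0 - rr_pin) * a
        else:
            rf = fixed["r_false"]
        if self.free_rr:
            b = theta[i]
            i += 1
            rr = (1.0 - rf) * b
        else:
            rr = fixed.get("r_reject", 0.0)
        if self.free_d:
            d = theta[i]
            i += 1
        else:
            d = fixed["d_prime"]
        if self.free_s:
            s = theta[i]
            i += 1
        else:
            s = fixed.get("variance_ratio", 1.0)
        t1 = theta[i]
        steps = theta[i + 1 :]
        thresholds = t1 + np.concatenate([[0.0], np.cumsum(steps)])
        # clip tiny constraint violations from optimiser round-off
        rf = float(np.clip(rf, 0.0, 1.0))
        rr = float(np.clip(rr, 0.0, 1.0 - rf))
        params = MixtureParams(
            r_false=rf, r_reject=rr, d_prime=float(max(d, 0.0)), variance_ratio=float(s)
        )
        return params, CriteriaVector(thresholds)

    def encode(
        self, params: MixtureParams, criteria: CriteriaVector
    ) -> np.ndarray:
        """Inverse of :meth:`decode` (used for the moment-based start)."""
        fixed = self.config.fixed
        theta: list[float] = []
        if self.free_rf:
            rr_pin = fixed.get("r_reject")
            denom = 1.0 if rr_pin is None else max(1.0 - rr_pin, 1e-12)
            theta.append(params.r_false / denom)
        if self.free_rr:
            denom = max(1.0 - params.r_false, 1e-12)
            theta.append(params.r_reject / denom)
        if self.free_d:
            theta.append(params.d_prime)
        if self.free_s:
            theta.append(params.variance_ratio)
        t = criteria.thresholds
        theta.append(t[0])
        theta.extend(np.diff(t))
        vec = np.asarray(theta, dtype=float)
        # nudge strictly inside the box so TRF has room to move
        span = self.upper - self.lower
        return np.clip(vec, self.lower + 1e-9 * span, self.upper - 1e-9 * span)

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        vec = self.lower + (self.upper - self.lower) * rng.random(self.n_free)
        # keep random criterion increments modest so thresholds stay in range
        vec[self.n_process + 1 :] = np.minimum(vec[self.n_process + 1 :], 1.5)
        return vec


@dataclass(frozen=True, eq=False)
class FitResult:
    """Outcome of a model fit.

    ``objective`` is the achieved SSE (method ``"sse"``) or negative
    log-likelihood (method ``"mle"``).  ``per_point_residuals`` holds the
    (x, y) residual pair for every fitted fROC point.
    ``information_criteria`` (AIC/BIC) is populated for likelihood fits.
    """

    params: MixtureParams
    criteria: CriteriaVector
    objective: float
    per_point_residuals: np.ndarray
    converged: bool
    n_points: int
    method: str
    starts_used: int
    information_criteria: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.objective < -1e-9:
            raise ValueError("objective must be >= 0")
        if self.per_point_residuals.shape[0] != self.n_points:
            raise ValueError("residual count must equal n_points")

    def to_dict(self) -> dict:
        out = {
            "r_false": self.params.r_false,
            "r_reject": self.params.r_reject,
            "d_prime": self.params.d_prime,
            "variance_ratio": self.params.variance_ratio,
            "thresholds": self.criteria.thresholds.tolist(),
            "objective": self.objective,
            "per_point_residuals": self.per_point_residuals.tolist(),
            "converged": self.converged,
            "n_points": self.n_points,
            "method": self.method,
            "starts_used": self.starts_used,
        }
        if self.information_criteria is not None:
            out["information_criteria"] = dict(self.information_criteria)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_csv_row(
        self, study_id: str = "", condition: str = ""
    ) -> dict[str, object]:
        """Flat summary row in the multi-study layout."""
        return {
            "study_id": study_id,
            "condition": condition,
            "r_false": self.params.r_false,
            "r_reject": self.params.r_reject,
            "d_prime": self.params.d_prime,
            "sse": self.objective if self.method == "sse" else float("nan"),
            "converged": self.converged,
        }


def _moment_start(
    froc: FrocPoints, codec: _ParamCodec, config: FitConfig
) -> np.ndarray:
    """Method-of-moments initial guess from the observed points."""
    x, y = froc.x, froc.y
    m = len(froc)
    eps = 1e-4
    if m >= 2 and x[1] - x[0] > 1e-6:
        slope0 = (y[1] - y[0]) / (x[1] - x[0])
        rf = y[0] - slope0 * x[0]
    else:
        rf = y[0]
    if m >= 2 and x[-1] - x[-2] > 1e-6:
        slope1 = (y[-1] - y[-2]) / (x[-1] - x[-2])
        rr = 1.0 - (y[-1] + slope1 * (1.0 - x[-1]))
    else:
        rr = 1.0 - y[-1]
    rf = float(np.clip(rf, 0.0, 0.8))
    rr = float(np.clip(rr, 0.0, 0.8))
    if rf + rr > 0.9:
        scale = 0.9 / (rf + rr)
        rf *= scale
        rr *= scale
    mid = m // 2
    d = ndtri(np.clip(y[mid], eps, 1 - eps)) - ndtri(np.clip(x[mid], eps, 1 - eps))
    d_lo, d_hi = config.bound("d_prime")
    d = float(np.clip(d, d_lo, d_hi))
    if "d_prime" in config.fixed:
        d = config.fixed["d_prime"]
    # criteria from the new-item proportions: x_j = Phi(-d/2 - t_j)
    t_desc = -d / 2.0 - ndtri(np.clip(x, eps, 1 - eps))
    t = np.sort(t_desc)
    t_lo, t_hi = config.bound("t_first")
    t = np.clip(t, t_lo, t_hi)
    step_lo = config.bound("t_step")[0]
    for j in range(1, t.size):
        t[j] = max(t[j], t[j - 1] + max(step_lo, 1e-3))
    params = MixtureParams(
        r_false=rf if "r_false" not in config.fixed else config.fixed["r_false"],
        r_reject=min(rr, 1.0 - rf)
        if "r_reject" not in config.fixed
        else config.fixed["r_reject"],
        d_prime=d,
        variance_ratio=config.fixed.get("variance_ratio", 1.0),
    )
    return codec.encode(params, CriteriaVector(t))


def _lexicographic_better(cand: MixtureParams, best: MixtureParams) -> bool:
    key_c = (cand.r_false, cand.r_reject, cand.d_prime)
    key_b = (best.r_false, best.r_reject, best.d_prime)
    return key_c < key_b


def _multistart(
    codec: _ParamCodec,
    objective_solver,
    froc: FrocPoints,
    config: FitConfig,
):
    """Run seeded multi-start local optimisation; pick the best solution.

    ``objective_solver(theta0) -> (objective, theta, success)`` runs one
    local optimisation.  Equal-objective optima (within 1e-10) are broken
    by the lexicographically smallest (r_false, r_reject, d_prime).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    starts = [_moment_start(froc, codec, config)]
    for _ in range(config.n_starts - 1):
        starts.append(codec.random_start(rng))
    best = None
    for theta0 in starts:
        obj, theta, success = objective_solver(theta0)
        params, criteria = codec.decode(theta)
        cand = (obj, params, criteria, theta, success)
        if best is None or obj < best[0] - _TIE_TOL:
            best = cand
        elif abs(obj - best[0]) <= _TIE_TOL and _lexicographic_better(
            params, best[1]
        ):
            best = cand
    return best


def _warn_small_samples(n_lure: int, n_new: int) -> None:
    if 0 < n_lure < MIN_TRIALS_RECOMMENDED or 0 < n_new < MIN_TRIALS_RECOMMENDED:
        warnings.warn(
            f"fewer than {MIN_TRIALS_RECOMMENDED} lure or new trials "
            f"(n_lure={n_lure}, n_new={n_new}); individual-level fROCs "
            "this sparse give unstable parameter estimates",
            UserWarning,
            stacklevel=3,
        )


def fit_sse(froc: FrocPoints, config: FitConfig | None = None) -> FitResult:
    """Fit the mixture model to observed fROC points by least squares.

    Minimises ``sum_j (x_obs_j - x_pred_j)^2 + (y_obs_j - y_pred_j)^2``
    jointly over (R_f, R_r, d') and the criteria, honouring any pinned
    parameters in ``config.fixed``.  Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    m = len(froc)
    if m < 2:
        raise ValueError("fit_sse needs at least 2 fROC points")
    codec = _ParamCodec(config, n_thresholds=m)
    if m < 4 and codec.n_process == 3:
        warnings.warn(
            f"only {m} fROC points for 3 free process parameters plus "
            f"{m} criteria; estimates may be poorly constrained",
            UserWarning,
            stacklevel=2,
        )
    _warn_small_samples(froc.n_lure, froc.n_new)
    degenerate = bool(
        np.all(froc.x == froc.x[0]) and np.all(froc.y == froc.y[0]) and m > 1
    )

    x_obs, y_obs = froc.x, froc.y

    def residuals(theta: np.ndarray) -> np.ndarray:
        params, criteria = codec.decode(theta)
        pred = predicted_froc(params, criteria)
        return np.concatenate([x_obs - pred.x, y_obs - pred.y])

    def solve(theta0: np.ndarray):
        res = least_squares(
            residuals,
            theta0,
            bounds=(codec.lower, codec.upper),
            method="trf",
            xtol=config.tolerance,
            ftol=config.tolerance,
            gtol=config.tolerance,
            max_nfev=2000,
        )
        return 2.0 * res.cost, res.x, bool(res.success)

    obj, params, criteria, theta, success = _multistart(codec, solve, froc, config)
    resid = residuals(theta)
    per_point = np.column_stack([resid[:m], resid[m:]])
    return FitResult(
        params=params,
        criteria=criteria,
        objective=float(obj),
        per_point_residuals=per_point,
        converged=bool(success and not degenerate),
        n_points=m,
        method="sse",
        starts_used=config.n_starts,
    )


def fit_mle(
    lure: ConfidenceCounts,
    new: ConfidenceCounts,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit by maximising the product-multinomial likelihood of the counts.

    Lure and new rating counts are modelled as independent multinomials
    with cell probabilities from :func:`~frocfit.model.bin_probabilities`;
    probabilities are floored at 1e-12 before logging.  Reports AIC/BIC.
    """
    config = config or FitConfig(method="mle")
    if lure.total == 0 or new.total == 0:
        raise ValueError("both count tables must contain trials")
    if lure.scale != new.scale:
        raise ValueError("lure and new counts must share one rating scale")
    _warn_small_samples(lure.total, new.total)
    k = lure.scale.k_levels
    m = k - 1
    codec = _ParamCodec(config, n_thresholds=m)
    froc = build_froc(lure, new)
    degenerate = bool(
        np.all(froc.x == froc.x[0]) and np.all(froc.y == froc.y[0])
    )
    c_lure = lure.counts.astype(float)
    c_new = new.counts.astype(float)
    floor = 1e-12

    def nll(theta: np.ndarray) -> float:
        params, criteria = codec.decode(theta)
        bp = bin_probabilities(params, criteria)
        return -float(
            c_lure @ np.log(np.maximum(bp.lure, floor))
            + c_new @ np.log(np.maximum(bp.new, floor))
        )

    bounds = list(zip(codec.lower, codec.upper))

    def solve(theta0: np.ndarray):
        res = minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": max(config.tolerance, 1e-14), "maxiter": 1000},
        )
        return float(res.fun), res.x, bool(res.success)

    obj, params, criteria, theta, success = _multistart(codec, solve, froc, config)
    pred = predicted_froc(params, criteria)
    per_point = np.column_stack([froc.x - pred.x, froc.y - pred.y])
    n_free = codec.n_free
    n_total = lure.total + new.total
    info = {
        "aic": 2.0 * n_free + 2.0 * obj,
        "bic": n_free * float(np.log(n_total)) + 2.0 * obj,
        "n_free_parameters": float(n_free),
    }
    return FitResult(
        params=params,
        criteria=criteria,
        objective=float(obj),
        per_point_residuals=per_point,
        converged=bool(success and not degenerate),
        n_points=m,
        method="mle",
        starts_used=config.n_starts,
        information_criteria=info,
    )


def fit_constrained(data, config: FitConfig) -> FitResult:
    """Fit a nested variant with parameters pinned via ``config.fixed``.

    ``data`` is either a :class:`FrocPoints` (method ``"sse"``) or a
    ``(lure_counts, new_counts)`` pair (either method).  Typical pins:
    ``{"r_reject": 0}`` for a dual-process-style model, ``{"r_false": 0,
    "r_reject": 0}`` for equal-variance SDT (add ``free_variance_ratio``
    for UVSD), ``{"d_prime": 0}`` for the linear two-threshold case.
    The achieved objective can never beat the corresponding full fit.
    """
    if isinstance(data, FrocPoints):
        if config.method == "mle":
            raise ValueError("mle fitting needs count tables, not fROC points")
        return fit_sse(data, config)
    lure, new = data
    if config.method == "mle":
        return fit_mle(lure, new, config)
    return fit_sse(build_froc(lure, new), config)


@dataclass(frozen=True, eq=False)
class FitReport:
    """Goodness-of-fit summary recomputed independently of the optimiser."""

    sse: float
    per_point_residuals: np.ndarray
    max_abs_residual: float
    predicted: FrocPoints
    curve_x: np.ndarray
    curve_y: np.ndarray


def goodness_of_fit(result: FitResult, observed: FrocPoints) -> FitReport:
    """Recompute the SSE and residuals of a fit from the model equations.

    Independent of any optimiser internals: the predicted points are
    re-evaluated from the fitted parameters and criteria, and the smooth
    model ROC is sampled for plotting.
    """
    if len(observed) != len(result.criteria):
        raise ValueError(
            f"observed fROC has {len(observed)} points but the fit used "
            f"{len(result.criteria)} criteria"
        )
    pred = predicted_froc(result.params, result.criteria)
    resid = np.column_stack([observed.x - pred.x, observed.y - pred.y])
    sse = float(np.sum(resid**2))
    grid = np.linspace(1e-4, 1 - 1e-4, 201)
    return FitReport(
        sse=sse,
        per_point_residuals=resid,
        max_abs_residual=float(np.max(np.abs(resid))),
        predicted=pred,
        curve_x=grid,
        curve_y=np.asarray(roc_curve(result.params, grid)),
    )


@dataclass(frozen=True)
class GridSearchResult:
    """Best point found by the exhaustive profile-grid search."""

    objective: float
    r_false: float
    r_reject: float
    d_prime: float


def grid_search_sse(
    froc: FrocPoints,
    n_grid: int = 20,
    n_thresh_grid: int = 481,
    refine: bool = True,
) -> GridSearchResult:
    """Coarse exhaustive SSE search used as an optimiser oracle.

    Scans an ``n_grid``-point lattice over each of R_f, R_r (on [0, 1],
    keeping R_f + R_r <= 1) and d' (on [0, 6]).  For each process triple
    the criteria are profiled out: each threshold enters the SSE through
    its own fROC point only, so the per-point 1-D minimisation over a
    dense threshold grid (optionally polished by a bounded scalar solver)
    yields the minimal SSE attainable at that triple.
    """
    x_obs, y_obs = froc.x, froc.y
    rf_grid = np.linspace(0.0, 1.0, n_grid)
    rr_grid = np.linspace(0.0, 1.0, n_grid)
    d_grid = np.linspace(0.0, 6.0, n_grid)
    t_grid = np.linspace(-6.0, 6.0, n_thresh_grid)

    best_obj = np.inf
    best = (0.0, 0.0, 0.0)
    for d in d_grid:
        x_pred = ndtr(-d / 2.0 - t_grid)
        phi_l = ndtr(d / 2.0 - t_grid)
        dx2 = (x_obs[:, None] - x_pred[None, :]) ** 2
        for rf in rf_grid:
            for rr in rr_grid:
                if rf + rr > 1.0:
                    continue
                y_pred = rf + (1.0 - rf - rr) * phi_l
                cost = dx2 + (y_obs[:, None] - y_pred[None, :]) ** 2
                total = float(cost.min(axis=1).sum())
                if total < best_obj:
                    best_obj = total
                    best = (float(rf), float(rr), float(d))

    if refine:
        rf, rr, d = best

        def point_cost(t: float, j: int) -> float:
            xp = ndtr(-d / 2.0 - t)
            yp = rf + (1.0 - rf - rr) * ndtr(d / 2.0 - t)
            return (x_obs[j] - xp) ** 2 + (y_obs[j] - yp) ** 2

        refined = 0.0
        for j in range(len(froc)):
            res = minimize_scalar(
                point_cost, args=(j,), bounds=(-8.0, 8.0), method="bounded",
                options={"xatol": 1e-10},
            )
            refined += float(res.fun)
        best_obj = min(best_obj, refined)

    return GridSearchResult(
        objective=best_obj, r_false=best[0], r_reject=best[1], d_prime=best[2]
    )
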