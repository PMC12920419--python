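"""Three-component mixture signal-detection model of similar-lure recognition.

A similar lure can be *falsely recollected* (probability ``r_false``),
producing a highest-confidence "old" response; *recollected-to-reject*
(probability ``r_reject``), producing a highest-confidence "new" response;
or, with the remaining probability, judged on perceived familiarity alone.
Familiarity strengths are Gaussian: new items at -d'/2 with unit SD, lures
at +d'/2 with SD ``variance_ratio`` (1 by default, the equal-variance
model).  A lure judged on familiarity is called "old" at criterion ``c``
whenever its familiarity exceeds ``c``:

    P("old" | lure) = R_f + (1 - R_f - R_r) * Phi(d'/2 - c)
    P("old" | new)  = Phi(-d'/2 - c)

Eliminating ``c`` gives the model ROC

    y(x) = R_f + (1 - R_f - R_r) * Phi(d' + Phi^{-1}(x)),

whose left intercept is R_f, right intercept 1 - R_r, and whose curvature
grows with d'.  All normal CDF/quantile evaluations go through SciPy's
erfc-based double-precision routines (`ndtr`/`ndtri`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .roc_data import FrocPoints

__all__ = [
    "MixtureParams",
    "CriteriaVector",
    "BinProbabilities",
    "lure_acceptance_prob",
    "new_acceptance_prob",
    "predicted_froc",
    "roc_curve",
    "bin_probabilities",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class MixtureParams:
    """Process parameters of the lure-recognition mixture model.

    Parameters
    ----------
    r_false:
        Probability of false recollection (maps to the highest rating).
    r_reject:
        Probability of recollection rejection (maps to the lowest rating).
    d_prime:
        False familiarity: mean separation of lure and new familiarity
        distributions in new-item SD units; must be >= 0.
    variance_ratio:
        SD of the lure familiarity distribution relative to the new-item
        distribution.  1 (default) is the equal-variance model; freeing it
        with ``r_false = r_reject = 0`` gives the unequal-variance
        signal-detection model.
    """

    r_false: float = 0.0
    r_reject: float = 0.0
    d_prime: float = 0.0
    variance_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_false <= 1.0:
            raise ValueError(f"r_false must be in [0, 1], got {self.r_false}")
        if not 0.0 <= self.r_reject <= 1.0:
            raise ValueError(f"r_reject must be in [0, 1], got {self.r_reject}")
        if self.r_false + self.r_reject > 1.0 + 1e-12:
            raise ValueError(
                f"r_false + r_reject must not exceed 1, got "
                f"{self.r_false} + {self.r_reject}"
            )
        if self.d_prime < 0.0:
            raise ValueError(f"d_prime must be >= 0, got {self.d_prime}")
        if self.variance_ratio <= 0.0:
            raise ValueError(
                f"variance_ratio must be > 0, got {self.variance_ratio}"
            )

    @property
    def familiarity_weight(self) -> float:
        """Mixture weight of the familiarity-only process, 1 - R_f - R_r."""
        return 1.0 - self.r_false - self.r_reject

    def to_json(self) -> str:
        return json.dumps(
            {
                "r_false": self.r_false,
                "r_reject": self.r_reject,
                "d_prime": self.d_prime,
                "variance_ratio": self.variance_ratio,
            }
        )


@dataclass(frozen=True, eq=False)
class CriteriaVector:
    """Ordered response criteria t_1 < ... < t_{K-1} on the familiarity axis.

    Rating j is given when familiarity falls in [t_{j-1}, t_j), with
    t_0 = -inf and t_K = +inf.  Units are new-item standard deviations on
    the common axis where new items sit at -d'/2 and lures at +d'/2.
    """

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if t.ndim != 1 or t.size == 0:
            raise ValueError("thresholds must be a non-empty 1-D vector")
        if not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        t.setflags(write=False)
        object.__setattr__(self, "thresholds", t)

    @property
    def k_levels(self) -> int:
        """Number of rating categories implied by the criteria."""
        return self.thresholds.size + 1

    def __len__(self) -> int:
        return self.thresholds.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaVector):
            return NotImplemented
        return np.array_equal(self.thresholds, other.thresholds)

    def to_json(self) -> str:
        return json.dumps({"thresholds": self.thresholds.tolist()})


#: Symmetric 5-threshold default for a 6-point scale; spans the informative
#: range of the standard normal and yields well-spread fROC points.
DEFAULT_CRITERIA = CriteriaVector(
    thresholds=np.array([-1.5, -0.75, 0.0, 0.75, 1.5])
)


def lure_acceptance_prob(params: MixtureParams, c) -> np.ndarray | float:
    """P("old" | lure) at criterion ``c``.

    R_f + (1 - R_f - R_r) * Phi((d'/2 - c) / variance_ratio); lies in
    [R_f, 1 - R_r] and is non-increasing in ``c``.
    """
    c_arr = np.asarray(c, dtype=float)
    out = params.r_false + params.familiarity_weight * ndtr(
        (params.d_prime / 2.0 - c_arr) / params.variance_ratio
    )
    return out if c_arr.ndim else float(out)


def new_acceptance_prob(params: MixtureParams, c) -> np.ndarray | float:
    """P("old" | new) at criterion ``c``: Phi(-d'/2 - c)."""
    c_arr = np.asarray(c, dtype=float)
    out = ndtr(-params.d_prime / 2.0 - c_arr)
    return out if c_arr.ndim else float(out)


def predicted_froc(params: MixtureParams, criteria: CriteriaVector) -> FrocPoints:
    """Model fROC at the given criteria, strictest criterion first.

    Point i pairs P("old"|new) with P("old"|lure) at threshold
    t_{K-i}, i = 1..K-1, so x and y are non-decreasing as in observed
    fROCs cumulated from the highest confidence downward.
    """
    t_desc = criteria.thresholds[::-1]
    return FrocPoints(
        x=new_acceptance_prob(params, t_desc),
        y=lure_acceptance_prob(params, t_desc),
        n_new=0,
        n_lure=0,
    )


def roc_curve(params: MixtureParams, far_grid) -> np.ndarray:
    """Continuous model ROC y(x) on a grid of false-alarm rates in (0, 1).

    y(x) = R_f + (1 - R_f - R_r) * Phi((d' + Phi^{-1}(x)) / variance_ratio).
    y -> R_f as x -> 0 and y -> 1 - R_r as x -> 1 (the projected left and
    right intercepts of the fitted fROC).
    """
    x = np.asarray(far_grid, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("far_grid values must lie strictly inside (0, 1)")
    z = ndtri(x)
    out = params.r_false + params.familiarity_weight * ndtr(
        (params.d_prime + z) / params.variance_ratio
    )
    return out if x.ndim else float(out)


@dataclass(frozen=True, eq=False)
class BinProbabilities:
    """Per-rating response probabilities for lures and new items."""

    lure: np.ndarray
    new: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lure", "new"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < -1e-12):
                raise ValueError(f"{name} bin probabilities must be >= 0")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} bin probabilities must sum to 1")
            v = np.clip(v, 0.0, None)
            v.setflags(write=False)
            object.__setattr__(self, name, v)


def bin_probabilities(
    params: MixtureParams, criteria: CriteriaVector
) -> BinProbabilities:
    """Rating-bin probabilities implied by the model.

    For lures, rating K receives the entire false-recollection mass plus
    the familiarity tail above t_{K-1}; rating 1 receives the entire
    recollection-rejection mass plus the familiarity tail below t_1;
    interior ratings receive familiarity mass between consecutive
    thresholds.  New items are purely familiarity-driven, N(-d'/2, 1).
    Cumulating from the top rating downward telescopes back to the
    acceptance probabilities at each threshold.
    """
    t = criteria.thresholds
    # survivor values P(rating >= j+1) at each t_j, ascending j
    surv_lure = np.asarray(lure_acceptance_prob(params, t))
    surv_new = np.asarray(new_acceptance_prob(params, t))
    lure = -np.diff(np.concatenate([[1.0], surv_lure, [0.0]]))
    new = -np.diff(np.concatenate([[1.0], surv_new, [0.0]]))
    return BinProbabilities(lure=lure, new=new)
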