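"""Trial-level simulation under the mixture model and recovery harnesses.

Each simulated lure trial first draws its generating process from
Categorical(R_f, R_r, 1 - R_f - R_r).  False recollection forces the
highest confidence rating, recollection rejection the lowest; the
familiarity-only remainder draws a strength from N(+d'/2, variance_ratio^2)
and is binned by the response criteria.  New items are always
familiarity-driven, drawn from N(-d'/2, 1).

Randomness follows a fixed substream protocol: one master seed, with the
process draw, the lure familiarity draw, the new-item familiarity draw and
every recovery replicate on separate deterministic substreams, so enlarging
a simulation never perturbs earlier draws and regression tests stay stable.

:func:`recovery_experiment` closes the loop (simulate -> fit -> compare to
truth) and :func:`dissociation_scenarios` generates paired-condition
datasets mimicking the three qualitative signatures reported for
recollect-to-reject instructions, lure-similarity manipulations, and
healthy ageing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .fitting import FitConfig, FitResult, fit_mle, fit_sse
from .model import (
    DEFAULT_CRITERIA,
    CriteriaVector,
    MixtureParams,
)
from .roc_data import ConfidenceCounts, FrocPoints, ItemClass, RatingScale, build_froc

__all__ = [
    "simulate_trials",
    "simulate_condition",
    "expected_proportions",
    "recovery_experiment",
    "RecoverySummary",
    "DissociationScenario",
    "dissociation_scenarios",
]

_PROCESS_NAMES = ("false_recollect", "recollection_reject", "familiarity_only")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))
    )


def child_seed(seed: int, *key: int) -> int:
    """A derived integer seed (< 2^31), stable across runs."""
    ss = np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_trials(
    params: MixtureParams,
    criteria: CriteriaVector,
    n_lure: int,
    n_new: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate per-trial records.

    Returns a DataFrame with columns ``item_class``, ``process``,
    ``familiarity`` (the Gaussian strength draw; drawn for every trial but
    consulted only on familiarity-driven ones) and ``rating`` (1..K).
    """
    if n_lure < 0 or n_new < 0:
        raise ValueError("trial counts must be non-negative")
    t = criteria.thresholds
    k = criteria.k_levels

    u = _stream(seed, 0).random(n_lure)
    proc = np.full(n_lure, 2, dtype=np.int64)  # familiarity_only
    proc[u < params.r_false + params.r_reject] = 1  # recollection_reject
    proc[u < params.r_false] = 0  # false_recollect

    f_lure = params.d_prime / 2.0 + params.variance_ratio * _stream(
        seed, 1
    ).standard_normal(n_lure)
    rating_lure = np.searchsorted(t, f_lure, side="right") + 1
    rating_lure[proc == 0] = k
    rating_lure[proc == 1] = 1

    f_new = -params.d_prime / 2.0 + _stream(seed, 2).standard_normal(n_new)
    rating_new = np.searchsorted(t, f_new, side="right") + 1

    return pd.DataFrame(
        {
            "item_class": np.concatenate(
                [
                    np.repeat(ItemClass.LURE.value, n_lure),
                    np.repeat(ItemClass.NEW.value, n_new),
                ]
            ),
            "process": np.concatenate(
                [
                    np.asarray(_PROCESS_NAMES)[proc],
                    np.repeat("familiarity_only", n_new),
                ]
            ),
            "familiarity": np.concatenate([f_lure, f_new]),
            "rating": np.concatenate([rating_lure, rating_new]).astype(np.int64),
        }
    )


def simulate_condition(
    params: MixtureParams,
    criteria: CriteriaVector,
    n_lure: int,
    n_new: int,
    seed: int,
) -> tuple[ConfidenceCounts, ConfidenceCounts]:
    """Simulate one condition and tabulate (lure_counts, new_counts)."""
    trials = simulate_trials(params, criteria, n_lure, n_new, seed)
    k = criteria.k_levels
    scale = RatingScale(k_levels=k)
    lure_ratings = trials.loc[trials["item_class"] == "lure", "rating"].to_numpy()
    new_ratings = trials.loc[trials["item_class"] == "new", "rating"].to_numpy()
    lure_counts = np.bincount(lure_ratings, minlength=k + 1)[1:]
    new_counts = np.bincount(new_ratings, minlength=k + 1)[1:]
    return (
        ConfidenceCounts(ItemClass.LURE, lure_counts, scale),
        ConfidenceCounts(ItemClass.NEW, new_counts, scale),
    )


def expected_proportions(
    params: MixtureParams, criteria: CriteriaVector
) -> FrocPoints:
    """Infinite-sample fROC implied by the model.

    Evaluated through the combined ROC identity
    ``P(old|lure) = P(old|new) + R_f + (1 - R_f - R_r) * Phi((d'/2 - c)/s)
    - Phi(-d'/2 - c)`` — an algebraically independent route that must agree
    with the acceptance-probability evaluation to machine precision.
    Trial totals are recorded as 0 to mark the points as analytic.
    """
    t = criteria.thresholds[::-1]
    x = ndtr(-params.d_prime / 2.0 - t)
    y = (
        x
        + params.r_false
        + params.familiarity_weight
        * ndtr((params.d_prime / 2.0 - t) / params.variance_ratio)
        - ndtr(-params.d_prime / 2.0 - t)
    )
    return FrocPoints(x=x, y=y, n_new=0, n_lure=0)


@dataclass(frozen=True, eq=False)
class RecoverySummary:
    """Bias/RMSE summary of a simulate-then-fit recovery experiment."""

    true_params: MixtureParams
    n_reps: int
    n_lure: int
    n_new: int
    seed: int
    mean_estimate: dict[str, float]
    bias: dict[str, float]
    rmse: dict[str, float]
    n_failed: int
    estimates: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "true_params": {
                "r_false": self.true_params.r_false,
                "r_reject": self.true_params.r_reject,
                "d_prime": self.true_params.d_prime,
            },
            "n_reps": self.n_reps,
            "n_lure": self.n_lure,
            "n_new": self.n_new,
            "seed": self.seed,
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "rmse": self.rmse,
            "n_failed": self.n_failed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def recovery_experiment(
    true_params: MixtureParams,
    criteria: CriteriaVector,
    n_lure: int,
    n_new: int,
    n_reps: int,
    seed: int,
    config: FitConfig | None = None,
) -> RecoverySummary:
    """Simulate ``n_reps`` datasets from known parameters and refit each.

    Replicate seeds derive deterministically from the master seed.  Fit
    failures (exceptions) are counted in ``n_failed`` rather than silently
    dropped; converged flags travel with the per-replicate estimates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or FitConfig()
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        rep_seed = child_seed(seed, 100, rep)
        lure, new = simulate_condition(true_params, criteria, n_lure, n_new, rep_seed)
        try:
            if config.method == "mle":
                fit = fit_mle(lure, new, config)
            else:
                fit = fit_sse(build_froc(lure, new), config)
        except Exception:  # noqa: BLE001 - failures are data, not crashes
            n_failed += 1
            continue
        rows.append(
            {
                "rep": rep,
                "r_false": fit.params.r_false,
                "r_reject": fit.params.r_reject,
                "d_prime": fit.params.d_prime,
                "objective": fit.objective,
                "converged": fit.converged,
            }
        )
    estimates = pd.DataFrame(rows)
    truth = {
        "r_false": true_params.r_false,
        "r_reject": true_params.r_reject,
        "d_prime": true_params.d_prime,
    }
    mean_est, bias, rmse = {}, {}, {}
    for name, true_val in truth.items():
        vals = estimates[name].to_numpy() if len(estimates) else np.array([])
        if vals.size:
            mean_est[name] = float(vals.mean())
            bias[name] = float(vals.mean() - true_val)
            rmse[name] = float(np.sqrt(np.mean((vals - true_val) ** 2)))
        else:
            mean_est[name] = bias[name] = rmse[name] = float("nan")
    return RecoverySummary(
        true_params=true_params,
        n_reps=n_reps,
        n_lure=n_lure,
        n_new=n_new,
        seed=seed,
        mean_estimate=mean_est,
        bias=bias,
        rmse=rmse,
        n_failed=n_failed,
        estimates=estimates,
    )


@dataclass(frozen=True)
class DissociationScenario:
    """A paired-condition synthetic dataset with a known process signature.

    ``conditions`` maps a condition label to
    ``(true_params, lure_counts, new_counts)``; ``expected_signs`` gives
    the sign (+1, -1 or 0) of the condition-B-minus-condition-A difference
    expected for each process parameter.
    """

    name: str
    description: str
    condition_a: str
    condition_b: str
    conditions: dict[str, tuple[MixtureParams, ConfidenceCounts, ConfidenceCounts]]
    expected_signs: dict[str, int]


#: True parameter pairs for the three qualitative dissociations: a
#: selective recollection-rejection boost under recollect-to-reject
#: instructions; a joint false-recollection + false-familiarity increase
#: with stronger lure similarity; opposed false-recollection /
#: recollection-rejection shifts with ageing at constant familiarity.
_SCENARIO_SPECS = [
    (
        "recollect_to_reject",
        "Standard instructions vs. an instructed recollect-to-reject "
        "strategy: selective increase in recollection rejection.",
        "standard",
        MixtureParams(r_false=0.15, r_reject=0.15, d_prime=1.0),
        "recollect_to_reject",
        MixtureParams(r_false=0.15, r_reject=0.40, d_prime=1.0),
        {"r_false": 0, "r_reject": +1, "d_prime": 0},
    ),
    (
        "lure_similarity",
        "Weakly vs. strongly related lures: joint increase in false "
        "recollection and false familiarity, recollection rejection flat.",
        "weak",
        MixtureParams(r_false=0.05, r_reject=0.20, d_prime=0.4),
        "strong",
        MixtureParams(r_false=0.25, r_reject=0.20, d_prime=1.2),
        {"r_false": +1, "r_reject": 0, "d_prime": +1},
    ),
    (
        "aging",
        "Young vs. older adults: more false recollection, less "
        "recollection rejection, unchanged false familiarity.",
        "young",
        MixtureParams(r_false=0.10, r_reject=0.35, d_prime=0.8),
        "older",
        MixtureParams(r_false=0.30, r_reject=0.10, d_prime=0.8),
        {"r_false": +1, "r_reject": -1, "d_prime": 0},
    ),
]


def dissociation_scenarios(
    seed: int,
    n_per_class: int = 10_000,
    criteria: CriteriaVector = DEFAULT_CRITERIA,
) -> list[DissociationScenario]:
    """Three paired-condition datasets with known process signatures.

    Each condition simulates ``n_per_class`` lure and new trials.  The two
    conditions of a scenario share one random substream (common random
    numbers), the synthetic analogue of a within-subject design: the
    condition difference then reflects the parameter manipulation rather
    than independent sampling noise.  Fitting both conditions and
    differencing the estimates should reproduce the scenario's
    ``expected_signs`` (zero-entries staying small).
    """
    scenarios = []
    for idx, (name, desc, lab_a, par_a, lab_b, par_b, signs) in enumerate(
        _SCENARIO_SPECS
    ):
        conditions = {}
        pair_seed = child_seed(seed, idx)
        for label, par in ((lab_a, par_a), (lab_b, par_b)):
            lure, new = simulate_condition(
                par, criteria, n_per_class, n_per_class, pair_seed
            )
            conditions[label] = (par, lure, new)
        scenarios.append(
            DissociationScenario(
                name=name,
                description=desc,
                condition_a=lab_a,
                condition_b=lab_b,
                conditions=conditions,
                expected_signs=signs,
            )
        )
    return scenarios
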