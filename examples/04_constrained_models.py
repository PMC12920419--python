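"""Compare the full mixture model against its nested special cases.

The same simulated fROC is fit by the full three-process model and by
constrained variants: no recollection rejection (dual-process style), no
recollection at all (equal-variance signal detection), and no familiarity
(the linear two-threshold case).  Pinning parameters can only raise the
achieved SSE; a large jump for a constraint says the data need the process
that was removed.
"""

from frocfit import (
    DEFAULT_CRITERIA,
    FitConfig,
    MixtureParams,
    build_froc,
    fit_constrained,
    fit_sse,
    simulate_condition,
)

truth = MixtureParams(r_false=0.15, r_reject=0.25, d_prime=0.9)
lure, new = simulate_condition(truth, DEFAULT_CRITERIA, 20_000, 20_000, seed=3)
froc = build_froc(lure, new)

full = fit_sse(froc, FitConfig(n_starts=10, seed=0))
print(f"full model:            SSE = {full.objective:.2e}  "
      f"(R_f={full.params.r_false:.3f}, R_r={full.params.r_reject:.3f}, "
      f"d'={full.params.d_prime:.3f})")

variants = {
    "no recollection rejection": {"r_reject": 0.0},
    "equal-variance SDT": {"r_false": 0.0, "r_reject": 0.0},
    "no familiarity (linear)": {"d_prime": 0.0},
}
for name, fixed in variants.items():
    res = fit_constrained(froc, FitConfig(n_starts=10, seed=0, fixed=fixed))
    print(f"{name:<25}  SSE = {res.objective:.2e}")
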