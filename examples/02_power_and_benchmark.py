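"""Power of relationship inference and the estimator benchmark.

Computes PW_R — the simulated power to discriminate half-siblings (and
parent-offspring pairs) from unrelated dyads at confidence level 0.05 — and
the per-category mean / variance / MSE benchmark that ranks the ML
estimator against the Queller-Goodnight moment estimator.
"""

from kindyad import CATEGORIES, benchmark_estimators, gen_frequencies, pw_r

panel = gen_frequencies(18, 8, float("inf"), seed=1)

for primary in ("HS", "PO"):
    res = pw_r(panel, CATEGORIES[primary], CATEGORIES["UR"], alpha=0.05,
               n_sims=5000, seed=3)
    print(f"PW_R {primary} vs UR: {res.pw_r:.2f} (+- {res.mc_se:.3f} MC SE)")
# PO vs UR saturates at 1.00 on this panel; HS vs UR is substantially lower,
# which is why dyad classification needs explicit cutoffs.

rep = benchmark_estimators(panel, n_per_category=500, seed=4)
print(rep.per_category.round(4).to_string(index=False))
print("pooled correlation with expected r:",
      {k: round(v, 3) for k, v in rep.correlation.items()})
# The ML estimator should show the higher pooled correlation; that is the
# criterion for choosing it for all downstream classification.
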