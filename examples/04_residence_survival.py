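"""Kin effects on male residence time and high-rank tenure.

Generates demographic records in which co-resident kin lower a male's
hazard of leaving the group (log-hazard -2.36) and extend his high-rank
tenure (+12.7 months), then recovers those effects with the Cox model, the
one-year-stay likelihood-ratio test, the tenure linear model, and a cluster
bootstrap over males.
"""

from kindyad import (DemographyConfig, cluster_bootstrap, cox_fit,
                     gen_demography, km_curve, stay_one_year_test,
                     tenure_model)

recs = gen_demography(DemographyConfig(n_males=300, seed=9))

cox = cox_fit(recs, ["kin_at_entry", "natal_disperser"],
              interaction=("kin_at_entry", "natal_disperser"))
for name, fit in cox.items():
    print(f"Cox {name}: beta = {fit.beta:.2f}, SE = {fit.se:.2f}, "
          f"LR chi2 = {fit.chi2_lr:.2f}, P = {fit.p_lr:.3g}")
# kin_at_entry should recover ~ -2.36 (a hazard ratio near 0.09: males with
# kin leave far more slowly); the other terms carry no simulated effect.

stay = stay_one_year_test(recs, "kin_at_entry")
print(f"1-year stay (kin at entry): LR chi2 = {stay.chi2_lr:.2f}, "
      f"P = {stay.p_lr:.3g} ({stay.note})")

tenure = tenure_model(recs, "kin_at_entry")
print(f"high-rank tenure: +{tenure.beta:.1f} months with kin "
      f"(SE {tenure.se:.1f}, P = {tenure.p_lr:.3g}, n = {tenure.n})")

boot = cluster_bootstrap(
    recs, lambda r: cox_fit(r, ["kin_at_entry"])["kin_at_entry"].beta,
    n_boot=200, seed=10)
print(f"cluster bootstrap of the Cox kin effect: "
      f"{boot['estimate']:.2f} (95% CI {boot['ci'][0]:.2f} "
      f"to {boot['ci'][1]:.2f})")

km = km_curve(recs, group_by="kin_at_entry")
for key, curve in sorted(km.items()):
    half = curve[curve["survival"] <= 0.5]
    med = half["time"].iloc[0] if len(half) else float("inf")
    print(f"median residence, kin={key}: {med} months")
# Kin-accompanied males should show a far longer median residence.
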