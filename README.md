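# kindyad

Dyadic relatedness estimation from microsatellite genotypes and downstream
tests of kin effects on male group residence — a pipeline for studying
nepotism in primate societies where males disperse and pedigrees are only
partially known.

In species such as long-tailed macaques, strong paternity skew means each
group cohort contains many paternal half-siblings, yet males leave their
natal group before breeding. Whether a dispersing male benefits from
relatives in his new group is a question that needs three pieces of
machinery, all provided here for users working from Python:

1. **Relatedness estimation** (`relatedness`): the likelihood of a genotype
   pair given the IBD coefficients k = (k0, k1, k2),

       Pr(g1, g2 | k) = k0·P0 + k1·P1 + k2·P2,

   maximised over the k-simplex to give the ML relatedness
   r̂ = k1/2 + k2 ("DyadML"), plus a symmetrized Queller-Goodnight moment
   estimator and a simulation benchmark (mean / variance / MSE per
   relationship category, pooled correlation with expected r).
2. **Kin classification** (`classification`, `power`): the power PW_R of a
   marker panel to separate relationship hypotheses; the A1 rule (empirical
   cutoff retaining the top 85% of known half-sib r̂) and the A2 rule
   (dual cutoffs from simulated half-sib and unrelated distributions with
   an unassigned exclusion zone); validation accounting and a Mendelian
   mother-offspring compatibility check.
3. **Residence and tenure models** (`residence`): Kaplan-Meier curves, a
   Cox partial-likelihood fit of residence time on kin presence, a logistic
   likelihood-ratio test of staying ≥ 1 year, a linear model of high-rank
   tenure, and a cluster bootstrap over males as a random-effects surrogate.

Because the motivating study's data are not deposited, `synthetic_data`
generates every input under known truth — Dirichlet marker panels,
IBD-model or pedigree (gene-drop) dyads with paternity skew and genotyping
error, and demographic records with a built-in kin effect — and
`genotype_io` reads/writes GenePop and CSV genotype tables with basic
marker QC (allele frequencies, Monte-Carlo Hardy-Weinberg test, Bonferroni).

## Worked example

```python
import numpy as np
from kindyad import (CATEGORIES, dyadml_estimate, gen_frequencies,
                     simulate_dyads, pw_r)

panel = gen_frequencies(n_loci=18, n_alleles=8,
                        concentration=float("inf"), seed=1)
dyads = simulate_dyads(CATEGORIES["HS"], panel, n=200, seed=2)
r_hat = [dyadml_estimate(d, panel).r for d in dyads]
print(f"mean r-hat = {np.mean(r_hat):.3f}")      # -> mean r-hat = 0.265

power = pw_r(panel, CATEGORIES["PO"], CATEGORIES["UR"],
             alpha=0.05, n_sims=5000, seed=3)
print(f"PW_R = {power.pw_r:.2f}")                # -> PW_R = 1.00
```

The half-sib mean sits near the expected r = 0.25 (slightly above, since
r̂ is truncated at 0), and the parent-offspring vs unrelated power
saturates: a single locus without a shared allele already excludes
parent-offspring, so 18 informative loci essentially always separate the
two hypotheses. The `examples/` directory walks through each capability —
estimation, power and benchmarking, cutoff derivation and validation, and
the survival analyses — as short narrative scripts.

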