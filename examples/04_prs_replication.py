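"""Project the instrument weights as a polygenic score and test the
cell-count mediation hypothesis.

The averaged instrument weights act as an MT-CN polygenic risk score in
an independent cohort: genotype probabilities collapse to expected
dosages, are hard-called at 0.5/1.5, and dotted with the weights.  If the
score's metabolic-trait association runs through blood composition,
adjusting for neutrophil and platelet counts should attenuate it.
"""

from mitomr import CohortConfig, simulate_cohort
from mitomr.mr import build_instrument
from mitomr.prs import (PrsWeights, compute_prs, expected_dosage, hard_call,
                        prepare_traits, prs_association)
from mitomr.stats import PenaltySpec

cfg = CohortConfig(n_samples=3000, n_variants=80, theta=0.4,
                   composition_loading=0.8, seed=31)
cohort = simulate_cohort(cfg)

inst = build_instrument(cohort.X, cohort.dosages, None,
                        PenaltySpec(kind="L2", selection="cross_validated"),
                        seed=32)
weights = PrsWeights(cohort.variant_ids, inst.beta_G_bar,
                     provenance="L2 instrument, synthetic cohort")

calls = hard_call(expected_dosage(cohort.gp_triplets))
prs = compute_prs(weights, calls, cohort.variant_ids)

traits = prepare_traits(cohort.cell_counts, cohort.sex)
extra = traits[["neutrophil", "platelet"]]

for name in ("neutrophil", "platelet", "lymphocyte"):
    r = prs_association(traits[name], prs, cohort.age, cohort.sex,
                        trait_name=name)
    print(f"{name:<11} ~ PRS: beta {r.beta:+.4f}, p {r.p:.2e}")

base = prs_association(cohort.Y, prs, cohort.age, cohort.sex,
                       trait_name="ln(insulin)")
adj = prs_association(cohort.Y, prs, cohort.age, cohort.sex,
                      extra_adjust=extra, trait_name="ln(insulin)")
print(f"\nln(insulin) ~ PRS             : |t| {abs(base.statistic):.2f}, "
      f"p {base.p:.4f}")
print(f"ln(insulin) ~ PRS + neut + plt: |t| {abs(adj.statistic):.2f}, "
      f"p {adj.p:.4f}")
print("the attenuation under cell-count adjustment is the mediation "
      "signature: the score tracks blood composition, not only "
      "intracellular copy number")
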