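"""Generate a small family-structured methylome cohort and inspect it.

Builds 200 individuals in nuclear families, draws a 500-CpG M-value matrix
with kinship/family/couple/sibling covariance plus plate and blood-draw-date
batch effects, and derives binary phenotypes by liability threshold.
"""

import numpy as np

from stressmwas import CohortDesign, simulate_cohort

design = CohortDesign(n_individuals=200, n_cpgs=500, seed=42)
cohort = simulate_cohort(design)

K = cohort.rel.matrices["K"]
n_related = int((K[np.triu_indices_from(K, 1)] > 0).sum())
print(f"samples: {len(cohort.samples)}, CpGs: {len(cohort.methylome.cpg_ids)}")
print(f"related pairs (kinship > 0): {n_related}")
print(f"preterm cases: {int(cohort.samples['preterm'].sum())} "
      f"({cohort.samples['preterm'].mean():.1%}, target 3.5%)")
print(f"MDD cases: {int(cohort.samples['mdd'].sum())} "
      f"({cohort.samples['mdd'].mean():.1%}, target 13%)")
print(f"plates: {cohort.samples['plate'].nunique()}, "
      f"draw dates: {cohort.samples['draw_date'].nunique()}")
# The case fractions track the configured prevalences up to binomial noise;
# relationship matrices are exact expected-relatedness/indicator structures.
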