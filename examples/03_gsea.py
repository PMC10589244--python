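"""Permutation GSEA between high- and low-PPI groups.

Ranks genes by signal-to-noise between the two PPI groups and scores gene
sets with the weighted running-sum statistic against a gene-label
permutation null.  The positive-regulator catalog itself is included as a
positive control: it should surface with a high NES and a tiny FDR because
the groups were defined by its own enrichment.
"""

from pyroppi.catalog import GeneSet
from pyroppi.cohort import split_groups
from pyroppi.enrichment import gsea_permutation, rank_genes
from pyroppi.scoring import compute_ppi
from pyroppi.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=2, n_samples=120, n_strata=1))
ppi = compute_ppi(cohort.expression, cohort.catalog)
groups = split_groups(ppi, cohort.clinical, rule="median")

ranked = rank_genes(cohort.expression, groups)
background = [g for g in cohort.expression.index if g.startswith("gene_")]
sets = [
    GeneSet(name="POSITIVE_REGULATORS", members=cohort.catalog.positive.members),
    GeneSet(name="NEGATIVE_REGULATORS", members=cohort.catalog.negative.members),
    GeneSet(name="RANDOM_A", members=frozenset(background[:30])),
    GeneSet(name="RANDOM_B", members=frozenset(background[30:70])),
]
res = gsea_permutation(ranked, sets, n_perm=1000, seed=7)
print(res.round(4).to_string(index=False))
print("\nNES > 0 = enriched toward the high-PPI group; the positive catalog")
print("is the planted signal, the random sets calibrate the null (FDR ~ 1).")
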