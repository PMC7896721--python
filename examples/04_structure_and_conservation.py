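"""Ancestry proportions, conservation tiers and family assignment.

The conservation rule bins individuals by their native-lineage
proportion at the mean, mean-1SD and mean-2SD: the top bin is the
nucleus breeding population, the bottom bin is discarded.  Families are
monophyletic groups cut from the IBS neighbour-joining tree, each
keeping at least one boar for rotational mating.
"""

from introsel import DemographyParams, simulate_panel
from introsel.structure import (
    assign_families,
    classify_conservation,
    ibs_matrix,
    nj_tree,
    supervised_ancestry,
)

_, gm, truth = simulate_panel(DemographyParams(seed=42))
p2 = gm.subset(individuals=gm.pop_index("P2"))

refs = {"native": truth.source_freqs["native"], "donor": truth.source_freqs["donor"]}
props = supervised_ancestry(p2, refs)
print(f"mean native ancestry: {props['native'].mean():.3f} "
      f"(truth: {1 - truth.donor_fraction('P2'):.3f})")

groups = classify_conservation(props, "native")
print("tier sizes:", dict(groups.counts()))
print("cutpoints: >= {mean:.3f} nucleus, >= {minus1sd:.3f} candidate1, "
      ">= {minus2sd:.3f} candidate2".format(**groups.cutpoints))

tree = nj_tree(ibs_matrix(p2))
sex = dict(zip(p2.individuals["id"], p2.individuals["sex"]))
families = assign_families(tree, sex, min_boars=1)
print(f"{families['family'].nunique()} families, each with >= 1 boar")
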