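"""Negative snapshots: which interactors does each phenotype leave intact?

Uses the synthetic curated dataset (mutations, interactor binding interfaces
and PTM sites) to build the phenotype x interactor impairment matrix and the
PTM-overlap report.
"""

from vhl_g2p import (
    build_impairment_matrix,
    filter_single_phenotype,
    missense,
    ptm_overlap,
)
from vhl_g2p.synthetic import synthetic_vhl_curation

mutations, interactors, ptm_sites = synthetic_vhl_curation()
single = filter_single_phenotype(missense(mutations))

matrix = build_impairment_matrix(single, interactors)
print(f"impairment matrix: {len(matrix.phenotypes)} phenotypes x "
      f"{len(matrix.interactors)} interactors")
for phenotype in matrix.phenotypes:
    spared = sorted(matrix.unaffected_of(phenotype)) or ["none"]
    print(f"  {phenotype}: conserved interactions -> {', '.join(spared)}")

report = ptm_overlap(mutations, ptm_sites)
print(f"\n{len(report)} of {len(ptm_sites)} PTM sites carry missense mutations:")
for entry in report.entries[:4]:
    print(f"  {entry.site.ptm_type} site {entry.site.position} "
          f"({entry.site.enzyme or 'enzyme n/a'}): "
          f"{', '.join(sorted(entry.phenotype_union))}")
print("An 'unaffected' interactor keeps its binding interface free of that "
      "phenotype's mutations, so the interaction is presumably retained.")
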