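"""Interactome impairment: conserved interactors per phenotype, PTM overlap.

For each phenotype, take the single-phenotype mutations associated to it and
ask which interactors' binding interfaces contain none of those mutated
positions.  Such interactors are "unaffected" — a negative snapshot of the
interactions a phenotype's mutations leave intact.  PTM overlap lists the
modification sites struck by missense mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AFFECTED = "affected"
UNAFFECTED = "unaffected"


@dataclass
class ImpairmentMatrix:
    """Phenotype x interactor matrix of affected/unaffected cells."""

    phenotypes: list[str]                    # row order
    interactors: list[str]                   # column order (alphabetical)
    cells: dict[tuple[str, str], str]        # (phenotype, interactor) -> state
    provenance: dict[str, dict] = field(default_factory=dict)  # per-row audit

    def unaffected_of(self, phenotype: str) -> set[str]:
        return {i for i in self.interactors
                if self.cells[(phenotype, i)] == UNAFFECTED}

    def write_tsv(self, path) -> None:
        from . import __version__
        with open(path, "w") as fh:
            fh.write(f"# vhl-g2p {__version__} impairment matrix (A=affected, U=unaffected)\n")
            fh.write("phenotype\t" + "\t".join(self.interactors) + "\n")
            for ph in self.phenotypes:
                row = [("U" if self.cells[(ph, i)] == UNAFFECTED else "A")
                       for i in self.interactors]
                fh.write(ph + "\t" + "\t".join(row) + "\n")


@dataclass(frozen=True)
class PTMOverlapEntry:
    site: "PTMSite"
    mutations: tuple
    phenotype_union: frozenset[str]


@dataclass
class PTMOverlapReport:
    entries: list[PTMOverlapEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self) -> set[int]:
        return {e.site.position for e in self.entries}

    def write_tsv(self, path) -> None:
        from . import __version__
        with open(path, "w") as fh:
            fh.write(f"# vhl-g2p {__version__} PTM overlap report\n")
            fh.write("position\tptm_type\tenzyme\tn_mutations\tphenotypes\n")
            for e in sorted(self.entries, key=lambda e: e.site.position):
                fh.write(f"{e.site.position}\t{e.site.ptm_type}\t{e.site.enzyme}\t"
                         f"{len(e.mutations)}\t{';'.join(sorted(e.phenotype_union))}\n")


def unaffected_interactors(phenotype: str, records, interactors,
                           margin: int = 0) -> tuple[set[str], dict]:
    """Interactors whose binding residues avoid every mutation of a phenotype.

    ``records`` must be pre-filtered to single-phenotype variants of the
    given phenotype.  ``margin`` widens each mutation to +/- margin residues
    (default 0: exact positional overlap).  Returns (names, provenance);
    with zero records every interactor is vacuously unaffected and the
    provenance is flagged.
    """
    positions: set[int] = set()
    for r in records:
        positions.update(range(r.position - margin, r.position + margin + 1))
    provenance = {
        "phenotype": phenotype,
        "n_mutations": len(list(records)),
        "mutated_positions": sorted({r.position for r in records}),
        "vacuous": not positions,
        "margin": margin,
    }
    names = {it.name for it in interactors if not (it.binding_residues & positions)}
    return names, provenance


def build_impairment_matrix(records, interactors, phenotypes=None,
                            margin: int = 0) -> ImpairmentMatrix:
    """Build the full phenotype x interactor matrix.

    ``records`` must already be single-phenotype missense variants with
    normalized phenotype terms.  Rows cover phenotypes with >= 1 record (or
    the explicit list given); columns are alphabetical.  Deterministic:
    identical inputs give identical matrices.
    """
    by_pheno: dict[str, list] = {}
    for r in records:
        (term,) = tuple(r.phenotypes) if len(r.phenotypes) == 1 else (None,)
        if term is None:
            raise ValueError(f"record {r.variant_label} is not single-phenotype; "
                             "apply filter_single_phenotype first")
        by_pheno.setdefault(term, []).append(r)
    rows = sorted(by_pheno) if phenotypes is None else list(phenotypes)
    cols = sorted(it.name for it in interactors)
    cells: dict[tuple[str, str], str] = {}
    prov: dict[str, dict] = {}
    for ph in rows:
        subset = by_pheno.get(ph, [])
        names, p = unaffected_interactors(ph, subset, interactors, margin=margin)
        prov[ph] = p
        for it in cols:
            cells[(ph, it)] = UNAFFECTED if it in names else AFFECTED
    return ImpairmentMatrix(phenotypes=rows, interactors=cols, cells=cells,
                            provenance=prov)


def ptm_overlap(records, sites) -> PTMOverlapReport:
    """Report every PTM site whose position carries >= 1 missense mutation.

    The phenotype union of an entry pools the phenotypes of all overlapping
    records.  Synonymous variants never count as overlapping.
    """
    missense = [r for r in records if not r.is_synonymous]
    report = PTMOverlapReport()
    for site in sites:
        hits = tuple(r for r in missense if r.position == site.position)
        if hits:
            union = frozenset().union(*(r.phenotypes for r in hits))
            report.entries.append(PTMOverlapEntry(site=site, mutations=hits,
                                                  phenotype_union=union))
    return report
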