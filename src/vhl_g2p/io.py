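"""Readers and writers for the tabular and structural inputs.

Tables are TSV with a header row; lines starting with ``#`` are comments.
Writers prepend a commented header recording the tool version and the
parameters used, so every output file is self-describing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    Atom,
    HgvsParseError,
    InteractorRecord,
    MutationRecord,
    PTMSite,
    Structure,
    SurfaceDefinition,
    format_ranges,
    parse_hgvs_p,
    parse_ranges,
)
from .phenotypes import normalize_set

MUTATION_COLUMNS = {"variant": "variant", "n_patients": "n_patients",
                    "phenotypes": "phenotypes", "source": "source"}


class ConfigurationError(ValueError):
    """A required column or config key is missing."""


class InputError(ValueError):
    """An input file is malformed or refers to unknown entities."""


@dataclass
class ParseReport:
    """Parsed records plus row-level errors (never silently dropped)."""

    records: list[MutationRecord] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line number, message)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    return df


def parse_mutation_table(path: str | Path, dialect: dict[str, str] | None = None) -> ParseReport:
    """Read a curated mutation TSV into :class:`MutationRecord` objects.

    ``dialect`` maps the logical column names (variant, n_patients,
    phenotypes, source) onto the file's actual column names.  HGVS labels are
    parsed into (wt_aa, position, mut_aa); rows with malformed tokens are
    collected in the report's ``errors`` with their line number.
    """
    cols = dict(MUTATION_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = _read_tsv(path)
    for logical in ("variant", "n_patients"):
        if cols[logical] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[logical]!r} (for {logical}) missing in {path}")
    report = ParseReport()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        label = str(row[cols["variant"]]).strip()
        try:
            wt, pos, mut = parse_hgvs_p(label)
            n = int(row[cols["n_patients"]] or 0)
            raw_ph = str(row.get(cols["phenotypes"], "") or "")
            phenos = normalize_set(p for p in raw_ph.split(";"))
            rec = MutationRecord(
                variant_label=label, position=pos, wt_aa=wt, mut_aa=mut,
                n_patients=n, phenotypes=phenos,
                source_id=str(row.get(cols["source"], "") or ""),
            )
        except (HgvsParseError, ValueError) as exc:
            report.errors.append((line_no, str(exc)))
            continue
        report.records.append(rec)
    return report


def write_mutation_table(records, path: str | Path, raw_phenotypes: dict | None = None) -> None:
    """Write records to TSV (inverse of :func:`parse_mutation_table`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# vhl-g2p {__version__} mutation table\n")
        fh.write("variant\tn_patients\tphenotypes\tsource\n")
        for r in records:
            phenos = ";".join(sorted(r.phenotypes))
            fh.write(f"{r.variant_label}\t{r.n_patients}\t{phenos}\t{r.source_id}\n")


def filter_single_phenotype(records) -> list[MutationRecord]:
    """Keep records associated with exactly one normalized phenotype term.

    Records are assumed already normalized, so e.g. a record curated with both
    "ccRCC" and "renal cysts" carries the single term ``renal_disease`` and
    passes.  Idempotent; output is a subset of input.
    """
    return [r for r in records if len(r.phenotypes) == 1]


def parse_interactor_table(path: str | Path) -> list[InteractorRecord]:
    """Read an interactor TSV: name, uniprot, binding_residues (range text)."""
    df = _read_tsv(path)
    if "name" not in df.columns or "binding_residues" not in df.columns:
        raise ConfigurationError(f"interactor table {path} needs 'name' and 'binding_residues'")
    out = []
    for _, row in df.iterrows():
        out.append(InteractorRecord(
            name=str(row["name"]).strip(),
            uniprot_id=str(row.get("uniprot", "") or ""),
            binding_residues=parse_ranges(row["binding_residues"]),
            notes=str(row.get("notes", "") or ""),
        ))
    return out


def write_interactor_table(interactors, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vhl-g2p {__version__} interactor table\n")
        fh.write("name\tuniprot\tbinding_residues\tnotes\n")
        for it in interactors:
            fh.write(f"{it.name}\t{it.uniprot_id}\t{format_ranges(it.binding_residues)}\t{it.notes}\n")


def parse_ptm_table(path: str | Path) -> list[PTMSite]:
    """Read a PTM-site TSV: position, type, enzyme[, surface]."""
    df = _read_tsv(path)
    if "position" not in df.columns or "type" not in df.columns:
        raise ConfigurationError(f"PTM table {path} needs 'position' and 'type'")
    return [
        PTMSite(position=int(row["position"]), ptm_type=str(row["type"]).strip(),
                enzyme=str(row.get("enzyme", "") or ""),
                surface_id=str(row.get("surface", "") or ""))
        for _, row in df.iterrows()
    ]


def write_ptm_table(sites, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vhl-g2p {__version__} PTM table\n")
        fh.write("position\ttype\tenzyme\tsurface\n")
        for s in sites:
            fh.write(f"{s.position}\t{s.ptm_type}\t{s.enzyme}\t{s.surface_id}\n")


def load_surface_config(path: str | Path | None = None) -> list[SurfaceDefinition]:
    """Load surface definitions from YAML/JSON; None loads the packaged default.

    The file maps surface ids to range text, e.g. ``A: "155-189"``.
    """
    if path is None:
        ref = importlib.resources.files("vhl_g2p.data") / "surfaces_default.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    surfaces = doc.get("surfaces", doc)
    defs = [SurfaceDefinition(surface_id=str(sid), residues=parse_ranges(spec))
            for sid, spec in surfaces.items()]
    if not defs:
        raise ConfigurationError("surface config defines no surfaces")
    return defs


def parse_structure(path: str | Path, chain: str) -> Structure:
    """Load one chain's ATOM records from a PDB file.

    First model only; waters excluded; alternate locations resolved to the
    highest-occupancy conformer per atom name.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise InputError(f"no models in {path}")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise InputError(f"chain {chain!r} not found in {path} "
                         f"(has {[c.name for c in model]})")
    atoms: list[Atom] = []
    for res in ch:
        if res.is_water():
            continue
        best: dict[str, gemmi.Atom] = {}
        for a in res:
            prev = best.get(a.name)
            if prev is None or a.occ > prev.occ:
                best[a.name] = a
        for name, a in best.items():
            atoms.append(Atom(chain=chain, res_seq=res.seqid.num, res_name=res.name,
                              atom_name=name, x=a.pos.x, y=a.pos.y, z=a.pos.z,
                              element=a.element.name))
    if not atoms:
        raise InputError(f"no ATOM records for chain {chain!r} in {path}")
    return Structure(atoms=atoms, chain_of_interest=chain)
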