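"""Shared data model: mutations, surfaces, interactors, PTM sites, structures.

All residue positions are 1-based indices on full-length pVHL30 numbering
(residues 1-213); ranges are inclusive on both ends, matching PDB and HGVS
conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.SeqUtils import seq1, seq3

PROTEIN_LENGTH_DEFAULT = 213

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

# p.Arg167Trp / p.R167W / p.Arg167= (synonymous); the "p." prefix is optional.
_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<wt>[A-Za-z]{3}|[A-Z])"
    r"(?P<pos>\d+)"
    r"(?P<mut>[A-Za-z]{3}|[A-Z]|=)"
    r"\)?$"
)


class HgvsParseError(ValueError):
    """A protein-level HGVS token could not be parsed."""


def _to_one_letter(token: str) -> str:
    if token == "=":
        return "="
    if len(token) == 1:
        aa = token.upper()
    else:
        aa = seq1(token.capitalize())
    if aa not in _AA1:
        raise HgvsParseError(f"unknown amino acid token {token!r}")
    return aa


def parse_hgvs_p(label: str) -> tuple[str, int, str]:
    """Parse a protein-level HGVS substitution into (wt_aa, position, mut_aa).

    Accepts three-letter ("p.Arg167Trp") and one-letter ("p.R167W") forms and
    the synonymous notation "p.Arg167=".  DNA-level (c.) notation is out of
    scope.  Raises :class:`HgvsParseError` on anything else.
    """
    m = _HGVS_RE.match(label.strip())
    if not m:
        raise HgvsParseError(f"malformed HGVS protein token {label!r}")
    wt = _to_one_letter(m.group("wt"))
    mut = _to_one_letter(m.group("mut"))
    pos = int(m.group("pos"))
    if pos < 1:
        raise HgvsParseError(f"position must be >= 1 in {label!r}")
    return wt, pos, mut


def format_hgvs_p(wt_aa: str, position: int, mut_aa: str) -> str:
    """Inverse of :func:`parse_hgvs_p` in three-letter notation."""
    wt3 = seq3(wt_aa)
    mut3 = "=" if mut_aa == "=" else seq3(mut_aa)
    return f"p.{wt3}{position}{mut3}"


@dataclass(frozen=True)
class MutationRecord:
    """One curated missense/synonymous variant with patient count and phenotypes.

    ``mut_aa`` is "=" for synonymous variants.  ``phenotypes`` holds normalized
    controlled-vocabulary terms.
    """

    variant_label: str
    position: int
    wt_aa: str
    mut_aa: str
    n_patients: int = 0
    phenotypes: frozenset[str] = field(default_factory=frozenset)
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.is_synonymous and self.wt_aa == self.mut_aa:
            raise ValueError(f"wt and mutant residue identical in {self.variant_label!r}")

    @property
    def is_synonymous(self) -> bool:
        return self.mut_aa == "="


@dataclass(frozen=True)
class SurfaceDefinition:
    """A named pVHL binding interface as a set of residue positions."""

    surface_id: str
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"surface {self.surface_id} has no residues")
        if min(self.residues) < 1:
            raise ValueError("residue positions are 1-based")

    @property
    def size(self) -> int:
        return len(self.residues)

    def __contains__(self, position: int) -> bool:
        return position in self.residues


@dataclass(frozen=True)
class InteractorRecord:
    """A pVHL interactor with the residues of its binding interface."""

    name: str
    uniprot_id: str = ""
    binding_residues: frozenset[int] = field(default_factory=frozenset)
    notes: str = ""


@dataclass(frozen=True)
class PTMSite:
    """A post-translational modification site on pVHL."""

    position: int
    ptm_type: str
    enzyme: str = ""
    surface_id: str = ""

    PTM_TYPES = ("phosphorylation", "neddylation", "sumoylation", "methylation", "ubiquitination")

    def __post_init__(self) -> None:
        if self.ptm_type not in self.PTM_TYPES:
            raise ValueError(f"unknown PTM type {self.ptm_type!r}")
        if self.ptm_type == "phosphorylation" and not self.enzyme:
            raise ValueError(f"phosphorylation site at {self.position} requires an enzyme")


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str = ""


@dataclass
class Structure:
    """A light container for one chain's ATOM records of a PDB model."""

    atoms: list[Atom]
    chain_of_interest: str = ""

    def residues(self) -> dict[int, str]:
        """Ordered mapping residue index -> residue name for the chain."""
        out: dict[int, str] = {}
        for a in self.atoms:
            out.setdefault(a.res_seq, a.res_name)
        return out

    def atoms_of(self, res_seq: int) -> list[Atom]:
        return [a for a in self.atoms if a.res_seq == res_seq]


def parse_ranges(text: str) -> frozenset[int]:
    """Parse "54-113,157-171" (1-based, inclusive) into a position set."""
    out: set[int] = set()
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            lo_i, hi_i = int(lo), int(hi)
            if lo_i > hi_i or lo_i < 1:
                raise ValueError(f"bad range {part!r}")
            out.update(range(lo_i, hi_i + 1))
        else:
            out.add(int(part))
    return frozenset(out)


def format_ranges(positions) -> str:
    """Inverse of :func:`parse_ranges`: compact sorted range text."""
    pos = sorted(positions)
    if not pos:
        return ""
    spans: list[tuple[int, int]] = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p == prev + 1:
            prev = p
        else:
            spans.append((start, prev))
            start = prev = p
    spans.append((start, prev))
    return ",".join(f"{a}-{b}" if a != b else str(a) for a, b in spans)
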