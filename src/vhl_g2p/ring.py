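"""Typed residue-residue interaction networks from 3D coordinates.

A deliberately simple, fully documented geometry: contacts are typed from
heavy-atom distances only (no angular terms, no energy model).

salt_bridge  opposite-charge side-chain N/O pair within cutoff (4.0 A)
hbond        donor/acceptor heavy-atom pair within cutoff (3.5 A)
pipi         aromatic ring-centroid pair within cutoff (6.5 A)
vdw          heavy-atom pair within sum of vdW radii + tolerance (0.5 A)

Per residue pair, only the highest-priority type is kept
(salt_bridge > hbond > pipi > vdw).  Sequence-adjacent pairs (|i-j| <= 1)
are excluded to avoid trivial backbone contacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import Structure

TYPE_PRIORITY = ("salt_bridge", "hbond", "pipi", "vdw")

# charged side-chain atoms
POSITIVE_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# H-bond donor/acceptor heavy atoms (side chains plus backbone N/O)
DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


@dataclass(frozen=True)
class GeometryParams:
    """Distance cutoffs in Angstrom, recorded in every serialization."""

    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    pipi_cutoff: float = 6.5
    vdw_tolerance: float = 0.5
    min_sequence_separation: int = 2  # |i-j| >= 2 for intra-chain edges

    def as_dict(self) -> dict[str, float]:
        return {
            "salt_bridge_cutoff": self.salt_bridge_cutoff,
            "hbond_cutoff": self.hbond_cutoff,
            "pipi_cutoff": self.pipi_cutoff,
            "vdw_tolerance": self.vdw_tolerance,
            "min_sequence_separation": self.min_sequence_separation,
        }


@dataclass(frozen=True)
class ContactEdge:
    residue_i: int
    residue_j: int
    contact_type: str
    distance: float
    atoms: tuple[str, str]
    chain_scope: str = "intra"

    def __post_init__(self) -> None:
        if self.residue_i >= self.residue_j:
            raise ValueError("edges stored with residue_i < residue_j")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class ResidueInteractionNetwork:
    nodes: dict[int, str]  # position -> residue name
    edges: list[ContactEdge] = field(default_factory=list)
    parameters: GeometryParams = field(default_factory=GeometryParams)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for pos, name in self.nodes.items():
            g.add_node(pos, res_name=name)
        for e in self.edges:
            g.add_edge(e.residue_i, e.residue_j, contact_type=e.contact_type,
                       distance=round(e.distance, 3), atoms="-".join(e.atoms))
        g.graph.update(self.parameters.as_dict())
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def write_edge_table(self, path) -> None:
        from . import __version__
        with open(path, "w") as fh:
            fh.write(f"# vhl-g2p {__version__} residue contacts {self.parameters.as_dict()}\n")
            fh.write("residue_i\tresidue_j\ttype\tdistance\tatoms\n")
            for e in sorted(self.edges, key=lambda e: (e.residue_i, e.residue_j)):
                fh.write(f"{e.residue_i}\t{e.residue_j}\t{e.contact_type}\t"
                         f"{e.distance:.3f}\t{e.atoms[0]}-{e.atoms[1]}\n")


def _atom_xyz(atom) -> np.ndarray:
    return np.array([atom.x, atom.y, atom.z])


def _min_pair_distance(atoms_a, atoms_b):
    """Closest pair between two atom lists: (distance, name_a, name_b)."""
    best = (np.inf, "", "")
    for a in atoms_a:
        pa = _atom_xyz(a)
        for b in atoms_b:
            d = float(np.linalg.norm(pa - _atom_xyz(b)))
            if d < best[0]:
                best = (d, a.atom_name, b.atom_name)
    return best


def _heavy(atoms):
    return [a for a in atoms if not a.atom_name.startswith("H")
            and (a.element or a.atom_name[0]) != "H"]


def _typed_atoms(atoms, table, res_name):
    names = table.get(res_name, set())
    return [a for a in atoms if a.atom_name in names]


def _ring_centroid(atoms, res_name):
    ring_names = AROMATIC_RING_ATOMS.get(res_name)
    if not ring_names:
        return None
    ring = [a for a in atoms if a.atom_name in ring_names]
    if len(ring) < len(ring_names):
        return None  # incomplete ring: degrade gracefully
    return np.mean([_atom_xyz(a) for a in ring], axis=0)


def _classify_pair(res_i, res_j, atoms_i, atoms_j, params: GeometryParams):
    """Return (type, distance, atom pair) for one residue pair, or None."""
    # salt bridge: opposite-charge side-chain N/O within cutoff
    for pos_tab, neg_tab in ((POSITIVE_ATOMS, NEGATIVE_ATOMS),):
        pi, nj = _typed_atoms(atoms_i, pos_tab, res_i), _typed_atoms(atoms_j, neg_tab, res_j)
        ni, pj = _typed_atoms(atoms_i, neg_tab, res_i), _typed_atoms(atoms_j, pos_tab, res_j)
        cand = []
        if pi and nj:
            cand.append(_min_pair_distance(pi, nj))
        if ni and pj:
            cand.append(_min_pair_distance(ni, pj))
        if cand:
            d, a, b = min(cand)
            if d <= params.salt_bridge_cutoff:
                return "salt_bridge", d, (a, b)

    # hydrogen bond: donor/acceptor heavy atoms within cutoff (no angle term)
    don_i = _typed_atoms(atoms_i, DONORS, res_i) + [a for a in atoms_i
                                                    if a.atom_name == BACKBONE_DONOR]
    acc_i = _typed_atoms(atoms_i, ACCEPTORS, res_i) + [a for a in atoms_i
                                                       if a.atom_name == BACKBONE_ACCEPTOR]
    don_j = _typed_atoms(atoms_j, DONORS, res_j) + [a for a in atoms_j
                                                    if a.atom_name == BACKBONE_DONOR]
    acc_j = _typed_atoms(atoms_j, ACCEPTORS, res_j) + [a for a in atoms_j
                                                       if a.atom_name == BACKBONE_ACCEPTOR]
    cand = []
    if don_i and acc_j:
        cand.append(_min_pair_distance(don_i, acc_j))
    if acc_i and don_j:
        cand.append(_min_pair_distance(acc_i, don_j))
    if cand:
        d, a, b = min(cand)
        if d <= params.hbond_cutoff:
            return "hbond", d, (a, b)

    # pi-pi stacking: aromatic ring centroids within cutoff
    ci, cj = _ring_centroid(atoms_i, res_i), _ring_centroid(atoms_j, res_j)
    if ci is not None and cj is not None:
        d = float(np.linalg.norm(ci - cj))
        if d <= params.pipi_cutoff:
            return "pipi", d, ("ring", "ring")

    # van der Waals: any heavy-atom pair within summed radii + tolerance
    d, a, b = _min_pair_distance(atoms_i, atoms_j)
    if np.isfinite(d):
        elem_a = a[0] if a[0] in VDW_RADII else "C"
        elem_b = b[0] if b[0] in VDW_RADII else "C"
        if d <= VDW_RADII[elem_a] + VDW_RADII[elem_b] + params.vdw_tolerance:
            return "vdw", d, (a, b)
    return None


def detect_contacts(structure: Structure,
                    params: GeometryParams | None = None) -> ResidueInteractionNetwork:
    """Build the typed contact network of one chain.

    Residues missing side-chain atoms degrade gracefully: typed detection
    uses whatever atoms are present, and the vdW fallback needs only heavy
    atoms.
    """
    params = params or GeometryParams()
    if not structure.atoms:
        raise ValueError("empty structure")
    residues = structure.residues()
    atoms_by_res = {pos: _heavy(structure.atoms_of(pos)) for pos in residues}
    edges: list[ContactEdge] = []
    for i, j in itertools.combinations(sorted(residues), 2):
        if abs(i - j) < params.min_sequence_separation:
            continue
        hit = _classify_pair(residues[i], residues[j], atoms_by_res[i],
                             atoms_by_res[j], params)
        if hit is not None:
            ctype, dist, atoms = hit
            edges.append(ContactEdge(residue_i=i, residue_j=j, contact_type=ctype,
                                     distance=dist, atoms=atoms, chain_scope="intra"))
    return ResidueInteractionNetwork(nodes=dict(residues), edges=edges, parameters=params)


def mutation_edge_impact(network: ResidueInteractionNetwork,
                         position: int) -> list[ContactEdge]:
    """Contacts a substitution at ``position`` could remove (incident edges)."""
    return [e for e in network.edges if position in (e.residue_i, e.residue_j)]
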