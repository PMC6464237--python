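"""Synthetic inputs with planted ground truth for every analysis stage.

The mutation-table generator emulates the statistical structure of a curated
VHL variant table: patient counts are heavy-tailed (most variants reported in
a single patient, a few recurrent), hotspot positions carry planted
count multipliers, phenotype sets are sampled from base rates with optional
surface-conditional odds multipliers, and roughly 45% of variants are
single-phenotype.  A JSON sidecar records the planted truth so recovery
experiments can be scored without re-reading the config.

The structure generator emits ideal-geometry PDB fragments (poly-alanine
helix, an Arg/Glu pair at a chosen side-chain distance, a Phe/Phe pair at a
chosen ring-centroid distance) with a sidecar listing the intended contacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import MutationRecord, format_hgvs_p, parse_ranges
from .io import load_surface_config, write_mutation_table
from .phenotypes import VOCABULARY

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Baseline phenotype frequencies (renal disease and hemangioblastoma are the
#: predominant VHL manifestations; the rest are minor).
DEFAULT_BASE_RATES: dict[str, float] = {
    "renal_disease": 0.35,
    "hemangioblastoma_cerebellar": 0.15,
    "hemangioblastoma_retinal": 0.12,
    "pheochromocytoma": 0.15,
    "pnet": 0.05,
    "pancreatic_cyst": 0.08,
    "polycythemia": 0.03,
    "paraganglioma": 0.02,
    "colorectal_cancer": 0.02,
    "elst": 0.01,
    "glial_tumor": 0.01,
    "cystadenoma": 0.01,
    "si_net": 0.005,
    "other": 0.02,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the mutation-table generator.

    hotspot_positions maps position -> patient-count multiplier (> 0).
    surface_enrichments maps (surface_id, term) -> odds multiplier applied to
    variants whose position lies on that surface.  single_phenotype_fraction
    is the probability a variant is associated with exactly one manifestation
    (default 0.45, echoing the roughly 45% single-phenotype share of curated
    VHL case reports).  Patient counts are geometric with success probability
    geometric_p (default 0.9: most variants are described in one patient).
    """

    n_variants: int = 500
    protein_length: int = 213
    hotspot_positions: dict[int, float] = field(default_factory=dict)
    phenotype_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES))
    surface_enrichments: dict[tuple[str, str], float] = field(default_factory=dict)
    single_phenotype_fraction: float = 0.45
    geometric_p: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if any(m <= 0 for m in self.hotspot_positions.values()):
            raise ValueError("hotspot multipliers must be > 0")
        if not 0.0 <= self.single_phenotype_fraction <= 1.0:
            raise ValueError("single_phenotype_fraction must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.phenotype_base_rates.values()):
            raise ValueError("base rates must be probabilities")
        bad = set(self.phenotype_base_rates) - set(VOCABULARY)
        if bad:
            raise ValueError(f"base rates for unknown terms: {sorted(bad)}")


def enrichment_multiplier(base_p: float, target_p: float) -> float:
    """Odds multiplier turning a base phenotype share into a target share.

    Convenience for planting enrichments stated as probability shifts: the
    multiplier m satisfies odds(target) = m * odds(base).
    """
    if not (0 < base_p < 1 and 0 < target_p < 1):
        raise ValueError("probabilities must be strictly inside (0, 1)")
    return (target_p / (1 - target_p)) / (base_p / (1 - base_p))


def _sample_phenotypes(rng, weights: dict[str, float], single: bool) -> frozenset[str]:
    terms = list(weights)
    w = np.array([weights[t] for t in terms], dtype=float)
    w /= w.sum()
    if single:
        return frozenset([terms[rng.choice(len(terms), p=w)]])
    k = 2 + int(rng.random() < 0.3)  # mostly 2, sometimes 3 manifestations
    idx = rng.choice(len(terms), size=min(k, len(terms)), replace=False, p=w)
    return frozenset(terms[i] for i in idx)


def generate_mutation_records(config: SyntheticConfig, surface_defs=None
                              ) -> tuple[list[MutationRecord], dict]:
    """Draw synthetic variants and the ground-truth sidecar dict.

    Pure function of (config, seed): identical inputs give identical output.
    """
    if surface_defs is None:
        surface_defs = load_surface_config()
    max_surface_res = max(max(d.residues) for d in surface_defs)
    if config.protein_length < max_surface_res:
        raise ValueError(f"protein_length {config.protein_length} < max surface "
                         f"residue {max_surface_res}")
    if config.n_variants > config.protein_length * (len(AA20) - 1):
        raise ValueError("n_variants exceeds the number of distinct substitutions")
    rng = np.random.default_rng(config.seed)
    # one wild-type residue per position, so co-occurring variants agree
    wt_table = [AA20[i] for i in rng.integers(len(AA20), size=config.protein_length)]
    records: list[MutationRecord] = []
    n_single_planted = 0
    seen: set[tuple[int, str]] = set()
    # planted hotspots are guaranteed representation: one variant each up
    # front, the remainder drawn uniformly over all positions
    pending_hotspots = sorted(config.hotspot_positions)
    while len(records) < config.n_variants:
        if pending_hotspots:
            pos = pending_hotspots[0]
        else:
            pos = int(rng.integers(1, config.protein_length + 1))
        wt = wt_table[pos - 1]
        mut = AA20[rng.integers(len(AA20))]
        if mut == wt or (pos, mut) in seen:
            continue
        if pending_hotspots:
            pending_hotspots.pop(0)
        seen.add((pos, mut))
        n = int(rng.geometric(config.geometric_p))
        mult = config.hotspot_positions.get(pos)
        if mult is not None:
            n = max(1, int(round(n * mult)))
        weights = dict(config.phenotype_base_rates)
        for d in surface_defs:
            if pos in d:
                for (sid, term), m in config.surface_enrichments.items():
                    if sid == d.surface_id and term in weights:
                        # multiplying the unnormalized weight multiplies the
                        # odds of `term` versus all other terms by m
                        weights[term] *= m
        single = bool(rng.random() < config.single_phenotype_fraction)
        n_single_planted += single
        phenos = _sample_phenotypes(rng, weights, single)
        records.append(MutationRecord(
            variant_label=format_hgvs_p(wt, pos, mut), position=pos,
            wt_aa=wt, mut_aa=mut, n_patients=n, phenotypes=phenos,
            source_id=f"synthetic:{config.seed}"))
    truth = {
        "seed": config.seed,
        "n_variants": config.n_variants,
        "hotspot_positions": {str(k): v for k, v in config.hotspot_positions.items()},
        "surface_enrichments": {f"{s}:{t}": m
                                for (s, t), m in config.surface_enrichments.items()},
        "n_single_phenotype": n_single_planted,
        "geometric_p": config.geometric_p,
    }
    return records, truth


def generate_mutation_table(config: SyntheticConfig, out_path: str | Path,
                            surface_defs=None) -> dict:
    """Write the synthetic mutation TSV plus its ground-truth JSON sidecar.

    The sidecar lands next to the table as ``<name>.truth.json``.  Returns
    the truth dict.  Byte-identical output for identical (config, seed).
    """
    records, truth = generate_mutation_records(config, surface_defs)
    out_path = Path(out_path)
    write_mutation_table(records, out_path)
    sidecar = out_path.with_suffix(out_path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


# ---------------------------------------------------------------------------
# synthetic curated dataset (deterministic, no RNG)


def synthetic_vhl_curation() -> tuple[list[MutationRecord], list, list]:
    """A synthetic stand-in for a curated VHL dataset: (mutations, interactors,
    PTM sites).

    Deterministic, hand-built tables emulating the *structure* of a manually
    curated mutation/interactor/PTM collection: single-phenotype mutation
    subsets whose positions spare the interactors known to stay unaffected in
    pheochromocytoma (HSPA4, AKT1) and hemangioblastoma (TP53, ID2, ELAVL1,
    E2F1, ELOC), plus a PTM table in which 14 sites carry overlapping
    missense mutations (phosphosites Ser33/Ser38/Ser68/Ser72/Ser111, five
    NEK1-target sites at synthetic placeholder positions, neddylated Lys159,
    sumoylated Lys171 and methylated Arg79/Arg82) and five sites carry none.
    It is synthetic data for exercising the analysis mechanics, not a
    reproduction of any real curated collection.
    """
    from .datamodel import InteractorRecord, PTMSite

    interactors = [
        InteractorRecord("HSPA4", "P34932", parse_ranges("1-20")),
        InteractorRecord("AKT1", "P31749", parse_ranges("30-40")),
        InteractorRecord("HIF1A", "Q16665", parse_ranges("91-99")),
        InteractorRecord("TP53", "P04637", parse_ranges("100-110")),
        InteractorRecord("ID2", "Q02363", parse_ranges("112-120")),
        InteractorRecord("E2F1", "Q01094", parse_ranges("122-130")),
        InteractorRecord("ELOC", "Q15369", parse_ranges("145-156")),
        InteractorRecord("ELAVL1", "Q15717", parse_ranges("157-172")),
        InteractorRecord("DGKZ", "Q13574", parse_ranges("175-185")),
        InteractorRecord("PRKCZ", "Q05513", parse_ranges("186-195")),
    ]

    def rec(pos: int, mut: str, phenos, n: int = 1) -> MutationRecord:
        wt = AA20[pos % len(AA20)]
        if wt == mut:
            mut = "A" if wt != "A" else "V"
        return MutationRecord(variant_label=format_hgvs_p(wt, pos, mut),
                              position=pos, wt_aa=wt, mut_aa=mut, n_patients=n,
                              phenotypes=frozenset(phenos),
                              source_id="synthetic_curation")

    pheo = [rec(p, "W", {"pheochromocytoma"})
            for p in (95, 105, 115, 125, 150, 160, 180, 190)]
    hb = [rec(p, "L", {"hemangioblastoma_cerebellar"})
          for p in (10, 35, 95, 178, 188)]
    renal = [rec(p, "S", {"renal_disease"})
             for p in (10, 35, 95, 105, 115, 125, 150, 160, 180, 190)]

    nek1_sites = (70, 75, 90, 108, 120, 133, 140)  # synthetic placeholder positions
    ptm_sites = [
        PTMSite(33, "phosphorylation", "CSNK2A1", "D"),
        PTMSite(38, "phosphorylation", "CSNK2A1", "D"),
        PTMSite(43, "phosphorylation", "CSNK2A1", "D"),
        PTMSite(68, "phosphorylation", "GSK3B", "B"),
        PTMSite(72, "phosphorylation", "AURKA", "B"),
        PTMSite(111, "phosphorylation", "CHEK2", "C"),
        *(PTMSite(p, "phosphorylation", "NEK1", "B" if p < 106 else "C")
          for p in nek1_sites),
        PTMSite(159, "neddylation", "NEDD8", "A"),
        PTMSite(171, "sumoylation", "PIAS4", "A"),
        PTMSite(79, "methylation", "PRMT1", "B"),
        PTMSite(82, "methylation", "PRMT1", "B"),
        PTMSite(155, "ubiquitination", "", "A"),
        PTMSite(196, "ubiquitination", "", "E"),
    ]
    ptm_hits = [
        rec(33, "F", {"renal_disease", "pheochromocytoma"}),
        rec(38, "F", {"renal_disease", "pheochromocytoma"}),
        rec(68, "F", {"renal_disease", "hemangioblastoma_retinal", "pheochromocytoma"}),
        rec(72, "F", {"renal_disease", "hemangioblastoma_cerebellar"}),
        rec(111, "F", {"renal_disease", "pancreatic_cyst", "pheochromocytoma"}),
        *(rec(p, "F", {"renal_disease", "hemangioblastoma_cerebellar"})
          for p in (70, 75, 90, 108, 120)),  # 5 of the 7 NEK1 sites mutated
        rec(159, "F", {"renal_disease", "pheochromocytoma"}),
        rec(171, "F", {"renal_disease"}),
        rec(79, "F", {"renal_disease", "polycythemia"}),
        rec(82, "F", {"renal_disease", "pnet"}),
    ]
    mutations = pheo + hb + renal + ptm_hits
    return mutations, interactors, ptm_sites


# ---------------------------------------------------------------------------
# toy structures


def _pdb_atom_line(serial: int, name: str, res_name: str, chain: str,
                   res_seq: int, xyz, element: str) -> str:
    x, y, z = xyz
    return (f"ATOM  {serial:5d}  {name:<3s} {res_name:<3s} {chain}{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def _write_pdb(path: Path, residues: list[tuple[int, str, list[tuple[str, tuple, str]]]],
               chain: str = "A") -> None:
    serial = 1
    with open(path, "w") as fh:
        fh.write("REMARK synthetic toy structure generated by vhl-g2p\n")
        for res_seq, res_name, atoms in residues:
            for name, xyz, element in atoms:
                fh.write(_pdb_atom_line(serial, name, res_name, chain, res_seq,
                                        xyz, element))
                serial += 1
        fh.write("END\n")


def _helix_residues(n_residues: int = 12):
    """Ideal-ish poly-alanine alpha helix (N, CA, C, O, CB per residue)."""
    radius, rise, turn = 2.3, 1.5, math.radians(100.0)
    cas = [np.array([radius * math.cos(i * turn), radius * math.sin(i * turn),
                     i * rise]) for i in range(n_residues)]
    residues = []
    for i, ca in enumerate(cas):
        prev_dir = (cas[i - 1] - ca) if i > 0 else (ca - cas[i + 1])
        next_dir = (cas[i + 1] - ca) if i < n_residues - 1 else (ca - cas[i - 1])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        radial = np.array([ca[0], ca[1], 0.0])
        radial = radial / np.linalg.norm(radial)
        n = ca + 1.46 * prev_dir
        c = ca + 1.52 * next_dir
        o = c + 1.23 * radial
        cb = ca + 1.53 * radial
        atoms = [("N", tuple(n), "N"), ("CA", tuple(ca), "C"), ("C", tuple(c), "C"),
                 ("O", tuple(o), "O"), ("CB", tuple(cb), "C")]
        residues.append((i + 1, "ALA", atoms))
    return residues


def _argglu_residues(distance: float):
    """Arg (res 2) and Glu (res 6) with NH1-OE1 = distance, backbones apart."""
    arg_atoms = [
        ("N", (-1.2, 1.0, 0.0), "N"), ("CA", (0.0, 0.0, 0.0), "C"),
        ("C", (-0.5, -1.4, 0.0), "C"), ("O", (-1.6, -1.7, 0.5), "O"),
        ("CB", (1.5, 0.2, 0.0), "C"), ("CG", (2.6, -0.8, 0.0), "C"),
        ("CD", (4.0, -0.3, 0.0), "C"), ("NE", (5.0, -1.3, 0.0), "N"),
        ("CZ", (6.3, -1.1, 0.0), "C"), ("NH1", (7.2, -0.1, 0.0), "N"),
        ("NH2", (6.8, -2.3, 0.0), "N"),
    ]
    x0 = 7.2 + distance  # OE1 sits exactly `distance` from NH1 along +x
    glu_atoms = [
        ("OE1", (x0, -0.1, 0.0), "O"), ("OE2", (x0 + 0.7, -1.2, 0.4), "O"),
        ("CD", (x0 + 1.0, -0.1, 0.0), "C"), ("CG", (x0 + 2.4, 0.4, 0.0), "C"),
        ("CB", (x0 + 3.5, -0.6, 0.0), "C"), ("CA", (x0 + 4.9, 0.0, 0.0), "C"),
        ("C", (x0 + 6.0, -1.0, 0.0), "C"), ("O", (x0 + 7.1, -0.7, -0.4), "O"),
        ("N", (x0 + 5.2, 1.3, 0.0), "N"),
    ]
    return [(2, "ARG", arg_atoms), (6, "GLU", glu_atoms)]


def _phephe_residues(distance: float):
    """Two Phe rings in parallel planes with centroids `distance` apart."""
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    r = 1.39

    def ring(cx: float):
        return [(name, (cx, r * math.cos(k * math.pi / 3.0),
                        r * math.sin(k * math.pi / 3.0)), "C" if name[0] == "C" else "N")
                for k, name in enumerate(ring_names)]

    phe1 = ring(0.0) + [("CB", (-1.6, 1.39, 0.0), "C"), ("CA", (-3.0, 1.8, 0.0), "C"),
                        ("N", (-3.6, 3.0, 0.0), "N"), ("C", (-4.0, 0.7, 0.0), "C"),
                        ("O", (-5.2, 0.9, 0.0), "O")]
    phe2 = ring(distance) + [("CB", (distance + 1.6, 1.39, 0.0), "C"),
                             ("CA", (distance + 3.0, 1.8, 0.0), "C"),
                             ("N", (distance + 3.6, 3.0, 0.0), "N"),
                             ("C", (distance + 4.0, 0.7, 0.0), "C"),
                             ("O", (distance + 5.2, 0.9, 0.0), "O")]
    return [(2, "PHE", phe1), (6, "PHE", phe2)]


def generate_toy_structure(case: str, out_path: str | Path,
                           distance: float = 3.0, n_residues: int = 12) -> dict:
    """Write a toy PDB fragment plus a sidecar of intended contacts.

    case "helix": poly-alanine helix, no charged or aromatic residues (truth:
    no salt bridges, no pi-pi).  case "argglu": Arg/Glu pair whose closest
    charged atoms sit exactly ``distance`` apart (truth: one salt bridge iff
    distance <= cutoff).  case "phephe": Phe/Phe rings with centroid distance
    ``distance`` (truth: one pi-pi edge iff within cutoff).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    out_path = Path(out_path)
    if case == "helix":
        residues = _helix_residues(n_residues)
        expected = []
    elif case == "argglu":
        residues = _argglu_residues(distance)
        expected = [{"i": 2, "j": 6, "type": "salt_bridge", "distance": distance}]
    elif case == "phephe":
        residues = _phephe_residues(distance)
        expected = [{"i": 2, "j": 6, "type": "pipi", "distance": distance}]
    else:
        raise ValueError(f"unknown toy-structure case {case!r}")
    _write_pdb(out_path, residues)
    truth = {"case": case, "distance": distance, "chain": "A",
             "n_residues": len(residues), "expected_contacts": expected}
    sidecar = out_path.with_suffix(out_path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


# ---------------------------------------------------------------------------
# fixture hypoxia-response net


def fixture_petri_net() -> dict:
    """A miniature hypoxia-response net (9 places, 8 transitions).

    Distills the qualitative pVHL pathway: constitutive HIF-1a production, a
    pVHL-dependent degradation transition (the only HIF sink, consuming two
    HIF tokens per firing so wild-type HIF stays bounded under the uniform
    firing policy), HIF-driven VEGF production feeding vessel growth, and an
    AKT activation/inhibition branch with downstream MAPK/glycolysis/POMC
    readouts.  Alias ids
    (p_54, p_38, p_39, p_60, t_181, t_109) map the published pathway-model
    node names onto fixture elements so the same perturbation commands run
    end-to-end.
    """
    return {
        "places": [
            {"id": "hif", "label": "HIF-1a (stabilized)", "initial": 0},
            {"id": "vegf", "label": "VEGF", "initial": 0},
            {"id": "pvhl", "label": "pVHL (VCB complex)", "initial": 2},
            {"id": "akt_active", "label": "AKT1 active", "initial": 1},
            {"id": "akt_inactive", "label": "AKT1 inactive", "initial": 2},
            {"id": "mapk", "label": "MAPK activation", "initial": 0},
            {"id": "vessel_growth", "label": "vessel growth", "initial": 0},
            {"id": "glycolysis", "label": "glycolysis flux", "initial": 0},
            {"id": "pomc", "label": "POMC", "initial": 0},
        ],
        "transitions": [
            {"id": "t_hif_prod", "label": "HIF-1a synthesis"},
            {"id": "t_hif_deg", "label": "pVHL-mediated HIF-1a degradation"},
            {"id": "t_vegf_prod", "label": "HIF-driven VEGF transcription"},
            {"id": "t_angio", "label": "VEGF-driven angiogenesis"},
            {"id": "t_akt_act", "label": "AKT1 activation"},
            {"id": "t_akt_inh", "label": "pVHL-dependent AKT1 inhibition"},
            {"id": "t_mapk_act", "label": "AKT-driven MAPK/glycolysis"},
            {"id": "t_pomc", "label": "MAPK-driven POMC production"},
        ],
        "arcs": [
            {"from": "t_hif_prod", "to": "hif"},
            {"from": "hif", "to": "t_hif_deg", "weight": 2},
            {"from": "pvhl", "to": "t_hif_deg"},
            {"from": "t_hif_deg", "to": "pvhl"},
            {"from": "hif", "to": "t_vegf_prod"},
            {"from": "t_vegf_prod", "to": "hif"},
            {"from": "t_vegf_prod", "to": "vegf"},
            {"from": "vegf", "to": "t_angio"},
            {"from": "t_angio", "to": "vessel_growth"},
            {"from": "akt_inactive", "to": "t_akt_act"},
            {"from": "t_akt_act", "to": "akt_active"},
            {"from": "akt_active", "to": "t_akt_inh"},
            {"from": "pvhl", "to": "t_akt_inh"},
            {"from": "t_akt_inh", "to": "akt_inactive"},
            {"from": "t_akt_inh", "to": "pvhl"},
            {"from": "akt_active", "to": "t_mapk_act"},
            {"from": "t_mapk_act", "to": "akt_active"},
            {"from": "t_mapk_act", "to": "mapk"},
            {"from": "t_mapk_act", "to": "glycolysis"},
            {"from": "mapk", "to": "t_pomc"},
            {"from": "t_pomc", "to": "pomc"},
        ],
        "aliases": {
            "t_181": "t_hif_deg",
            "t_109": "t_akt_inh",
            "p_54": "mapk",
            "p_38": "akt_active",
            "p_39": "glycolysis",
            "p_60": "vessel_growth",
        },
    }


def write_fixture_net(out_path: str | Path) -> dict:
    spec = fixture_petri_net()
    Path(out_path).write_text(json.dumps(spec, indent=2) + "\n")
    return spec
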