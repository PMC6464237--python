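"""End-to-end orchestration of the analysis stages.

A run executes the enabled stages in a fixed order (parse -> hotspots ->
surfaces -> network -> impairment -> petri), writes one TSV/JSON artifact per
stage and a manifest recording tool version, parameters, seed and input
checksums, so identical (inputs, config, seed) give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .hotspots import HotspotParams, detect_hotspots, write_hotspot_table
from .impairment import build_impairment_matrix, ptm_overlap
from .io import (
    filter_single_phenotype,
    load_surface_config,
    parse_interactor_table,
    parse_mutation_table,
    parse_ptm_table,
    parse_structure,
)
from .petri import SimulationConfig, build_net, compare_experiments, knockout, simulate
from .ring import GeometryParams, detect_contacts
from .surfaces import compare_surfaces, missense, mutated_fraction, phenotype_distribution

logger = logging.getLogger(__name__)

STAGE_ORDER = ("parse", "hotspots", "surfaces", "network", "impairment", "petri")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Inputs, stage toggles and per-stage parameters of one pipeline run."""

    mutations: str | None = None
    interactors: str | None = None
    ptm: str | None = None
    surfaces: str | None = None          # None -> packaged default definitions
    structure: str | None = None
    structure_chain: str = "A"
    net: str | None = None
    out_dir: str = "vhl_g2p_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: dict.fromkeys(STAGE_ORDER, True))
    hotspot_quantile: float = 0.95
    hotspot_strict: bool = True
    comparison_method: str = "chi_square"
    petri_steps: int = 2000
    petri_replicates: int = 50
    petri_knockouts: tuple[str, ...] = ()
    petri_increments: dict[str, int] = field(default_factory=dict)
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "petri_knockouts" in doc:
            doc["petri_knockouts"] = tuple(doc["petri_knockouts"])
        cfg = cls(**doc)
        for name, path_str in (("mutations", cfg.mutations), ("interactors", cfg.interactors),
                               ("ptm", cfg.ptm), ("structure", cfg.structure),
                               ("net", cfg.net), ("surfaces", cfg.surfaces)):
            if path_str is not None and not Path(path_str).exists():
                raise FileNotFoundError(f"config input {name!r}: {path_str} does not exist")
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the manifest dict.

    Any stage failure raises :class:`StageError`; artifacts written before
    the failure are retained and the manifest is saved with a ``failed``
    marker naming the stage.
    """
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise StageError("setup", "exists", f"{manifest_path} exists; use force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "vhl-g2p",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "hotspot_quantile": config.hotspot_quantile,
            "hotspot_strict": config.hotspot_strict,
            "comparison_method": config.comparison_method,
            "petri_steps": config.petri_steps,
            "petri_replicates": config.petri_replicates,
            "petri_knockouts": list(config.petri_knockouts),
            "petri_increments": dict(config.petri_increments),
        },
        "inputs": {},
        "stages_completed": [],
        "outputs": {},
    }
    for name in ("mutations", "interactors", "ptm", "surfaces", "structure", "net"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    state: dict = {}
    current = None
    try:
        for current in (s for s in STAGE_ORDER if config.stages.get(s, False)):
            t0 = time.perf_counter()
            _run_stage(current, config, state, out, manifest)
            manifest["stages_completed"].append(current)
            logger.info("stage %s done in %.2fs", current, time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed"] = current
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(current or "setup", "error", str(exc)) from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _require(condition: bool, stage: str, code: str, message: str) -> None:
    if not condition:
        raise StageError(stage, code, message)


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path,
               manifest: dict) -> None:
    if stage == "parse":
        _require(config.mutations is not None, stage, "missing_input",
                 "parse stage needs a mutation table")
        report = parse_mutation_table(config.mutations)
        state["records"] = report.records
        state["surface_defs"] = load_surface_config(config.surfaces)
        if report.errors:
            err_path = out / "parse_errors.tsv"
            with open(err_path, "w") as fh:
                fh.write("line\terror\n")
                for line_no, msg in report.errors:
                    fh.write(f"{line_no}\t{msg}\n")
            manifest["outputs"]["parse_errors"] = str(err_path)
        manifest["outputs"]["n_records"] = len(report.records)
        manifest["outputs"]["n_parse_errors"] = len(report.errors)

    elif stage == "hotspots":
        _require("records" in state, stage, "missing_dep", "parse stage must run first")
        params = HotspotParams(quantile_level=config.hotspot_quantile,
                               strict=config.hotspot_strict)
        summaries = detect_hotspots(state["records"], params)
        path = out / "hotspots.tsv"
        write_hotspot_table(summaries, path, params)
        manifest["outputs"]["hotspots"] = str(path)
        manifest["outputs"]["n_hotspots"] = len(summaries)

    elif stage == "surfaces":
        _require("records" in state, stage, "missing_dep", "parse stage must run first")
        defs = state["surface_defs"]
        mis = missense(state["records"])
        single = filter_single_phenotype(mis)
        state["single"] = single
        stats_path = out / "surface_stats.tsv"
        with open(stats_path, "w") as fh:
            fh.write(f"# vhl-g2p {__version__} surface stats\n")
            fh.write("surface\tn_mutated_positions\tinterface_size\tmutated_fraction_pct\n")
            for d in sorted(defs, key=lambda d: d.surface_id):
                s = mutated_fraction(mis, d)
                fh.write(f"{s.surface_id}\t{s.n_mutated_positions}\t"
                         f"{s.interface_size}\t{s.mutated_fraction_pct}\n")
        dists = {d.surface_id: phenotype_distribution(single, d.surface_id, defs).as_dict()
                 for d in defs}
        dists["overall"] = phenotype_distribution(single, "overall").as_dict()
        comparison = None
        try:
            res = compare_surfaces(single, defs, method=config.comparison_method,
                                   seed=config.seed)
            comparison = {"method": res.method, "statistic": res.statistic,
                          "p_value": res.p_value, "surfaces": list(res.surfaces)}
        except ValueError as exc:
            logger.warning("surface comparison skipped: %s", exc)
        dist_path = out / "phenotype_distributions.json"
        dist_path.write_text(json.dumps(
            {"distributions": dists, "comparison": comparison,
             "n_single_phenotype": len(single)}, indent=2, sort_keys=True) + "\n")
        manifest["outputs"]["surface_stats"] = str(stats_path)
        manifest["outputs"]["phenotype_distributions"] = str(dist_path)

    elif stage == "network":
        _require(config.structure is not None, stage, "missing_input",
                 "network stage needs a PDB structure")
        structure = parse_structure(config.structure, config.structure_chain)
        network = detect_contacts(structure, GeometryParams())
        path = out / "residue_contacts.tsv"
        network.write_edge_table(path)
        network.write_graphml(out / "residue_contacts.graphml")
        manifest["outputs"]["residue_contacts"] = str(path)
        manifest["outputs"]["n_contacts"] = len(network.edges)

    elif stage == "impairment":
        _require(config.interactors is not None, stage, "missing_input",
                 "impairment stage needs an interactor table")
        _require("single" in state, stage, "missing_dep", "surfaces stage must run first")
        interactors = parse_interactor_table(config.interactors)
        matrix = build_impairment_matrix(state["single"], interactors)
        path = out / "impairment_matrix.tsv"
        matrix.write_tsv(path)
        manifest["outputs"]["impairment_matrix"] = str(path)
        if config.ptm is not None:
            sites = parse_ptm_table(config.ptm)
            report = ptm_overlap(state["records"], sites)
            ptm_path = out / "ptm_overlap.tsv"
            report.write_tsv(ptm_path)
            manifest["outputs"]["ptm_overlap"] = str(ptm_path)
            manifest["outputs"]["n_ptm_overlaps"] = len(report)

    elif stage == "petri":
        _require(config.net is not None, stage, "missing_input",
                 "petri stage needs a net spec")
        net, initial = build_net(config.net)
        sim_cfg = SimulationConfig(steps=config.petri_steps,
                                   replicates=config.petri_replicates,
                                   seed=config.seed)
        wt = simulate(net, initial, sim_cfg)
        result = {"wild_type": {"place_means": wt.place_means,
                                "place_stds": wt.place_stds}}
        if config.petri_knockouts or config.petri_increments:
            pert_net = knockout(net, config.petri_knockouts) if config.petri_knockouts else net
            from .petri import perturb_marking
            pert_marking = (perturb_marking(initial, config.petri_increments, net)
                            if config.petri_increments else initial)
            pert = simulate(pert_net, pert_marking, sim_cfg)
            result["perturbed"] = {"place_means": pert.place_means,
                                   "place_stds": pert.place_stds}
            result["deltas"] = compare_experiments(wt, pert)
        path = out / "petri_results.json"
        path.write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        manifest["outputs"]["petri_results"] = str(path)
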