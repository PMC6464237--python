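"""Discrete place/transition Petri nets for pathway perturbation experiments.

A net is a bipartite graph of places (token holders) and transitions
(events).  A transition is enabled when each input place holds at least the
arc weight; firing consumes and produces tokens along the arcs.  Perturbation
experiments disable transitions (knockouts, emulating loss of an interaction)
or raise initial token counts (emulating constitutive activation), then
compare token accumulation per place against the wild-type net.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


class ValidationError(ValueError):
    """The net specification violates the place/transition bipartite schema."""


class StateError(RuntimeError):
    """An operation was attempted in an illegal token state."""


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    weight: int = 1

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValidationError(f"arc {self.source}->{self.target}: weight must be >= 1")


@dataclass(frozen=True)
class PetriNet:
    """Immutable place/transition net; knockouts return a modified copy."""

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    arcs: tuple[Arc, ...]
    labels: dict[str, str] = field(default_factory=dict, compare=False)
    aliases: dict[str, str] = field(default_factory=dict, compare=False)
    disabled: frozenset[str] = frozenset()

    def resolve(self, node_id: str) -> str:
        return self.aliases.get(node_id, node_id)

    def inputs(self, transition: str) -> list[Arc]:
        return [a for a in self.arcs if a.target == transition]

    def outputs(self, transition: str) -> list[Arc]:
        return [a for a in self.arcs if a.source == transition]


Marking = dict[str, int]


@dataclass(frozen=True)
class SimulationConfig:
    steps: int = 2000
    replicates: int = 1
    seed: int = 0
    policy: str = "random_single_fire"
    trajectory_every: int = 100

    def __post_init__(self) -> None:
        if self.steps < 1 or self.replicates < 1:
            raise ValueError("steps and replicates must be >= 1")
        if self.policy not in ("random_single_fire", "maximal_step"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class ExperimentResult:
    """Summary of replicate simulations of one (net, marking, config)."""

    place_means: dict[str, float]
    place_stds: dict[str, float]
    firing_counts: dict[str, int]           # total over replicates
    trajectories: dict[str, list[float]]    # mean token count every k steps
    deadlock_steps: list[int | None]        # first deadlock step per replicate
    config: SimulationConfig
    final_markings: list[Marking] = field(default_factory=list)


def validate_net(places, transitions, arcs) -> None:
    place_set, trans_set = set(places), set(transitions)
    if place_set & trans_set:
        raise ValidationError(f"ids used as both place and transition: {place_set & trans_set}")
    dangling = [a for a in arcs
                if a.source not in place_set | trans_set or a.target not in place_set | trans_set]
    if dangling:
        raise ValidationError("dangling arc endpoints: "
                              + ", ".join(f"{a.source}->{a.target}" for a in dangling))
    bad = [a for a in arcs
           if (a.source in place_set) == (a.target in place_set)]
    if bad:
        raise ValidationError("non-bipartite arcs (place-place or transition-transition): "
                              + ", ".join(f"{a.source}->{a.target}" for a in bad))


def build_net(spec: dict | str | Path) -> tuple[PetriNet, Marking]:
    """Build a validated net (plus its initial marking) from a JSON spec.

    Spec schema: ``{"places": [{"id", "label", "initial"}], "transitions":
    [{"id", "label"}], "arcs": [{"from", "to", "weight"}], "aliases": {...}}``.
    """
    if not isinstance(spec, dict):
        spec = json.loads(Path(spec).read_text())
    places = tuple(p["id"] for p in spec["places"])
    transitions = tuple(t["id"] for t in spec["transitions"])
    arcs = tuple(Arc(source=a["from"], target=a["to"], weight=int(a.get("weight", 1)))
                 for a in spec["arcs"])
    validate_net(places, transitions, arcs)
    labels = {n["id"]: n.get("label", n["id"])
              for n in list(spec["places"]) + list(spec["transitions"])}
    aliases = dict(spec.get("aliases", {}))
    for alias, real in aliases.items():
        if real not in places and real not in transitions:
            raise ValidationError(f"alias {alias!r} points to unknown id {real!r}")
    net = PetriNet(places=places, transitions=transitions, arcs=arcs,
                   labels=labels, aliases=aliases)
    marking = {p["id"]: int(p.get("initial", 0)) for p in spec["places"]}
    if any(v < 0 for v in marking.values()):
        raise ValidationError("initial token counts must be >= 0")
    return net, marking


def read_pnml(path: str | Path) -> tuple[PetriNet, Marking]:
    """Read a minimal PNML subset (place/transition/arc, initialMarking,
    inscription)."""
    from lxml import etree

    tree = etree.parse(str(path))
    ns = {"p": tree.getroot().nsmap.get(None) or "http://www.pnml.org/version-2009/grammar/pnml"}

    def _text(el, xpath):
        hit = el.findall(xpath, ns)
        return hit[0].text.strip() if hit and hit[0].text else None

    spec = {"places": [], "transitions": [], "arcs": []}
    for pl in tree.findall(".//p:place", ns):
        initial = _text(pl, "p:initialMarking/p:text")
        name = _text(pl, "p:name/p:text")
        spec["places"].append({"id": pl.get("id"), "label": name or pl.get("id"),
                               "initial": int(initial or 0)})
    for tr in tree.findall(".//p:transition", ns):
        name = _text(tr, "p:name/p:text")
        spec["transitions"].append({"id": tr.get("id"), "label": name or tr.get("id")})
    for arc in tree.findall(".//p:arc", ns):
        weight = _text(arc, "p:inscription/p:text")
        spec["arcs"].append({"from": arc.get("source"), "to": arc.get("target"),
                             "weight": int(weight or 1)})
    return build_net(spec)


def enabled_transitions(net: PetriNet, marking: Marking) -> set[str]:
    """Transitions not disabled whose every input place holds >= arc weight."""
    out = set()
    for t in net.transitions:
        if t in net.disabled:
            continue
        if all(marking[a.source] >= a.weight for a in net.inputs(t)):
            out.add(t)
    return out


def fire(net: PetriNet, marking: Marking, transition: str) -> Marking:
    """Fire one transition, returning the successor marking (input unchanged)."""
    transition = net.resolve(transition)
    if transition in net.disabled:
        raise StateError(f"transition {transition!r} is disabled")
    if transition not in enabled_transitions(net, marking):
        raise StateError(f"transition {transition!r} is not enabled")
    new = dict(marking)
    for a in net.inputs(transition):
        new[a.source] -= a.weight
    for a in net.outputs(transition):
        new[a.target] += a.weight
    return new


def knockout(net: PetriNet, transition_ids) -> PetriNet:
    """Return a copy of the net with the given transitions disabled."""
    resolved = {net.resolve(t) for t in transition_ids}
    unknown = resolved - set(net.transitions)
    if unknown:
        raise ValueError(f"unknown transition ids: {sorted(unknown)}")
    return replace(net, disabled=net.disabled | frozenset(resolved))


def perturb_marking(marking: Marking, increments: dict[str, int],
                    net: PetriNet | None = None) -> Marking:
    """Pointwise addition of token increments; other places unchanged."""
    new = dict(marking)
    for pid, inc in increments.items():
        key = net.resolve(pid) if net is not None else pid
        if key not in new:
            raise ValueError(f"unknown place id {pid!r}")
        new[key] += int(inc)
    return new


def _simulate_once(net: PetriNet, initial: Marking, steps: int, policy: str,
                   rng: np.random.Generator, every: int):
    marking = dict(initial)
    firing: dict[str, int] = dict.fromkeys(net.transitions, 0)
    deadlock: int | None = None
    traj: dict[str, list[int]] = {p: [] for p in net.places}
    for step in range(1, steps + 1):
        enabled = enabled_transitions(net, marking)
        if not enabled:
            if deadlock is None:
                deadlock = step
            # deadlock: record and hold the marking, never error
        elif policy == "random_single_fire":
            t = sorted(enabled)[rng.integers(len(enabled))]
            marking = fire(net, marking, t)
            firing[t] += 1
        else:  # maximal_step: fire a maximal set of concurrently enabled transitions
            for t in rng.permutation(sorted(enabled)):
                if t in enabled_transitions(net, marking):
                    marking = fire(net, marking, str(t))
                    firing[str(t)] += 1
        if step % every == 0:
            for p in net.places:
                traj[p].append(marking[p])
    return marking, firing, deadlock, traj


def simulate(net: PetriNet, initial: Marking,
             config: SimulationConfig | None = None) -> ExperimentResult:
    """Run seeded replicate token-game simulations.

    Each replicate uses an independent stream seeded ``seed + replicate
    index``; with ``random_single_fire`` every step fires one uniformly chosen
    enabled transition.  Deadlocked nets run to the step count with constant
    marking.
    """
    config = config or SimulationConfig()
    if set(initial) != set(net.places):
        raise ValueError("marking domain must equal the net's place set")
    finals, firings, deadlocks, trajs = [], [], [], []
    for rep in range(config.replicates):
        rng = np.random.default_rng(config.seed + rep)
        m, f, d, tr = _simulate_once(net, initial, config.steps, config.policy,
                                     rng, config.trajectory_every)
        finals.append(m)
        firings.append(f)
        deadlocks.append(d)
        trajs.append(tr)
    means = {p: float(np.mean([m[p] for m in finals])) for p in net.places}
    stds = {p: float(np.std([m[p] for m in finals])) for p in net.places}
    total_firings = {t: int(sum(f[t] for f in firings)) for t in net.transitions}
    mean_traj = {p: [float(np.mean([tr[p][k] for tr in trajs]))
                     for k in range(len(trajs[0][p]))] for p in net.places}
    return ExperimentResult(place_means=means, place_stds=stds,
                            firing_counts=total_firings, trajectories=mean_traj,
                            deadlock_steps=deadlocks, config=config,
                            final_markings=finals)


def compare_experiments(wild_type: ExperimentResult,
                        perturbed: ExperimentResult) -> list[dict]:
    """Per-place mean difference and log2 ratio (pseudocount 1) vs wild-type.

    Returned rows are ranked by absolute mean difference, largest first.
    """
    if set(wild_type.place_means) != set(perturbed.place_means):
        raise ValueError("experiments cover different place sets")
    rows = []
    for p in wild_type.place_means:
        wt, pert = wild_type.place_means[p], perturbed.place_means[p]
        rows.append({
            "place": p,
            "wild_type_mean": wt,
            "perturbed_mean": pert,
            "delta": pert - wt,
            "log2_ratio": float(np.log2((pert + 1.0) / (wt + 1.0))),
        })
    rows.sort(key=lambda r: (-abs(r["delta"]), r["place"]))
    return rows
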