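"""Petri-net semantics: validation, firing, simulation, perturbations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vhl_g2p.petri import (
    Arc,
    SimulationConfig,
    StateError,
    ValidationError,
    build_net,
    compare_experiments,
    enabled_transitions,
    fire,
    knockout,
    perturb_marking,
    simulate,
)
from vhl_g2p.synthetic import fixture_petri_net


def tiny_spec():
    return {
        "places": [{"id": "p", "initial": 1}, {"id": "q", "initial": 0}],
        "transitions": [{"id": "t"}],
        "arcs": [{"from": "p", "to": "t"}, {"from": "t", "to": "q"}],
    }


def test_build_minimal_self_loop():
    spec = {"places": [{"id": "p", "initial": 1}], "transitions": [{"id": "t"}],
            "arcs": [{"from": "p", "to": "t"}, {"from": "t", "to": "p"}]}
    net, marking = build_net(spec)
    assert net.places == ("p",) and net.transitions == ("t",)
    assert marking == {"p": 1}


def test_build_rejects_place_place_arc():
    spec = tiny_spec()
    spec["arcs"].append({"from": "p", "to": "q"})
    with pytest.raises(ValidationError):
        build_net(spec)


def test_build_rejects_dangling_endpoint():
    spec = tiny_spec()
    spec["arcs"].append({"from": "ghost", "to": "t"})
    with pytest.raises(ValidationError, match="ghost"):
        build_net(spec)


def test_build_rejects_zero_weight():
    spec = tiny_spec()
    spec["arcs"][0]["weight"] = 0
    with pytest.raises(ValidationError):
        build_net(spec)


def test_fixture_net_shape_and_validity(hypoxia_net):
    net, marking = hypoxia_net
    assert len(net.places) == 9 and len(net.transitions) == 8
    assert set(marking) == set(net.places)
    # aliases resolve onto real elements
    for alias in ("t_181", "t_109", "p_54", "p_38", "p_39", "p_60"):
        assert net.resolve(alias) in net.places + net.transitions


def test_enabled_source_transition_on_empty_marking():
    spec = {"places": [{"id": "q"}], "transitions": [{"id": "src"}],
            "arcs": [{"from": "src", "to": "q"}]}
    net, marking = build_net(spec)
    assert enabled_transitions(net, marking) == {"src"}


def test_enabled_respects_arc_weight():
    spec = tiny_spec()
    spec["arcs"][0]["weight"] = 2
    net, marking = build_net(spec)  # p holds 1 < weight 2
    assert enabled_transitions(net, marking) == set()


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_enabled_matches_bruteforce_on_random_nets(seed):
    rng = np.random.default_rng(seed)
    n_p, n_t = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    places = [f"p{i}" for i in range(n_p)]
    transitions = [f"t{i}" for i in range(n_t)]
    arcs = []
    for t in transitions:
        for p in places:
            if rng.random() < 0.4:
                arcs.append(Arc(p, t, int(rng.integers(1, 3))))
            if rng.random() < 0.4:
                arcs.append(Arc(t, p, int(rng.integers(1, 3))))
    spec = {"places": [{"id": p, "initial": int(rng.integers(0, 4))} for p in places],
            "transitions": [{"id": t} for t in transitions],
            "arcs": [{"from": a.source, "to": a.target, "weight": a.weight}
                     for a in arcs]}
    net, marking = build_net(spec)
    expected = set()
    for t in transitions:  # brute force: check every input arc directly
        if all(marking[a.source] >= a.weight for a in arcs
               if a.target == t and a.source in marking):
            expected.add(t)
    assert enabled_transitions(net, marking) == expected


def test_fire_moves_token():
    net, marking = build_net(tiny_spec())
    assert fire(net, marking, "t") == {"p": 0, "q": 1}
    assert marking == {"p": 1, "q": 0}  # input untouched


def test_fire_self_loop_conserves():
    spec = {"places": [{"id": "p", "initial": 1}], "transitions": [{"id": "t"}],
            "arcs": [{"from": "p", "to": "t"}, {"from": "t", "to": "p"}]}
    net, marking = build_net(spec)
    assert fire(net, marking, "t") == {"p": 1}


def test_fire_weighted_consumption():
    spec = {"places": [{"id": "p", "initial": 3}], "transitions": [{"id": "t"}],
            "arcs": [{"from": "p", "to": "t", "weight": 2}]}
    net, marking = build_net(spec)
    assert fire(net, marking, "t") == {"p": 1}


def test_fire_disabled_or_not_enabled_raises():
    net, marking = build_net(tiny_spec())
    with pytest.raises(StateError):
        fire(net, {"p": 0, "q": 0}, "t")
    with pytest.raises(StateError):
        fire(knockout(net, ["t"]), marking, "t")


def test_simulate_no_transitions_holds_marking():
    spec = {"places": [{"id": "p", "initial": 4}], "transitions": [], "arcs": []}
    net, marking = build_net(spec)
    res = simulate(net, marking, SimulationConfig(steps=50, seed=1))
    assert res.place_means == {"p": 4.0}
    assert res.deadlock_steps == [1]


def test_simulate_source_accumulates_one_per_step():
    spec = {"places": [{"id": "q", "initial": 0}], "transitions": [{"id": "src"}],
            "arcs": [{"from": "src", "to": "q"}]}
    net, marking = build_net(spec)
    res = simulate(net, marking, SimulationConfig(steps=100, seed=5))
    assert res.place_means == {"q": 100.0}


def test_simulate_seed_determinism(hypoxia_net):
    net, marking = hypoxia_net
    cfg = SimulationConfig(steps=300, replicates=5, seed=42)
    r1 = simulate(net, marking, cfg)
    r2 = simulate(net, marking, cfg)
    assert r1.place_means == r2.place_means
    assert r1.final_markings == r2.final_markings
    assert r1.trajectories == r2.trajectories


def test_knockout_returns_new_net(hypoxia_net):
    net, _ = hypoxia_net
    ko = knockout(net, ["t_181"])
    assert "t_hif_deg" in ko.disabled and net.disabled == frozenset()
    with pytest.raises(ValueError):
        knockout(net, ["no_such_transition"])


def test_knockout_never_fires(hypoxia_net):
    net, marking = hypoxia_net
    ko = knockout(net, ["t_181"])
    res = simulate(ko, marking, SimulationConfig(steps=500, replicates=3, seed=2))
    assert res.firing_counts["t_hif_deg"] == 0


def test_knockout_only_transition_freezes_net():
    net, marking = build_net(tiny_spec())
    res = simulate(knockout(net, ["t"]), marking, SimulationConfig(steps=20, seed=0))
    assert res.place_means == {"p": 1.0, "q": 0.0}


def test_perturb_marking():
    marking = {"p_54": 2, "x": 0}
    assert perturb_marking(marking, {}) == marking
    assert perturb_marking(marking, {"p_54": 5}) == {"p_54": 7, "x": 0}
    with pytest.raises(ValueError):
        perturb_marking(marking, {"ghost": 1})


def test_perturb_marking_via_aliases(hypoxia_net):
    net, marking = hypoxia_net
    bumped = perturb_marking(marking, {"p_38": 3, "p_39": 3, "p_60": 3}, net)
    assert bumped["akt_active"] == marking["akt_active"] + 3
    assert bumped["glycolysis"] == marking["glycolysis"] + 3
    assert bumped["vessel_growth"] == marking["vessel_growth"] + 3


def test_compare_experiments_identical_and_pseudocount(hypoxia_net):
    net, marking = hypoxia_net
    cfg = SimulationConfig(steps=200, replicates=3, seed=8)
    res = simulate(net, marking, cfg)
    deltas = compare_experiments(res, res)
    assert all(row["delta"] == 0 and row["log2_ratio"] == 0 for row in deltas)
    fake_wt = simulate(net, marking, cfg)
    fake_wt.place_means = {p: 0.0 for p in net.places}
    fake_pert = simulate(net, marking, cfg)
    fake_pert.place_means = {p: 7.0 for p in net.places}
    out = compare_experiments(fake_wt, fake_pert)
    assert all(row["log2_ratio"] == pytest.approx(3.0) for row in out)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_reachable_markings_stay_nonnegative(seed):
    rng = np.random.default_rng(seed)
    places = [f"p{i}" for i in range(int(rng.integers(2, 5)))]
    transitions = [f"t{i}" for i in range(int(rng.integers(1, 4)))]
    arcs = []
    for t in transitions:
        for p in places:
            if rng.random() < 0.5:
                arcs.append({"from": p, "to": t, "weight": int(rng.integers(1, 3))})
            if rng.random() < 0.5:
                arcs.append({"from": t, "to": p, "weight": int(rng.integers(1, 3))})
    spec = {"places": [{"id": p, "initial": int(rng.integers(0, 3))} for p in places],
            "transitions": [{"id": t} for t in transitions], "arcs": arcs}
    net, marking = build_net(spec)
    res = simulate(net, marking, SimulationConfig(steps=40, seed=int(seed % 2**31)))
    assert all(v >= 0 for m in res.final_markings for v in m.values())


@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6))
def test_cycle_conservation(n, seed):
    # unit-weight cycle p0 -> t0 -> p1 -> t1 -> ... -> p0: total tokens invariant
    places = [f"p{i}" for i in range(n)]
    transitions = [f"t{i}" for i in range(n)]
    arcs = []
    for i in range(n):
        arcs.append({"from": places[i], "to": transitions[i]})
        arcs.append({"from": transitions[i], "to": places[(i + 1) % n]})
    spec = {"places": [{"id": p, "initial": 2} for p in places],
            "transitions": [{"id": t} for t in transitions], "arcs": arcs}
    net, marking = build_net(spec)
    res = simulate(net, marking, SimulationConfig(steps=60, seed=seed))
    total = sum(marking.values())
    for final in res.final_markings:
        assert sum(final.values()) == total


def test_read_pnml_minimal_subset(tmp_path):
    from vhl_g2p.petri import read_pnml

    pnml = tmp_path / "net.pnml"
    pnml.write_text("""<?xml version="1.0"?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
  <net id="n1" type="http://www.pnml.org/version-2009/grammar/ptnet">
    <page id="pg1">
      <place id="p"><name><text>substrate</text></name>
        <initialMarking><text>3</text></initialMarking></place>
      <place id="q"/>
      <transition id="t"><name><text>convert</text></name></transition>
      <arc id="a1" source="p" target="t">
        <inscription><text>2</text></inscription></arc>
      <arc id="a2" source="t" target="q"/>
    </page>
  </net>
</pnml>
""")
    net, marking = read_pnml(pnml)
    assert set(net.places) == {"p", "q"} and net.transitions == ("t",)
    assert marking == {"p": 3, "q": 0}
    assert fire(net, marking, "t") == {"p": 1, "q": 1}
    assert net.labels["p"] == "substrate"


def test_maximal_step_policy_runs(hypoxia_net):
    net, marking = hypoxia_net
    cfg = SimulationConfig(steps=100, replicates=2, seed=1, policy="maximal_step")
    res = simulate(net, marking, cfg)
    assert all(v >= 0 for v in res.place_means.values())
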