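# vhl-g2p

Genotype–phenotype analysis of the von Hippel–Lindau tumor suppressor
protein (pVHL) from curated disease-mutation tables, interactor binding
interfaces, post-translational modification (PTM) sites, 3D structures and a
discrete model of the hypoxia-response pathway.

VHL syndrome is a familial cancer predisposition caused by inactivation of
pVHL, the substrate-recognition subunit of the VCB E3 ubiquitin-ligase
complex that degrades HIF-1α. Different missense mutations produce strikingly
different clinical pictures — renal cell carcinoma, pheochromocytoma,
cerebellar/retinal hemangioblastoma, polycythemia and more — and part of that
variability tracks *where* on the protein a mutation falls. This package is
for computational biologists who want to quantify that relationship on a
curated variant table and probe its mechanistic consequences.

## What it computes

- **Hotspots** — a position is a hotspot when its variants' patient counts
  exceed the empirical 95th quantile `Q₀.₉₅` of the per-variant patient-count
  vector (strictly greater, linear-interpolation estimator; both choices
  configurable).
- **Surface mapping** — mutations are assigned to the five pVHL binding
  interfaces (A: VCB assembly, B: HIF-1α site, C: Cullin-2 side, D: pVHL30
  N-terminal tail, E: C-terminal tail). Per interface the package reports the
  normalized mutated fraction `100·|mutated positions|/|interface|` and the
  phenotype distribution of single-phenotype variants, compared across
  surfaces by χ², label-permutation or one-way ANOVA.
- **Residue-interaction networks** — typed contacts from heavy-atom geometry
  (salt bridge ≤ 4.0 Å on opposite-charge side-chain N/O, H-bond ≤ 3.5 Å
  donor–acceptor, π-π ≤ 6.5 Å ring centroids, vdW within summed radii +
  0.5 Å; priority salt_bridge > hbond > pipi > vdw), and the edges a
  substitution would remove.
- **Impairment matrices** — per phenotype, the "negative snapshot": which
  interactors' binding residues contain *no* mutation of that phenotype's
  single-phenotype subset, hence which interactions that phenotype leaves
  intact. Plus PTM sites overlapped by missense mutations.
- **Petri-net perturbations** — token-game simulation of place/transition
  nets; interaction losses are modeled as transition knockouts, constitutive
  activation as initial-token increments, and per-place token accumulation is
  compared against wild type (mean difference and log2 ratio, pseudocount 1).
- **Synthetic data** — generators for all of the above with planted ground
  truth (hotspot multipliers, phenotype enrichments, toy geometries with
  known contacts, a 9-place hypoxia net), so every claim is testable offline.

## Worked example

Knock out the pVHL-dependent HIF-degradation transition in the fixture
hypoxia net (`examples/05_petri_knockout.py`):

```python
from vhl_g2p import (SimulationConfig, build_net, compare_experiments,
                     fixture_petri_net, knockout, simulate)

net, initial = build_net(fixture_petri_net())
config = SimulationConfig(steps=2000, replicates=50, seed=7)
wild_type = simulate(net, initial, config)
perturbed = simulate(knockout(net, ["t_181"]), initial, config)
for row in compare_experiments(wild_type, perturbed)[:3]:
    print(row["place"], round(row["wild_type_mean"], 1),
          round(row["perturbed_mean"], 1), round(row["log2_ratio"], 2))
```

prints

```
hif 2.2 336.0 6.74
vessel_growth 261.6 316.3 0.27
vegf 4.9 21.2 1.92
```

Wild type holds HIF near zero (production balanced by degradation, mean 2.2
tokens); with the degradation transition disabled HIF accumulates to a mean
of 336 tokens and downstream VEGF rises 4-fold — the token-level signature of
constitutive hypoxia signaling. The other `examples/` scripts walk through
hotspot detection, surface mapping, contact typing and impairment matrices
the same way, and the `vhl-g2p` command exposes each stage from the shell
(`vhl-g2p run --config run.yaml` for the full pipeline).

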