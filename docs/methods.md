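# Methods

This note documents the models, parameters and design choices behind
`vhl-g2p`, and what the synthetic-data experiments do and do not establish.

## Coordinates and vocabulary

All residue positions are 1-based on full-length pVHL30 numbering (1–213);
ranges are inclusive. Phenotype labels from case reports are normalized into
a closed vocabulary with an `other` sink; renal manifestations (ccRCC, RCC,
renal cysts, renal carcinoma) collapse into a single `renal_disease` term
because case reports frequently omit the sub-type. The synonym map is
editable config; unknown labels are logged, never dropped. Synonymous
variants (`p.Xaa123=`) are parsed and retained but excluded from surface and
phenotype statistics by default.

## Binding-surface definitions

The five interfaces are configuration, not code. The shipped default
partitions the sequence into contiguous ranges — D: 1–59, B: 63–105,
C: 106–154, A: 155–189, E: 191–213 — chosen so that (a) the per-surface
sizes are 35/43/49/59/23 (A/B/C/D/E), the denominators used in normalized
mutated-fraction reporting, and (b) every residue with a published surface
assignment lands on its surface (Arg167/Arg161 on A, Tyr98/Ser65/Asn78/Pro81
on B, Ala149/Ser111 on C, Ser33/38/43 on D, Arg200 on E). The exact
membership of the real interfaces is not published residue-by-residue, so
this is an explicit best-effort reconstruction; users with a better
partition override it with one YAML file. Positions outside every surface
(60–62, 190) contribute to overall statistics only. Records touching several
surfaces count once per surface by default (`all-match`); a `first-match`
policy is available.

## Hotspot rule

The hotspot threshold is the empirical quantile (default level 0.95) of the
per-variant patient-count vector, using linearly interpolated order
statistics (the common statistical-environment default; a nearest-rank
estimator is selectable). Variants with counts strictly greater than the
threshold survive (a ≥ flag exists), and surviving variants are collapsed to
positions ranked by total patient burden, ties broken by ascending position.
Computing the quantile per variant and collapsing afterwards (rather than
per position) is the default because the count vector is naturally indexed
by variant; `aggregate_by="position"` gives the alternative reading. On
heavy-tailed counts the strict rule flags well under 5% of positions (the
measured null rate on geometric counts is ≈ 2%), because the quantile lands
on a tied small value and only the genuine tail exceeds it.

## Surface–phenotype statistics

Mutated fractions are counts of *distinct* mutated positions over interface
size, rounded to integer percent; distributions are percentages of
single-phenotype records per surface, one decimal. Cross-surface differences
use, by default, Pearson's χ² on the surface × phenotype contingency table
(matching the categorical structure of the question); a label-permutation
test with the same statistic (seeded, add-one smoothed, 10,000 shuffles
default) provides an exact-conditional alternative that converges to the χ²
p-value on well-filled tables; one-way ANOVA on per-position mutation counts
grouped by surface is provided for the count-distribution reading.
All-zero phenotype columns are dropped with a log entry. The significance
threshold is 0.05 with no multiple-testing correction by default (a
Bonferroni option exists but is off, matching common practice for a single
planned comparison).

## Residue-interaction geometry

Contact typing is deliberately simple and fully recorded in outputs:
salt bridge — opposite-charge side-chain N/O pair (Lys NZ, Arg NE/NH1/NH2,
His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2) within 4.0 Å; hydrogen bond —
donor/acceptor heavy atoms (side chains plus backbone N/O) within 3.5 Å with
no angular term; π-π — aromatic ring centroids (Phe/Tyr/Trp/His) within
6.5 Å; van der Waals — any heavy-atom pair within summed radii + 0.5 Å
(C 1.70, N 1.55, O 1.52, S 1.80 Å). One edge per residue pair, keeping the
highest-priority type (salt_bridge > hbond > pipi > vdw). Sequence-adjacent
pairs (|i−j| < 2) are excluded to suppress trivial backbone contacts; only
the first model of a PDB file is read; altlocs resolve to highest occupancy;
waters are excluded; residues with missing side-chain atoms degrade to
whatever typed atoms remain, ultimately vdW. There is no angle-dependent
H-bond energy, ionic-cluster merging or interface-area computation — the
aim is reproducible qualitative edges, not a full interaction-energy model.

## Impairment analysis

"Affected" is exact positional membership of a mutation in an interactor's
binding residues; a ±k-residue margin is available (default 0) since binding
blocks are themselves approximate. Rows are normalized phenotype terms of
single-phenotype variants (renal manifestations merged first). A phenotype
with zero records leaves every interactor vacuously unaffected and is
flagged as such in the row's provenance. PTM overlap requires a missense
mutation exactly at the modified residue.

## Petri-net semantics

Nets are ordinary place/transition nets with positive integer arc weights;
validation rejects non-bipartite or dangling arcs. The default firing policy
is seeded random single-fire: each step picks one enabled transition
uniformly at random; a maximal-step policy (fire a random maximal set of
still-enabled transitions per round) covers the other common reading of
"simulation steps". Deadlocks are recorded and the marking held, never an
error. Replicate r uses seed + r, so experiments are bit-reproducible.
Knockouts disable transitions without touching structure; marking
perturbations add tokens pointwise. Comparisons report per-place mean
difference and log2 ratio with pseudocount 1, ranked by |difference|.
Default inspection horizon is 2,000 steps; perturbation increments default
to +5 tokens and conclusions are reported relative to wild type so direction
is robust to the magnitude choice.

The shipped fixture net is a 9-place, 8-transition distillation of the
hypoxia response: a HIF source, a pVHL-catalyzed degradation transition
consuming two HIF tokens per firing (the weight makes wild-type HIF mean
drift negative, hence bounded, under uniform firing), a catalytic
HIF→VEGF→vessel-growth branch, and an AKT activation/inhibition cycle
feeding MAPK/glycolysis/POMC. Alias ids (p_54, p_38, p_39, p_60, t_181,
t_109) map published pathway-model node names onto fixture elements so the
same perturbation commands run end-to-end; when a user supplies the full
published pathway net, the same aliases address its real nodes.

## Synthetic-data generator

The mutation generator emulates the statistical structure of a curated
variant table: positions uniform over 1–213 (planted hotspots are guaranteed
at least one variant and have patient counts multiplied by their planted
factor), patient counts geometric with p = 0.9 (most variants reported in a
single patient — the heavy-tailed shape of curated counts), phenotype sets
drawn from base rates reflecting the predominance of renal disease and
hemangioblastoma, a 45% single-phenotype fraction (echoing the roughly
0.44 single-phenotype share of curated VHL reports), and optional
surface-conditional odds multipliers (multiplying a term's unnormalized
weight multiplies its odds against all other terms). A JSON sidecar freezes
the planted truth. "Recovery" of a planted hotspot means the planted
position is detected and top-ranked. The planted-enrichment power
experiment converts a probability shift into an odds multiplier via
`enrichment_multiplier` (base 0.35 → target 0.85, the scale of the
renal-disease contrast reported for the pVHL30 tail).

The generator does not model: position-dependent mutability, germline vs
somatic provenance, patient-count correlation between variants at one
position, or real interactor binding footprints. Passing recovery and power
tests therefore shows the estimators are correct and well-calibrated under
the stated sampling model, not that real curated data meet that model. The
separate `synthetic_vhl_curation` fixture is a deterministic, hand-built
stand-in for a curated mutation/interactor/PTM collection used to exercise
the impairment and PTM mechanics end-to-end; its tables are synthetic and
labelled as such.

Toy structures are ideal-geometry fragments (poly-Ala helix; Arg/Glu pair
with closest charged atoms at an exact requested distance; parallel Phe
rings at an exact centroid distance) written as plain PDB with sidecar
truth; they exercise every typing rule without real crystallographic noise.

## Problem sizes and numerical choices

Acceptance experiments use 500-variant tables, 100 replicates for recovery
and power, 20 replicates for null/exactness rates, 50 replicates × 2,000
steps for Petri experiments, 10,000 permutation shuffles, and a 1,000-net
invariant sweep at 25 steps — sizes at which the measured rates are stable
to a few percent across seeds. Quantile agreement with the order-statistic
oracle is asserted to 1e-9; permutation p-values are compared within three
Monte-Carlo standard errors; rounding follows the reporting conventions
(integer percent for mutated fractions, one decimal for distributions).

## Known limitations

- Surface memberships are a reconstruction (see above); mutated-fraction
  numerators on real data depend on them.
- H-bond detection without angles over-calls contacts relative to
  energy-based tools; treat hbond edges as candidate interactions.
- The χ² test on sparse surface × phenotype tables relies on the asymptotic
  null; the permutation method is the safer choice for small subsets.
- Petri results are policy-dependent; only direction-of-change claims on
  the fixture net are asserted, not token magnitudes.
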