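"""Mutation hotspot detection by the patient-count quantile rule.

A hotspot is a protein position whose variants' patient counts exceed the
empirical 95th quantile of the dataset's per-variant patient-count vector.
Variants surviving the threshold are collapsed to the distinct positions they
occupy, ranked by total patient burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

QUANTILE_METHODS = ("linear", "nearest_rank")


@dataclass(frozen=True)
class HotspotParams:
    """Parameters of the quantile rule.

    quantile_level
        Fraction in (0, 1); default 0.95 (the 95th quantile, p = 0.05).
    strict
        If True (default), keep variants with count strictly greater than the
        threshold; if False, greater-or-equal.
    aggregate_by
        "variant": the quantile is computed over per-variant counts, then
        survivors are collapsed to positions (default).  "position": counts
        are first summed per position and the quantile taken over positions.
    estimator
        "linear" (interpolated order statistics) or "nearest_rank".
    """

    quantile_level: float = 0.95
    strict: bool = True
    aggregate_by: str = "variant"
    estimator: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must be in (0, 1)")
        if self.aggregate_by not in ("variant", "position"):
            raise ValueError("aggregate_by must be 'variant' or 'position'")
        if self.estimator not in QUANTILE_METHODS:
            raise ValueError(f"estimator must be one of {QUANTILE_METHODS}")


@dataclass(frozen=True)
class PositionSummary:
    """Aggregated burden at one hotspot position."""

    position: int
    total_patients: int
    variants: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def n_distinct_variants(self) -> int:
        return len(self.variants)


def patient_count_quantile(counts, level: float, estimator: str = "linear") -> float:
    """Empirical quantile of a patient-count vector.

    The default estimator linearly interpolates order statistics (the common
    statistical-environment default); ``nearest_rank`` takes the smallest
    order statistic with cumulative frequency >= level.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    method = {"linear": "linear", "nearest_rank": "inverted_cdf"}[estimator]
    return float(np.quantile(arr, level, method=method))


def detect_hotspots(records, params: HotspotParams | None = None) -> list[PositionSummary]:
    """Apply the quantile rule and summarize surviving positions.

    Returns one :class:`PositionSummary` per hotspot position, sorted by
    total_patients descending, ties broken by ascending position.  The
    summary's variant list covers *all* variants at the position (so variant
    multiplicity is reported even when only one variant crossed the
    threshold).
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    params = params or HotspotParams()

    if params.aggregate_by == "variant":
        counts = [r.n_patients for r in records]
        thr = patient_count_quantile(counts, params.quantile_level, params.estimator)
        selected = [r for r in records
                    if (r.n_patients > thr if params.strict else r.n_patients >= thr)]
        positions = {r.position for r in selected}
    else:
        per_pos: dict[int, int] = {}
        for r in records:
            per_pos[r.position] = per_pos.get(r.position, 0) + r.n_patients
        thr = patient_count_quantile(list(per_pos.values()), params.quantile_level,
                                     params.estimator)
        positions = {p for p, c in per_pos.items()
                     if (c > thr if params.strict else c >= thr)}

    summaries = []
    for pos in positions:
        at_pos = [r for r in records if r.position == pos]
        by_mut: dict[str, int] = {}
        for r in at_pos:
            by_mut[r.mut_aa] = by_mut.get(r.mut_aa, 0) + r.n_patients
        variants = tuple(sorted(by_mut.items(), key=lambda kv: (-kv[1], kv[0])))
        summaries.append(PositionSummary(position=pos,
                                         total_patients=sum(by_mut.values()),
                                         variants=variants))
    summaries.sort(key=lambda s: (-s.total_patients, s.position))
    return summaries


def variant_multiplicity(records, position: int) -> int:
    """Number of distinct substitutions reported at a position (0 if none)."""
    return len({r.mut_aa for r in records if r.position == position})


def write_hotspot_table(summaries, path, params: HotspotParams | None = None) -> None:
    from . import __version__
    params = params or HotspotParams()
    with open(path, "w") as fh:
        fh.write(f"# vhl-g2p {__version__} hotspots "
                 f"quantile={params.quantile_level} strict={params.strict} "
                 f"aggregate_by={params.aggregate_by} estimator={params.estimator}\n")
        fh.write("position\ttotal_patients\tn_distinct_variants\tvariants\n")
        for s in summaries:
            var_text = ",".join(f"{aa}:{n}" for aa, n in s.variants)
            fh.write(f"{s.position}\t{s.total_patients}\t{s.n_distinct_variants}\t{var_text}\n")
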