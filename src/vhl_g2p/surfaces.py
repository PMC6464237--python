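"""Binding-surface genotype-phenotype mapping.

Maps missense mutations onto the five pVHL binding interfaces, computes the
normalized mutated fraction per interface, builds per-surface phenotype
distributions (over single-phenotype variants) and tests cross-surface
differences with chi-square, permutation or one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MutationRecord, SurfaceDefinition
from .phenotypes import VOCABULARY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurfaceMutationStats:
    """Mutated-position burden of one interface.

    ``mutated_fraction_pct`` is 100 * n_mutated_positions / interface_size
    rounded to the nearest integer percent.
    """

    surface_id: str
    n_mutated_positions: int
    interface_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_mutated_positions <= self.interface_size:
            raise ValueError("mutated positions outside [0, interface size]")

    @property
    def mutated_fraction_pct(self) -> int:
        return round(100.0 * self.n_mutated_positions / self.interface_size)


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Percentage of records carrying each phenotype on one surface."""

    surface_id: str  # a surface id or "overall"
    proportions: tuple[tuple[str, float], ...]  # (term, percent to one decimal)
    n_records: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.proportions)


@dataclass(frozen=True)
class SurfaceComparisonResult:
    surfaces: tuple[str, ...]
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def assign_surface(position: int, defs) -> set[str]:
    """All surfaces whose residue set contains the position (may be empty)."""
    return {d.surface_id for d in defs if position in d}


def missense(records):
    """Drop synonymous variants (retained in parsing, excluded from stats)."""
    return [r for r in records if not r.is_synonymous]


def mutated_fraction(records, definition: SurfaceDefinition) -> SurfaceMutationStats:
    """Distinct mutated positions on a surface, normalized by its size.

    Counting is over distinct positions, so duplicated records at one
    position do not inflate the fraction.
    """
    if not definition.residues:
        raise ValueError("empty surface definition")
    positions = {r.position for r in records if r.position in definition}
    return SurfaceMutationStats(surface_id=definition.surface_id,
                                n_mutated_positions=len(positions),
                                interface_size=definition.size)


def _records_on(records, surface_id: str, defs, overlap: str = "all"):
    if surface_id == "overall":
        return list(records)
    by_id = {d.surface_id: d for d in defs}
    if overlap == "all":
        return [r for r in records if r.position in by_id[surface_id]]
    # first-match policy: a position counts only for the first surface
    # (alphabetical) containing it
    out = []
    ordered = sorted(by_id)
    for r in records:
        hits = [sid for sid in ordered if r.position in by_id[sid]]
        if hits and hits[0] == surface_id:
            out.append(r)
    return out


def phenotype_distribution(records, surface_id: str, defs=None,
                           overlap: str = "all") -> PhenotypeDistribution:
    """Phenotype percentages among records mapping to one surface.

    ``records`` should already be restricted to single-phenotype missense
    variants.  A record carrying several phenotype terms contributes to each
    term's numerator; percentages are over records and reported to one
    decimal.  A surface with no records yields an empty distribution.
    """
    sub = _records_on(records, surface_id, defs or [], overlap)
    n = len(sub)
    if n == 0:
        return PhenotypeDistribution(surface_id=surface_id, proportions=(), n_records=0)
    counts: dict[str, int] = {}
    for r in sub:
        for term in r.phenotypes:
            counts[term] = counts.get(term, 0) + 1
    props = tuple(sorted(((t, round(100.0 * c / n, 1)) for t, c in counts.items()),
                         key=lambda kv: (-kv[1], kv[0])))
    return PhenotypeDistribution(surface_id=surface_id, proportions=props, n_records=n)


def contingency_table(records, defs, overlap: str = "all") -> pd.DataFrame:
    """Surface x phenotype table of record counts (single-phenotype records)."""
    rows = {}
    for d in sorted(defs, key=lambda d: d.surface_id):
        sub = _records_on(records, d.surface_id, defs, overlap)
        counts = dict.fromkeys(VOCABULARY, 0)
        for r in sub:
            for term in r.phenotypes:
                counts[term] += 1
        rows[d.surface_id] = counts
    return pd.DataFrame(rows).T


def _clean_table(table: pd.DataFrame) -> pd.DataFrame:
    zero_cols = [c for c in table.columns if table[c].sum() == 0]
    if zero_cols:
        logger.info("dropping all-zero phenotype columns: %s", zero_cols)
        table = table.drop(columns=zero_cols)
    table = table.loc[table.sum(axis=1) > 0]
    if len(table) < 2:
        raise ValueError("need >= 2 non-empty groups to compare")
    return table


def compare_surfaces_table(table: pd.DataFrame, method: str = "chi_square",
                           n_permutations: int = 10_000,
                           seed: int = 0) -> SurfaceComparisonResult:
    """Test for differences between surfaces from a surface x phenotype table.

    chi_square: Pearson chi-square of independence on the contingency table.
    permutation: same statistic, null built by shuffling surface labels over
    records (seeded); p is the fraction of shuffles with statistic >= observed
    (add-one smoothed).
    """
    table = _clean_table(table)
    obs = table.to_numpy(dtype=float)
    surfaces = tuple(table.index)
    # identical row profiles give chi2 exactly 0, p exactly 1 by construction
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    if method == "chi_square":
        return SurfaceComparisonResult(surfaces=surfaces, statistic=float(chi2),
                                       p_value=float(p), method=method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        # expand the table back to per-record labels
        n_rows, n_cols = obs.shape
        row_labels = np.repeat(np.arange(n_rows), obs.sum(axis=1).astype(int))
        col_labels = np.concatenate([np.repeat(np.arange(n_cols), obs[i].astype(int))
                                     for i in range(n_rows)])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(row_labels)
            t = np.zeros_like(obs)
            np.add.at(t, (perm, col_labels), 1.0)
            # chi2 statistic with expected from margins (margins are invariant)
            exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.nansum((t - exp) ** 2 / exp)
            if s >= chi2 - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_permutations + 1)
        return SurfaceComparisonResult(surfaces=surfaces, statistic=float(chi2),
                                       p_value=float(p_perm), method=method)
    raise ValueError(f"unknown method {method!r} for table comparison")


def compare_surfaces(records, defs, method: str = "chi_square",
                     n_permutations: int = 10_000, seed: int = 0,
                     overlap: str = "all") -> SurfaceComparisonResult:
    """Cross-surface difference test on records.

    For ``anova``, a one-way ANOVA on per-position mutation counts grouped by
    surface; for ``chi_square``/``permutation``, the phenotype contingency
    table route (see :func:`compare_surfaces_table`).
    """
    if method == "anova":
        groups, ids = [], []
        for d in sorted(defs, key=lambda d: d.surface_id):
            per_pos = {p: 0 for p in d.residues}
            for r in records:
                if r.position in d:
                    per_pos[r.position] += 1
            if sum(per_pos.values()) > 0:
                groups.append(np.array(list(per_pos.values()), dtype=float))
                ids.append(d.surface_id)
        if len(groups) < 2:
            raise ValueError("need >= 2 non-empty groups to compare")
        if all(np.array_equal(g, groups[0]) for g in groups[1:]):
            return SurfaceComparisonResult(surfaces=tuple(ids), statistic=0.0,
                                           p_value=1.0, method="anova")
        f, p = stats.f_oneway(*groups)
        return SurfaceComparisonResult(surfaces=tuple(ids), statistic=float(f),
                                       p_value=float(p), method="anova")
    table = contingency_table(records, defs, overlap)
    return compare_surfaces_table(table, method=method,
                                  n_permutations=n_permutations, seed=seed)


def plot_phenotype_donut(dist: PhenotypeDistribution, path) -> None:
    """Donut chart of one phenotype distribution (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [t for t, _ in dist.proportions]
    sizes = [p for _, p in dist.proportions]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(sizes, labels=labels, wedgeprops=dict(width=0.4), startangle=90)
    ax.set_title(f"{dist.surface_id} (n={dist.n_records})")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
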