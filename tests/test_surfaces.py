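"""Surface assignment, mutated fractions, phenotype distributions, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vhl_g2p.datamodel import MutationRecord, SurfaceDefinition, format_hgvs_p
from vhl_g2p.surfaces import (
    assign_surface,
    compare_surfaces,
    compare_surfaces_table,
    contingency_table,
    mutated_fraction,
    phenotype_distribution,
)


def rec(pos, phenos=("renal_disease",), mut="W", n=1):
    wt = "A" if mut != "A" else "G"
    return MutationRecord(format_hgvs_p(wt, pos, mut), pos, wt, mut,
                          n_patients=n, phenotypes=frozenset(phenos))


@pytest.mark.parametrize("pos, expected", [
    (167, {"A"}),   # VCB-assembly face
    (98, {"B"}),    # HIF-1a substrate site
    (200, {"E"}),   # C-terminal tail
    (33, {"D"}),    # pVHL30 N-terminal tail
    (149, {"C"}),
    (62, set()),    # between surfaces
])
def test_assign_surface_defaults(pos, expected, surface_defs):
    assert assign_surface(pos, surface_defs) == expected


def test_mutated_fraction_distinct_positions():
    surface = SurfaceDefinition("X", frozenset(range(1, 11)))
    records = [rec(2), rec(5), rec(9), rec(5, mut="Q")]  # 5 mutated twice
    s = mutated_fraction(records, surface)
    assert s.n_mutated_positions == 3
    assert s.mutated_fraction_pct == 30


def test_mutated_fraction_duplication_invariant():
    surface = SurfaceDefinition("X", frozenset(range(1, 11)))
    records = [rec(2), rec(5)]
    once = mutated_fraction(records, surface)
    twice = mutated_fraction(records + records, surface)
    assert once.n_mutated_positions == twice.n_mutated_positions


def test_mutated_fraction_empty_surface_zero():
    surface = SurfaceDefinition("X", frozenset(range(1, 11)))
    assert mutated_fraction([rec(50)], surface).mutated_fraction_pct == 0


@pytest.mark.parametrize("n_mutated, size, pct", [
    (39, 43, 91), (43, 49, 88), (28, 35, 80), (15, 23, 65), (3, 10, 30),
])
def test_mutated_fraction_rounding(n_mutated, size, pct):
    surface = SurfaceDefinition("X", frozenset(range(1, size + 1)))
    records = [rec(p) for p in range(1, n_mutated + 1)]
    assert mutated_fraction(records, surface).mutated_fraction_pct == pct


def test_phenotype_distribution_single_record():
    dist = phenotype_distribution([rec(5)], "overall")
    assert dist.as_dict() == {"renal_disease": 100.0}


def test_phenotype_distribution_c_terminal_profile():
    # 27 records mirroring a C-terminal tail profile: 11 renal, 5 pheo,
    # 4 polycythemia, 4 colorectal, 2 glial, 1 other
    groups = [("renal_disease", 11), ("pheochromocytoma", 5), ("polycythemia", 4),
              ("colorectal_cancer", 4), ("glial_tumor", 2), ("other", 1)]
    records = [rec(200 + i % 10, (term,), mut="QWLMKF"[j % 6])
               for j, (term, k) in enumerate(groups) for i in range(k)]
    assert len(records) == 27
    dist = phenotype_distribution(records, "overall")
    assert dist.as_dict() == {
        "renal_disease": 40.7, "pheochromocytoma": 18.5, "polycythemia": 14.8,
        "colorectal_cancer": 14.8, "glial_tumor": 7.4, "other": 3.7,
    }


def test_phenotype_distribution_empty_surface(surface_defs):
    dist = phenotype_distribution([], "A", surface_defs)
    assert dist.n_records == 0 and dist.proportions == ()


def test_phenotype_proportions_sum_to_100(surface_defs):
    rng = np.random.default_rng(5)
    terms = ["renal_disease", "pheochromocytoma", "pnet", "polycythemia"]
    records = [rec(int(p), (terms[int(t)],)) for p, t in
               zip(rng.integers(1, 214, 200), rng.integers(0, 4, 200))]
    for sid in "ABCDE":
        dist = phenotype_distribution(records, sid, surface_defs)
        if dist.n_records:
            assert sum(dist.as_dict().values()) == pytest.approx(100.0, abs=0.1)


def test_identical_distributions_no_signal():
    table = pd.DataFrame([[10, 5, 5], [10, 5, 5]], index=["A", "B"],
                         columns=["renal", "pheo", "pnet"])
    res = compare_surfaces_table(table, method="chi_square")
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_permutation_agrees_with_exact_oracle():
    # 2x2 [[10,0],[0,10]]: compare the permutation p-value with the exact
    # hypergeometric null (Fisher) within Monte-Carlo error
    table = pd.DataFrame([[10, 0], [0, 10]], index=["A", "B"], columns=["x", "y"])
    perm = compare_surfaces_table(table, method="permutation",
                                  n_permutations=10_000, seed=1)
    exact = stats.fisher_exact(table.to_numpy())[1]
    # the permutation null over label shuffles IS the hypergeometric null
    mc_err = 3 * np.sqrt(exact * (1 - exact) / 10_000) + 2e-4
    assert perm.p_value == pytest.approx(exact, abs=mc_err)


def test_permutation_seed_reproducible():
    table = pd.DataFrame([[8, 2], [4, 6]], index=["A", "B"], columns=["x", "y"])
    p1 = compare_surfaces_table(table, method="permutation", n_permutations=2000, seed=9)
    p2 = compare_surfaces_table(table, method="permutation", n_permutations=2000, seed=9)
    assert p1.p_value == p2.p_value


def test_permutation_converges_to_chi2_large_table():
    table = pd.DataFrame([[40, 25, 30], [28, 35, 22]], index=["A", "B"],
                         columns=["x", "y", "z"])
    chi = compare_surfaces_table(table, method="chi_square")
    perm = compare_surfaces_table(table, method="permutation",
                                  n_permutations=10_000, seed=3)
    assert perm.p_value == pytest.approx(chi.p_value, abs=0.02)


def test_compare_requires_two_groups():
    table = pd.DataFrame([[10, 5]], index=["A"], columns=["x", "y"])
    with pytest.raises(ValueError):
        compare_surfaces_table(table)


def test_zero_phenotype_column_dropped():
    table = pd.DataFrame([[10, 0, 5], [8, 0, 7]], index=["A", "B"],
                         columns=["x", "never_seen", "y"])
    res = compare_surfaces_table(table, method="chi_square")
    assert np.isfinite(res.statistic) and 0 <= res.p_value <= 1


def test_anova_on_identical_groups(surface_defs):
    res = compare_surfaces([rec(p) for p in (10, 70, 110, 160, 200)],
                           surface_defs, method="anova")
    assert 0 <= res.p_value <= 1


def test_contingency_table_counts(surface_defs):
    records = [rec(10, ("renal_disease",)), rec(70, ("pheochromocytoma",)),
               rec(70, ("renal_disease",), mut="Q")]
    table = contingency_table(records, surface_defs)
    assert table.loc["D", "renal_disease"] == 1
    assert table.loc["B", "pheochromocytoma"] == 1
    assert table.loc["B", "renal_disease"] == 1
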