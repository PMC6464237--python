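"""Data model, HGVS parsing, table IO and phenotype normalization."""

import pytest
from hypothesis import given, strategies as st

from vhl_g2p.datamodel import (
    HgvsParseError,
    MutationRecord,
    format_hgvs_p,
    format_ranges,
    parse_hgvs_p,
    parse_ranges,
)
from vhl_g2p.io import (
    ConfigurationError,
    InputError,
    filter_single_phenotype,
    load_surface_config,
    parse_mutation_table,
    parse_structure,
    write_mutation_table,
)
from vhl_g2p.phenotypes import normalize_phenotype
from vhl_g2p.synthetic import generate_toy_structure


@pytest.mark.parametrize("label, expected", [
    ("p.Arg167Trp", ("R", 167, "W")),
    ("p.Arg167Gln", ("R", 167, "Q")),
    ("p.R167W", ("R", 167, "W")),
    ("p.Tyr98His", ("Y", 98, "H")),
    ("p.Arg167=", ("R", 167, "=")),
    ("Ser65Leu", ("S", 65, "L")),
])
def test_hgvs_roundtrip(label, expected):
    assert parse_hgvs_p(label) == expected
    wt, pos, mut = expected
    assert parse_hgvs_p(format_hgvs_p(wt, pos, mut)) == expected


@pytest.mark.parametrize("bad", ["p.Arg167", "c.500G>A", "p.Xyz167Trp", "167W", ""])
def test_hgvs_rejects_malformed(bad):
    with pytest.raises(HgvsParseError):
        parse_hgvs_p(bad)


def test_mutation_record_invariants():
    with pytest.raises(ValueError):
        MutationRecord("p.Arg167Arg", 167, "R", "R")  # silent non-synonymous
    with pytest.raises(ValueError):
        MutationRecord("p.Arg167Trp", 0, "R", "W")
    syn = MutationRecord("p.Arg167=", 167, "R", "=")
    assert syn.is_synonymous


@pytest.mark.parametrize("raw, term", [
    ("ccRCC", "renal_disease"),
    ("Renal cysts", "renal_disease"),
    ("renal carcinoma", "renal_disease"),
    ("PHEOCHROMOCYTOMA", "pheochromocytoma"),
    ("cerebellar hemangioblastoma", "hemangioblastoma_cerebellar"),
    ("definitely not a phenotype", "other"),
])
def test_normalize_phenotype(raw, term):
    assert normalize_phenotype(raw).term == term


@given(st.sampled_from(["ccRCC", "RCC", "renal cysts", "pheo", "glioma",
                        "ELST", "unheard-of label"]))
def test_normalize_idempotent(raw):
    once = normalize_phenotype(raw)
    assert normalize_phenotype(once.term).term == once.term


def test_parse_mutation_table(mutation_tsv):
    report = parse_mutation_table(mutation_tsv)
    assert not report.errors
    assert len(report) == 5
    r167 = report.records[0]
    assert (r167.position, r167.wt_aa, r167.mut_aa) == (167, "R", "W")
    assert r167.phenotypes == {"renal_disease", "pheochromocytoma"}
    # renal cysts + ccRCC collapse to the single renal_disease term
    s65 = next(r for r in report.records if r.position == 65)
    assert s65.phenotypes == {"renal_disease"}


def test_parse_empty_table(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("variant\tn_patients\tphenotypes\tsource\n")
    assert len(parse_mutation_table(path)) == 0


def test_parse_reports_malformed_rows(tmp_path):
    path = tmp_path / "mixed.tsv"
    path.write_text(
        "variant\tn_patients\tphenotypes\tsource\n"
        "p.Arg167Trp\t10\tccRCC\ta\n"
        "p.Tyr98His\t5\tpheo\ta\n"
        "totally-broken\t5\tpheo\ta\n"
        "p.Ser65Leu\t2\tccRCC\ta\n"
        "p.Arg200Trp\t1\tpolycythemia\ta\n"
    )
    report = parse_mutation_table(path)
    assert len(report.records) == 4
    assert len(report.errors) == 1
    line_no, msg = report.errors[0]
    assert line_no == 4 and "totally-broken" in msg


def test_missing_required_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("mutation\tcount\nfoo\t1\n")
    with pytest.raises(ConfigurationError):
        parse_mutation_table(path)
    # a dialect mapping the logical names onto the file's columns fixes it
    report = parse_mutation_table(path, dialect={"variant": "mutation",
                                                 "n_patients": "count"})
    assert len(report.records) == 0 and len(report.errors) == 1


def test_mutation_table_roundtrip(tmp_path, mutation_tsv):
    first = parse_mutation_table(mutation_tsv).records
    out = tmp_path / "rt.tsv"
    write_mutation_table(first, out)
    second = parse_mutation_table(out).records
    assert first == second


def test_filter_single_phenotype_subset_and_idempotent(mutation_tsv):
    records = parse_mutation_table(mutation_tsv).records
    single = filter_single_phenotype(records)
    assert set(single) <= set(records)
    assert filter_single_phenotype(single) == single
    # the two-phenotype record is excluded, the collapsed renal one kept
    positions = {r.position for r in single}
    assert 167 not in positions or all(
        len(r.phenotypes) == 1 for r in single if r.position == 167)
    assert 65 in positions


def test_parse_ranges_roundtrip():
    ranges = parse_ranges("54-113,157-171")
    assert min(ranges) == 54 and max(ranges) == 171 and 130 not in ranges
    assert format_ranges(ranges) == "54-113,157-171"
    with pytest.raises(ValueError):
        parse_ranges("10-5")


def test_default_surface_sizes(surface_by_id):
    sizes = {sid: d.size for sid, d in surface_by_id.items()}
    assert sizes == {"A": 35, "B": 43, "C": 49, "D": 59, "E": 23}


def test_parse_structure_toy_helix(tmp_path):
    pdb = tmp_path / "helix.pdb"
    generate_toy_structure("helix", pdb, n_residues=12)
    st = parse_structure(pdb, "A")
    residues = st.residues()
    assert len(residues) == 12
    assert all(any(a.atom_name == "CA" for a in st.atoms_of(r)) for r in residues)


def test_parse_structure_chain_selection(tmp_path):
    pdb = tmp_path / "two_chains.pdb"
    lines = ["REMARK two chains\n"]
    for i, chain in enumerate(["V", "H"]):
        lines.append(f"ATOM  {i+1:5d}  CA  ALA {chain}{i+1:4d}    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n")
    lines.append("END\n")
    pdb.write_text("".join(lines))
    st = parse_structure(pdb, "V")
    assert {a.chain for a in st.atoms} == {"V"}
    with pytest.raises(InputError):
        parse_structure(pdb, "Z")


def test_surface_config_override(tmp_path):
    cfg = tmp_path / "surfaces.yaml"
    cfg.write_text("surfaces:\n  A: '1-10'\n  B: '20-29'\n")
    defs = load_surface_config(cfg)
    assert {d.surface_id: d.size for d in defs} == {"A": 10, "B": 10}
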