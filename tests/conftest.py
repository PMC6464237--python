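import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from vhl_g2p.io import load_surface_config  # noqa: E402
from vhl_g2p.petri import build_net  # noqa: E402
from vhl_g2p.synthetic import fixture_petri_net  # noqa: E402


@pytest.fixture(scope="session")
def surface_defs():
    return load_surface_config()


@pytest.fixture(scope="session")
def surface_by_id(surface_defs):
    return {d.surface_id: d for d in surface_defs}


@pytest.fixture()
def hypoxia_net():
    return build_net(fixture_petri_net())


@pytest.fixture()
def mutation_tsv(tmp_path):
    """A small well-formed mutation table on disk."""
    path = tmp_path / "mutations.tsv"
    path.write_text(
        "variant\tn_patients\tphenotypes\tsource\n"
        "p.Arg167Trp\t200\tccRCC;pheochromocytoma\tlit\n"
        "p.Arg167Gln\t166\tRCC\tlit\n"
        "p.Tyr98His\t50\tretinal hemangioblastoma\tlit\n"
        "p.Ser65Leu\t12\trenal cysts;ccRCC\tlit\n"
        "p.Arg200Trp\t30\tpolycythemia\tlit\n"
    )
    return path
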