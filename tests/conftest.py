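import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("fracres").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scheme():
    from fracres import FunctionalScheme

    return FunctionalScheme.default()


@pytest.fixture(scope="session")
def mini_dag(default_scheme, tmp_path_factory):
    """The generated miniature ontology, loaded through the OBO reader."""
    from fracres import load_obo
    from fracres.synthetic import build_mini_obo

    path = tmp_path_factory.mktemp("obo") / "mini.obo"
    path.write_text(build_mini_obo(default_scheme))
    return load_obo(path)


@pytest.fixture(scope="session")
def fig5_dag():
    """Toy DAG: a low-level secretion term inheriting two branches that
    both reach the biological-process root."""
    from fracres import GODag

    edges = [
        ("protein secretion", "secretion by cell"),
        ("protein secretion", "protein transport"),
        ("secretion by cell", "secretion"),
        ("secretion", "cellular process"),
        ("protein transport", "transport"),
        ("transport", "localization"),
        ("cellular process", "biological process"),
        ("localization", "biological process"),
    ]
    return GODag.from_edges(edges)


@pytest.fixture(scope="session")
def small_sim():
    """A modest deterministic simulation shared by read-only tests."""
    from fracres import SimConfig, simulate

    return simulate(SimConfig(n_families=1500, seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_sim, tmp_path_factory):
    from fracres import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_sim, outdir)
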