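import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ddinfer import (
    DDIPairSet,
    DomainComposition,
    PPINetwork,
    SyntheticSpec,
    generate,
)


@pytest.fixture
def toy_chain():
    """Four proteins in a path; two candidate pairs (A,B) and (A,C)."""
    network = PPINetwork.from_edges([("P1", "P2"), ("P2", "P3"), ("P3", "P4")])
    composition = DomainComposition.from_dict(
        {"P1": {"A"}, "P2": {"B"}, "P3": {"A"}, "P4": {"C"}}
    )
    return network, composition


@pytest.fixture
def toy_triangle_hub():
    """A triangle a-b-c plus three pendant neighbors of b.

    With K=2, a, c and the pendants are poor (bin 1) and b is the hub
    (bin 2); the edges (a,b) and (b,c) close triangles through a poor
    common neighbor, so their domain pairs get weight 1/2.
    """
    network = PPINetwork.from_edges(
        [("a", "b"), ("a", "c"), ("b", "c"), ("b", "x1"), ("b", "x2"), ("b", "x3")]
    )
    composition = DomainComposition.from_dict(
        {"a": {"D1"}, "b": {"D2"}, "c": {"D3"}, "x1": {"D4"}, "x2": {"D4"}, "x3": {"D4"}}
    )
    return network, composition


@pytest.fixture(scope="session")
def default_dataset():
    """The default desk-scale synthetic dataset (~500 edges, planted DDIs)."""
    return generate(SyntheticSpec(seed=11))


def private_pair_spec(seed: int, triangle_boost: float = 0.6) -> SyntheticSpec:
    """Dataset in the near-private cover regime: single-domain proteins,
    large domain universe, substantial false-positive edges.  This is the
    structural regime where prediction totals are nearly weight-independent
    and the triangle-weight significance test is informative."""
    return SyntheticSpec(
        n_proteins=200,
        n_domains=220,
        domains_per_protein=1.0,
        planted_ddi_density=0.012,
        fp_rate=0.4,
        fn_rate=0.1,
        triangle_boost=triangle_boost,
        seed=seed,
    )
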