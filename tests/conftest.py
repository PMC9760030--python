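import pytest

from sitesim.combinatorics import BindingStep, MultisiteScheme
from sitesim.core import AgentSignature, SignatureSet, Species
from sitesim.kappa_io import parse_pattern, pattern_to_graph


@pytest.fixture(scope="session")
def pp2b_scheme():
    """The calcium activation ladder of PP2B: four uniquely named Ca sites
    filled in two reversible two-ion steps."""
    return MultisiteScheme(
        "PP2B",
        4,
        "Ca",
        (BindingStep(2, 1.0, 0.5), BindingStep(2, 2.0, 0.25)),
        activation={0: "inactive", 2: "half_active", 4: "active"},
    )


@pytest.fixture(scope="session")
def ab_signatures():
    return SignatureSet(
        [AgentSignature("A", ("x",)), AgentSignature("B", ("y",))]
    )


def species(expr: str, signatures) -> Species:
    return Species.from_graph(pattern_to_graph(parse_pattern(expr), signatures), signatures)


@pytest.fixture(scope="session")
def make_species():
    return species
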