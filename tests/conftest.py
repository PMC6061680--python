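import pytest

from pathvis.model import Interaction, build_graph


@pytest.fixture
def six_edge_fixture():
    """Six interactions over five ids; one annotated receptor, one group.

    Hand-enumerable: ids are {A, B, C, R1, TF1}; edge types cover direct and
    indirect activation, inhibition, ppi and binding, with a score spread.
    """
    interactions = [
        Interaction("R1", "A", "activation", "direct", score=0.9),
        Interaction("A", "B", "activation", "indirect", score=0.5),
        Interaction("A", "C", "inhibition", "direct", score=0.7),
        Interaction("B", "TF1", "activation", "transcriptional", score=0.2),
        Interaction("B", "C", "ppi", "direct"),
        Interaction("A", "TF1", "binding", "direct", score=0.4),
    ]
    annotations = {"R1": ("protein", "membrane"), "TF1": ("protein", "nucleus")}
    groups = {"cplx": ["A", "B"]}
    return interactions, annotations, groups


@pytest.fixture
def six_edge_graph(six_edge_fixture):
    interactions, annotations, groups = six_edge_fixture
    return build_graph(interactions, annotations, groups)
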