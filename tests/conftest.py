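import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bbmrange import AreaAlphabet, parse_chronogram

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: 4-tip worked example used throughout: root age 3, cherry (A,B) at 1,
#: cherry (C,D) at 2.
TOY_NEWICK = "((A:1,B:1):2,(C:2,D:2):1);"


@pytest.fixture
def toy_tree():
    return parse_chronogram(TOY_NEWICK)


@pytest.fixture
def toy_assignment(toy_tree):
    """Ranges: left cherry in Y, everything else in X -> one transition on
    the branch into MRCA(A,B), dated at (3+1)/2 = 2.0."""
    label_id = {toy_tree.labels[i]: int(i) for i in toy_tree.tip_ids}
    assign = {
        toy_tree.root: frozenset("X"),
        int(toy_tree.parent[label_id["A"]]): frozenset("Y"),
        int(toy_tree.parent[label_id["C"]]): frozenset("X"),
        label_id["A"]: frozenset("Y"),
        label_id["B"]: frozenset("Y"),
        label_id["C"]: frozenset("X"),
        label_id["D"]: frozenset("X"),
    }
    return assign


@pytest.fixture
def xy_alphabet():
    return AreaAlphabet.from_string("XY")


@pytest.fixture
def ten_areas():
    return AreaAlphabet.from_string("ABCDEFGHIJ")
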