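import numpy as np
import pytest

import symevol as se


@pytest.fixture(scope="session")
def clade_tree():
    """The fixed 4-taxon tree ((B,C),D,A) with 0.2-substitution branches."""
    return se.clade_tree()


@pytest.fixture(scope="session")
def equal_params():
    return se.CodonModelParams(2.0, {"background": 0.2}, se.equal_pi())


@pytest.fixture(scope="session")
def two_class_params():
    return se.CodonModelParams(
        2.0, {"background": 0.1, "foreground": 1.5}, se.equal_pi()
    )


@pytest.fixture(scope="session")
def marker_references():
    return se.synthetic_marker_references()


@pytest.fixture(scope="session")
def small_alignment(clade_tree, equal_params):
    aln, _ = se.simulate_codon_alignment(clade_tree, equal_params, 300, seed=42)
    return aln
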