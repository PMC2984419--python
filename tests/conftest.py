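import numpy as np
import pytest

from codereassign.seqio import PhyloTree
from codereassign.synthetic_data import fig1_code_states, fig1_tree


@pytest.fixture()
def rng():
    return np.random.default_rng(20101026)


@pytest.fixture(scope="session")
def fig1():
    """The shipped prose-reconstructed reference topology and code states."""
    return fig1_tree(), fig1_code_states()


@pytest.fixture()
def balanced4():
    return PhyloTree.from_newick("((A:0.3,B:0.2):0.1,(C:0.4,D:0.15):0.2);")


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
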