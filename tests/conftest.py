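import numpy as np
import pytest

from resfunc.conservation import make_aligned_set
from resfunc.synth import synth_helix, synth_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic study, generated once per session (seed 0)."""
    return synth_study(0)


@pytest.fixture()
def helix20():
    return synth_helix(20, model_id="helix20")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def msa_from_columns(columns, name="toy", reference_id=None, ids=None):
    """Build an AlignedSet from a list of column strings.

    ``columns[c][r]`` is the residue of sequence r at column c, so
    ``msa_from_columns(["AA", "C-"])`` is two sequences of width 2.
    """
    n = len(columns[0])
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return make_aligned_set(name, list(zip(ids, seqs)), reference_id or ids[0])
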