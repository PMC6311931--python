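"""Shared fixtures for MRF instances."""

import numpy as np
import pytest

from csnets.mrf import MRFInstance
from csnets.simulate import random_mrf_instance  # re-exported for tests

__all__ = ["random_mrf_instance"]


@pytest.fixture
def make_instance():
    def _make(p1, edges=()):
        p1 = np.asarray(p1, dtype=float)
        return MRFInstance(
            tf_id="TF",
            gene_id="g",
            cell_lines=[f"c{i}" for i in range(len(p1))],
            p1=p1,
            edges=list(edges),
        )

    return _make
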