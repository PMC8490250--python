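import numpy as np
import pytest

from rhdnipt.assay import FetalMarkerPanel, ReplicateCallMatrix
from rhdnipt.cohort import ASSAY_EXONS


def make_matrix(per_exon: tuple[int, int, int], ct: float = 36.0) -> ReplicateCallMatrix:
    """Build a call matrix with the given positive-call count per exon.

    Positive wells are filled replicate-first within each exon and all get
    the same ct value, which is enough to drive every interpretation rule.
    """
    calls, cts = {}, {}
    for exon, n_pos in zip(ASSAY_EXONS, per_exon):
        for rep in range(1, 4):
            pos = rep <= n_pos
            calls[(exon, rep)] = pos
            if pos:
                cts[(exon, rep)] = ct
    return ReplicateCallMatrix(calls=calls, ct=cts)


def make_markers(sry: int = 3, rassf1a: int = 3) -> FetalMarkerPanel:
    return FetalMarkerPanel(sry_calls=sry, rassf1a_calls=rassf1a)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
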