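import numpy as np
import pandas as pd
import pytest

from icgec import synthetic
from icgec.preprocess import NormalizedPair, scale_columns, scale_rows


def make_normalized_pair(n_genes, n_marks, rng, identical=False):
    """A valid NormalizedPair from random positive signal (no zeros, so the
    low-signal filter is a no-op and no genes are dropped)."""
    genes = [f"g{i}" for i in range(n_genes)]
    marks = [f"m{j}" for j in range(n_marks)]
    x1 = np.exp2(rng.normal(2, 1, size=(n_genes, n_marks)))
    x2 = x1 if identical else np.exp2(rng.normal(2, 1, size=(n_genes, n_marks)))
    d1 = pd.DataFrame(np.log2(x1 + 1), index=genes, columns=marks)
    d2 = pd.DataFrame(np.log2(x2 + 1), index=genes, columns=marks)
    ms1, ms2 = scale_columns(d1), scale_columns(d2)
    gs1, drop1 = scale_rows(ms1)
    gs2, drop2 = scale_rows(ms2)
    assert not drop1 and not drop2
    return NormalizedPair(ms1, ms2, gs1, gs2)


@pytest.fixture(scope="session")
def sim_pair_small():
    """Standard small simulated pair with planted dynamic genes (300×16)."""
    import icgec

    m1, m2, truth = synthetic.generate_paired_matrices(300, 16, 0.2, seed=11)
    pair = icgec.normalize_pair(m1, m2)
    return m1, m2, truth, pair


@pytest.fixture(scope="session")
def sim_result_small(sim_pair_small):
    import icgec

    _, _, _, pair = sim_pair_small
    return icgec.run_icgec(pair)
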