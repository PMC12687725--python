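import numpy as np
import pandas as pd
import pytest

from oomethkit import synthetic_data as synth
from oomethkit.quantify import CountTable


@pytest.fixture(scope="session")
def annotation():
    return synth.simulate_annotation(n_genes=40, n_cgis=60, n_tiles=6, seed=3)


@pytest.fixture(scope="session")
def truth_pair(annotation):
    params = synth.EffectParams()
    ctrl = synth.simulate_truth(annotation, "ctrl", params, seed=3)
    mut = synth.simulate_truth(annotation, "aKO_bKO", params, seed=3)
    return ctrl, mut


def make_count_table(counts: np.ndarray, genotypes, lengths=None, **meta_cols):
    """Small helper: CountTable from a dense matrix and genotype labels."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    libs = pd.Index([f"s{j}" for j in range(counts.shape[1])], name="library")
    meta = pd.DataFrame({"genotype": list(genotypes)}, index=libs)
    for k, v in meta_cols.items():
        meta[k] = list(v)
    lengths_s = (
        pd.Series(lengths, index=genes, dtype=float) if lengths is not None else None
    )
    return CountTable(pd.DataFrame(counts, index=genes, columns=libs), meta, lengths_s)
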