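import numpy as np
import pandas as pd
import pytest

from repliprof.processing import CountMatrix, FragmentTable
from repliprof.synthetic import GenomeSpec, Origin, OriginProgram


@pytest.fixture
def toy_genome():
    return GenomeSpec((("c1", 2000),))


@pytest.fixture
def toy_genome_seq():
    # GATC at offsets 2 and 8 -> fragments [0,2), [2,8), [8,14)
    return GenomeSpec((("c1", 14),), {"c1": "AAGATCCCGATCTT"})


@pytest.fixture
def single_origin_program():
    return OriginProgram((Origin("c1", 1000, 0.0),), fork_velocity=1.0, s_phase_duration=2000.0)


def make_fragments(rows):
    """rows: list of (chrom, start, end)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["length"] = df["end"] - df["start"]
    return FragmentTable(df)


def make_matrix(values, fragments, gates=None, strains=None):
    """values: 2D array-like (fragments x experiments)."""
    values = np.asarray(values)
    cols = [f"e{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=fragments.df.index[: values.shape[0]], columns=cols)
    meta = pd.DataFrame(
        {
            "strain": strains or ["s"] * len(cols),
            "gate": gates or ["S"] * len(cols),
        },
        index=pd.Index(cols),
    )
    meta["total_reads"] = vdf.sum(axis=0)
    return CountMatrix(vdf, fragments, meta)


@pytest.fixture
def tiling_fragments():
    return make_fragments([("c1", 0, 2), ("c1", 2, 8), ("c1", 8, 14)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
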