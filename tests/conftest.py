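import numpy as np
import pytest

import deimmune as dm


@pytest.fixture
def toy_fasta(tmp_path):
    """3-record alignment; the target carries 2 gaps in 10 columns."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">target\nAC-DEFG-HI\n"
        ">homolog1\nACQDEFGAHI\n"
        ">homolog2\nAC-DWFG-HL\n")
    return path


@pytest.fixture
def small_population():
    """Two synthetic alleles with thresholds from a fixed context protein."""
    context = "ACDEFGHIKLMNPQRSTVWY" * 2
    alleles = []
    for s in (7, 8):
        a = dm.random_pssm(e_n=4, seed=s, name=f"HLA-{s}")
        dm.binding_threshold(a, percentile=60, background="protein",
                             context=context)
        alleles.append(a)
    return dm.Population(alleles=alleles, p={"HLA-7": 0.4, "HLA-8": 0.3})


@pytest.fixture
def toy_problem():
    return dm.make_toy_problem(dm.ToySpec(seed=3))


def weighted_alignment(matrix_rows, weights=None):
    """Build an Alignment from explicit rows, optionally with weights."""
    mat = np.array([list(r) for r in matrix_rows])
    ids = [f"s{i}" for i in range(len(matrix_rows))]
    w = None if weights is None else np.asarray(weights, dtype=float)
    return dm.Alignment(ids=ids, matrix=mat,
                        focus_columns=np.arange(mat.shape[1]),
                        target_id="s0", weights=w)
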