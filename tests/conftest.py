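import numpy as np
import pytest

from dassomb import CaseControlDataset


@pytest.fixture
def tiny_dataset() -> CaseControlDataset:
    """4 samples x 3 SNPs, both classes present, one missing call."""
    return CaseControlDataset(
        genotypes=np.array(
            [
                [0, 1, 2],
                [1, 0, -1],
                [2, 2, 0],
                [0, 1, 1],
            ],
            dtype=np.int8,
        ),
        phenotype=np.array([0, 0, 1, 1], dtype=np.int8),
        snp_ids=["rs1", "rs2", "rs3"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


def make_dataset(genotypes, phenotype, prefix="X") -> CaseControlDataset:
    g = np.asarray(genotypes, dtype=np.int8)
    return CaseControlDataset(
        genotypes=g,
        phenotype=np.asarray(phenotype, dtype=np.int8),
        snp_ids=[f"{prefix}{j + 1}" for j in range(g.shape[1])],
        sample_ids=[f"s{i + 1}" for i in range(g.shape[0])],
    )
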