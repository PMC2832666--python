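import numpy as np
import pandas as pd
import pytest

from melascan.genodata import GenotypeMatrix, PhenotypeTable, SnpRecord
from melascan.wglrh import HaplotypeSet


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t1/1\n"
    )
    return path


@pytest.fixture
def small_gm():
    """4 samples x 2 SNPs with one missing call."""
    return GenotypeMatrix(
        samples=["S1", "S2", "S3", "S4"],
        snps=[
            SnpRecord("rs1", "1", 100, "A", "G"),
            SnpRecord("rs2", "1", 200, "C", "T", ancestral="C"),
        ],
        calls=np.array([[0, 1], [1, 2], [2, -1], [1, 0]], dtype=np.int8),
    )


@pytest.fixture
def pheno_for(small_gm):
    return PhenotypeTable(
        data=pd.DataFrame(
            {
                "sample_id": small_gm.samples,
                "melanin_index": [30.0, 31.0, 29.5, 32.0],
                "sex": [0, 1, 0, 1],
            }
        )
    )


@pytest.fixture
def toy_haplotypes():
    """6 haplotypes x 6 SNPs used for brute-force EHH checks."""
    haps = np.array(
        [
            [1, 1, 1, 1, 0, 0],
            [1, 1, 1, 1, 0, 0],
            [0, 1, 1, 0, 1, 0],
            [0, 1, 1, 0, 1, 1],
            [1, 0, 1, 1, 0, 0],
            [0, 0, 1, 0, 1, 1],
        ],
        dtype=np.uint8,
    )
    return HaplotypeSet(
        haps=haps, positions=np.array([10, 20, 30, 40, 50, 60]), chrom="1"
    )
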