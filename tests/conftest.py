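import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from coevoscan.io import HaplotypePanel, SiteRecord


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
1\t150\t.\tA\tAT\t.\tPASS\t.\tGT\t0|0\t0|0\t0|1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
1\t250\t.\tG\tA,T\t.\tPASS\t.\tGT\t0|1\t0|2\t0|0
1\t300\t.\tT\tC\t.\tPASS\t.\tGT\t1|1\t1|1\t0|1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """Toy VCF: 3 biallelic SNPs, 1 indel, 1 triallelic site, phased GTs."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_panel(haps, positions=None, chrom="1"):
    haps = np.asarray(haps, dtype=np.uint8)
    if positions is None:
        positions = range(100, 100 + 100 * haps.shape[1], 100)
    sites = [SiteRecord(chrom, int(p), "A", "G", "ref") for p in positions]
    return HaplotypePanel(sites, haps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
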