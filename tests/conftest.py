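import numpy as np
import pandas as pd
import pytest

from gsblup import KinshipMatrix
from gsblup.markers import GenotypeCallSet


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tg1\tg2\tg3
1\t100\tm1\tA\tG\t.\tPASS\t.\tGT:DP:AD\t0/0:10:10,0\t0/1:8:4,4\t1/1:6:0,6
1\t200\tm2\tC\tT\t.\tPASS\t.\tGT:DP:AD\t0/1:5:4,1\t0/0:3:3,0\t./.:0:0,0
1\t300\tm3\tG\tA\t.\tPASS\t.\tGT:DP:AD\t1/1:4:0,4\t0/1:9:5,4\t0/0:12:12,0
1\t400\tm4\tT\tC\t.\tPASS\t.\tGT:DP:AD\t0/0:7:7,0\t0/0:5:5,0\t0/1:6:3,3
"""

# same calls as TOY_VCF in HapMap coding (alleles ref/alt per marker)
TOY_HAPMAP = """\
rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID\tassayLSID\tpanelLSID\tQCcode\tg1\tg2\tg3
m1\tA/G\t1\t100\t+\tNA\tNA\tNA\tNA\tNA\tNA\tAA\tAG\tGG
m2\tC/T\t1\t200\t+\tNA\tNA\tNA\tNA\tNA\tNA\tCT\tCC\tNN
m3\tG/A\t1\t300\t+\tNA\tNA\tNA\tNA\tNA\tNA\tAA\tGA\tGG
m4\tT/C\t1\t400\t+\tNA\tNA\tNA\tNA\tNA\tNA\tTT\tTT\tTC
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_hapmap(tmp_path):
    p = tmp_path / "toy.hmp.txt"
    p.write_text(TOY_HAPMAP)
    return p


def make_callset(calls, depth=None, ref_depth=None, alt_depth=None, alleles=None):
    """Small helper: build a GenotypeCallSet from a (n, m) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeCallSet(
        genet_ids=[f"g{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        alleles=alleles or [("A", "B")] * m,
        calls=calls,
        depth=None if depth is None else np.asarray(depth, float),
        ref_depth=None if ref_depth is None else np.asarray(ref_depth, float),
        alt_depth=None if alt_depth is None else np.asarray(alt_depth, float),
    )


def random_kinship(n, m=200, seed=0, ids=None):
    """Well-conditioned VanRaden-style kinship from random genotypes."""
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    mc = dos[:, poly] - 2 * p[poly]
    k = mc @ mc.T / (2 * np.sum(p[poly] * (1 - p[poly])))
    return KinshipMatrix(
        genet_ids=ids or [f"g{i}" for i in range(n)],
        values=0.5 * (k + k.T),
        theta=1.0,
    )


def blup_frame(k, values, trait="t", cycle="C1"):
    return pd.DataFrame(
        {"genet_id": k.genet_ids, "cycle": cycle, "trait": trait, "value": values}
    )
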