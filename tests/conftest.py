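import os

import pytest

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=scf1,length=100000>
##contig=<ID=scf2,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM
"""

# 6 records: 2 het passing, 1 het below depth threshold, 1 multiallelic,
# 2 homozygous — exactly 2 should survive default filtering.
VCF_RECORDS = """\
scf1\t100\t.\tA\tC\t60\tPASS\t.\tGT:AD:DP:GQ\t0/1:10,10:20:99
scf1\t200\t.\tG\tT\t60\tPASS\t.\tGT:AD:DP:GQ\t0/1:30,10:40:99
scf1\t300\t.\tA\tG\t60\tPASS\t.\tGT:AD:DP:GQ\t0/1:4,3:7:99
scf1\t400\t.\tA\tC,T\t60\tPASS\t.\tGT:AD:DP:GQ\t1/2:2,9,9:20:99
scf2\t100\t.\tT\tC\t60\tPASS\t.\tGT:AD:DP:GQ\t0/0:20,0:20:99
scf2\t200\t.\tC\tG\t60\tPASS\t.\tGT:AD:DP:GQ\t1/1:0,22:22:99
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(VCF_HEADER + VCF_RECORDS)
    return os.fspath(path)
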