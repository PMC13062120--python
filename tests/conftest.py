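"""Shared fixtures: small hand-built genotype matrices and files."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.io_core import MISSING, GenotypeMatrix


def make_matrix(dosage, positions=None, chrom="chr1", gq=None, dp=None,
                biallelic=None, samples=None):
    """Build a GenotypeMatrix from a (sites x samples) dosage list."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    positions = (np.arange(1, n_sites + 1) * 100 if positions is None
                 else np.asarray(positions))
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": positions.astype(np.int64),
        "ref": "A",
        "alt": "G",
        "site_id": None,
        "is_biallelic_snp": (np.ones(n_sites, dtype=bool) if biallelic is None
                             else np.asarray(biallelic, dtype=bool)),
    })
    return GenotypeMatrix(
        sites=sites, samples=samples, dosage=dosage,
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32))


@pytest.fixture
def toy_vcf(tmp_path):
    """3-record VCF: one indel, two SNPs; one ./. genotype."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\trs1\tA\tT\t.\tPASS\t.\tGT:GQ:DP\t0/1:30:20\t./.:.:.\t1/1:55:30
chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:GQ:DP\t0/0:50:25\t0/1:40:22\t0/0:60:28
chr1\t300\t.\tG\tC\t.\tPASS\t.\tGT:GQ:DP\t0|1:45:15\t1/1:38:19\t0/0:52:33
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_gtf(tmp_path):
    text = (
        'chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tgene_id "gA"; gene_name "alpha";\n'
        'chr1\tsrc\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\tsrc\texon\t1000\t1500\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\tsrc\tgene\t5000\t9000\t.\t-\t.\tgene_id "gB";\n'
        'chr2\tsrc\tgene\t100\t400\t.\t+\t.\tgene_id "gC"; gene_name "gamma";\n'
    )
    path = tmp_path / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def filter_fixture():
    """10-site toy: 2 indels, 1 low-call-rate site, 1 low-MAC site.

    6 sites must survive the default filters (hand-enumerated); 10 samples,
    no GQ/DP so only site-level rules apply.
    """
    n_samples = 10
    # baseline polymorphic site with MAC 5: five hets
    common = [1] * 5 + [0] * 5
    rows, biallelic = [], []
    for i in range(10):
        rows.append(list(common))
        biallelic.append(True)
    biallelic[2] = False   # "indel" record
    biallelic[7] = False   # multi-allelic record
    rows[4] = [1, MISSING, MISSING, 0, 1, 1, 0, 0, 1, 1]  # 20% missing > 10%
    rows[6] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]              # MAC 1 < 5
    return make_matrix(rows, biallelic=biallelic), 6
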