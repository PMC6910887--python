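import numpy as np
import pandas as pd
import pytest

from snp_ploidy import SimConfig, SNPPanel, make_panel

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t12345\t.\tA\tG\t50\tPASS\t.\tGT:AD\t0/1:7,8\t0/0:12,0
chr1\t20000\t.\tC\tT\t50\tPASS\t.\tGT:AD\t0/1:5,6\t0/1:4,4
chr1\t30000\t.\tG\tA,T\t50\tPASS\t.\tGT:AD\t1/2:3,4,5\t0/1:6,2,1
chr1\t40000\t.\tT\tTA\t50\tPASS\t.\tGT:AD\t0/1:5,5\t0/1:5,5
chr1\t50000\t.\tA\tC\t50\tPASS\t.\tGT\t0/1\t0/1
chr2\t100\t.\tC\tT\t50\tPASS\t.\tGT:AD\t0/1:0,0\t0/1:9,9
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture
def toy_panel():
    """Hand-built 2-chromosome panel with sizes and one gap."""
    sites = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "pos": [12345, 20000, 99999, 100, 5000],
        "ref": ["A", "C", "G", "C", "T"],
        "alt": ["G", "T", "A", "T", "C"],
        "af": [0.31, 0.12, 0.04, 0.45, 0.97],
    })
    return SNPPanel(
        sites=sites,
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        gaps={"chr1": [(500_000, 600_000)]},
        build="toy",
    )


@pytest.fixture(scope="session")
def small_genome():
    return {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000}


@pytest.fixture(scope="session")
def small_sim_cfg(small_genome):
    return SimConfig(genome=small_genome, n_panel_sites=1500, seed=0)


@pytest.fixture(scope="session")
def shared_panel(small_sim_cfg):
    return make_panel(small_sim_cfg, np.random.default_rng(0))
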