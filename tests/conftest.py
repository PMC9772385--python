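import textwrap
from pathlib import Path

import pytest
from hypothesis import settings

from editome.io_formats import read_gene_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from editome.simulate import CohortDesign, simulate_cohort

FIVE_STAGES = ("oocyte_GV", "oocyte_MII", "zygote", "2cell", "4cell")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete 7-stage cohort reused across module tests."""
    design = CohortDesign(
        seed=11, n_genes=24, n_ree=40, n_noise=60, n_snp=15,
        n_non_a2g_noise=10,
        dropout={"AG": 4, "PG": 4, "elder_mother": 2},
    )
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory) -> Path:
    """Two genes: plus-strand coding GA (two exons) and minus-strand GB
    (single exon), with CDS inside exons."""
    gtf = textwrap.dedent("""\
    chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_name "GENEA";
    chr1\ttest\texon\t301\t500\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_name "GENEA";
    chr1\ttest\tCDS\t151\t200\t.\t+\t0\tgene_id "GA"; transcript_id "GA.1"; gene_name "GENEA";
    chr1\ttest\tCDS\t301\t400\t.\t+\t0\tgene_id "GA"; transcript_id "GA.1"; gene_name "GENEA";
    chr1\ttest\texon\t1001\t1300\t.\t-\t.\tgene_id "GB"; transcript_id "GB.1"; gene_name "GENEB";
    chr1\ttest\tCDS\t1101\t1220\t.\t-\t0\tgene_id "GB"; transcript_id "GB.1"; gene_name "GENEB";
    """)
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text(gtf)
    return path


@pytest.fixture(scope="session")
def toy_models(toy_gtf):
    return read_gene_model(toy_gtf)
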