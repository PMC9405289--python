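import textwrap

import pytest

from fusiontriage import SimulationConfig, load_annotation, make_toy_annotation

# Toy two-gene annotation used across modules:
#   AAA (chr1, +): exon1 [100,250) = 150 nt, exon2 [350,560) = 210 nt;
#     CDS covers the last 90 nt of exon1 and the first 120 nt of exon2,
#     so in transcript coordinates cds = [60, 270).
#   RET (chr2, -): exon1 (5'-most) [1300,1450), exon2 [1000,1150);
#     fully coding apart from 30-nt UTR pads: cds = [30, 270).
TOY_GTF = textwrap.dedent(
    """\
    chr1\ttoy\texon\t101\t250\t.\t+\t.\tgene_id "AAA"; transcript_id "AAA-1"; gene_name "AAA";
    chr1\ttoy\texon\t351\t560\t.\t+\t.\tgene_id "AAA"; transcript_id "AAA-1"; gene_name "AAA";
    chr1\ttoy\tCDS\t161\t250\t.\t+\t.\tgene_id "AAA"; transcript_id "AAA-1"; gene_name "AAA";
    chr1\ttoy\tCDS\t351\t470\t.\t+\t.\tgene_id "AAA"; transcript_id "AAA-1"; gene_name "AAA";
    chr2\ttoy\texon\t1001\t1150\t.\t-\t.\tgene_id "RET"; transcript_id "RET-1"; gene_name "RET";
    chr2\ttoy\texon\t1301\t1450\t.\t-\t.\tgene_id "RET"; transcript_id "RET-1"; gene_name "RET";
    chr2\ttoy\tCDS\t1031\t1120\t.\t-\t.\tgene_id "RET"; transcript_id "RET-1"; gene_name "RET";
    chr2\ttoy\tCDS\t1301\t1420\t.\t-\t.\tgene_id "RET"; transcript_id "RET-1"; gene_name "RET";
    """
)


@pytest.fixture(scope="session")
def toy_gtf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("ann") / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def toy_annotation(toy_gtf_path):
    return load_annotation(toy_gtf_path)


@pytest.fixture(scope="session")
def sim_default():
    """Default simulation: toy partner + RTK annotation and references."""
    cfg = SimulationConfig(seed=7)
    ann, refs = make_toy_annotation(cfg)
    return cfg, ann, refs
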