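import numpy as np
import pytest

from lncscan.io_formats import ScoreTable
from lncscan.synthetic_data import SimulationConfig, simulate
from lncscan.transcript_model import TranscriptModel


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default desk-scale synthetic bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate(SimulationConfig(seed=42), outdir)


@pytest.fixture(scope="session")
def pipeline_results(default_bundle, tmp_path_factory):
    """Full run_all output on the default bundle."""
    from lncscan.pipeline import PipelineConfig, run_all

    p = default_bundle.paths
    cfg = PipelineConfig(
        assembled_gtf=str(p["assembled_gtf"]),
        reference_gtf=str(p["reference_gtf"]),
        genome_fasta=str(p["genome"]),
        snps=str(p["snps_vcf"]),
        score_tables={
            "cpc": str(p["cpc"]), "cnci": str(p["cnci"]), "cpat": str(p["cpat"]),
            "pfam": str(p["pfam"]), "blastx": str(p["blastx"]),
            "blastn_human": str(p["blastn_human"]), "blastn_mouse": str(p["blastn_mouse"]),
        },
        fpkm=str(p["fpkm"]),
        chain_human=str(p["chain_human"]),
        chain_mouse=str(p["chain_mouse"]),
        score_track=str(p["track"]),
        outdir=str(tmp_path_factory.mktemp("run")),
        seed=1,
    )
    from lncscan.pipeline import run_all

    return run_all(cfg)


def _t(tid, exons, strand="+", chrom="chr1", locus=None):
    return TranscriptModel(
        id=tid, locus_id=locus or tid, chrom=chrom, strand=strand, exons=tuple(exons)
    )


@pytest.fixture
def cascade_fixture():
    """Hand-built ten-transcript input exercising each cascade rule once.

    Reference: one known gene with an exon at chr1:[10000,11000).
    Expected survivors: ok1 and ok2; every other transcript fails exactly
    one step by construction.
    """
    reference = [_t("REF1.1", [(10000, 11000)], locus="REF1")]
    transcripts = [
        _t("s1", [(100, 600)]),                      # single exon
        _t("s2", [(1000, 1400)]),                    # single exon
        _t("short1", [(2000, 2090), (2200, 2290)]),  # spliced length 180
        _t("ov1", [(10500, 10700), (11500, 11700)]),  # overlaps REF1 exon
        _t("ov2", [(10999, 11110), (11800, 11900)]),  # 1-bp overlap with REF1
        _t("cp1", [(20000, 20300), (20400, 20700)]),  # CPC positive
        _t("pf1", [(30000, 30300), (30400, 30700)]),  # Pfam domain hit
        _t("bx1", [(40000, 40300), (40400, 40700)]),  # blastx hit at 1e-8
        _t("ok1", [(50000, 50300), (50400, 50700)]),
        _t("ok2", [(60000, 60300), (60400, 60700)]),
    ]
    neg = {t.id: -1.0 for t in transcripts}
    scores = ScoreTable(
        cpc_score={**neg, "cp1": 1.0},
        cnci_score=dict(neg),
        pfam_hit={"pf1": True},
        blastx_min_evalue={"bx1": 1e-8},
        cpat_coding_prob={t.id: 0.1 for t in transcripts},
    )
    expected_reasons = {
        "s1": "multiexonic", "s2": "multiexonic",
        "short1": "length_gt_200",
        "ov1": "no_known_gene_overlap", "ov2": "no_known_gene_overlap",
        "cp1": "cpc_noncoding",
        "pf1": "no_pfam_domain",
        "bx1": "no_blastx_hit",
    }
    return transcripts, reference, scores, expected_reasons


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
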