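"""Chain coverage, the >=50% conservation rule, homology and score tracks."""

import numpy as np
import pandas as pd
import pytest

from lncscan.conservation import (
    GROUPS,
    chain_coverage,
    classify_conservation,
    score_track_summary,
    transcript_homology,
    venn_summary,
)
from lncscan.io_formats import ChainAlignmentSet
from lncscan.synthetic_data import make_conservation_fixture
from lncscan.transcript_model import RegionSet, Region, TranscriptModel


def _t(tid, exons, chrom="chr1"):
    return TranscriptModel(tid, tid, chrom, "+", tuple(exons))


def _chains(blocks, label="human"):
    return ChainAlignmentSet(label, {c: [(s, e, i + 1) for i, (s, e) in enumerate(v)]
                                     for c, v in blocks.items()})


def test_chain_coverage_basic_fraction():
    t = _t("t", [(0, 1000)])
    chains = _chains({"chr1": [(100, 600)]})
    assert chain_coverage(t, chains) == pytest.approx(0.5)


def test_chain_coverage_counts_overlapping_chains_once():
    t = _t("t", [(0, 1000)])
    chains = _chains({"chr1": [(100, 200), (100, 200), (150, 250)]})
    assert chain_coverage(t, chains) == pytest.approx(150 / 1000)
    # stricter 'uniquely intersected' reading: multiply-covered bases excluded
    assert chain_coverage(t, chains, unique_only=True) == pytest.approx(50 / 1000)


def test_chain_coverage_absent_chromosome_is_zero():
    t = _t("t", [(0, 1000)], chrom="chrZ")
    assert chain_coverage(t, _chains({"chr1": [(0, 500)]})) == 0.0


def test_chain_coverage_invariant_to_block_split():
    t = _t("t", [(0, 500), (700, 1200)])
    whole = _chains({"chr1": [(100, 900)]})
    split = _chains({"chr1": [(100, 400), (400, 900)]})
    assert chain_coverage(t, whole) == pytest.approx(chain_coverage(t, split))


def test_chain_coverage_matches_per_base_oracle(rng):
    for _ in range(50):
        n_ex = int(rng.integers(1, 5))
        cursor = int(rng.integers(0, 200))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(20, 300))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(1, 100))
        t = _t("t", exons)
        blocks = []
        for _ in range(int(rng.integers(0, 6))):
            s = int(rng.integers(0, cursor))
            blocks.append((s, s + int(rng.integers(1, 400))))
        chains = _chains({"chr1": blocks})
        mask = np.zeros(cursor + 500, dtype=bool)
        for s, e in blocks:
            mask[s:e] = True
        oracle = sum(int(mask[s:e].sum()) for s, e in exons) / sum(
            e - s for s, e in exons
        )
        assert chain_coverage(t, chains) == pytest.approx(oracle)


def test_classification_boundary_inclusive():
    t = _t("t", [(0, 1000)])
    half = _chains({"chr1": [(0, 500)]}, "human")  # coverage exactly 0.50
    low = _chains({"chr1": [(0, 200)]}, "mouse")  # coverage 0.20
    call = classify_conservation(t, half, low)
    assert call.group == "human_pig_only"
    assert call.coverage_human == pytest.approx(0.5)


@pytest.mark.parametrize(
    "cov_h,cov_m,rule,expected",
    [
        (0.0, 0.0, "below_threshold_both", "pig_specific"),
        (0.0, 0.0, "zero_overlap_both", "pig_specific"),
        (0.3, 0.3, "below_threshold_both", "pig_specific"),
        (0.3, 0.3, "zero_overlap_both", "unclassified"),
    ],
)
def test_pig_specific_rule_disambiguation(cov_h, cov_m, rule, expected):
    t = _t("t", [(0, 1000)])
    ch = _chains({"chr1": [(0, int(cov_h * 1000))] if cov_h else []}, "human")
    cm = _chains({"chr1": [(0, int(cov_m * 1000))] if cov_m else []}, "mouse")
    assert classify_conservation(t, ch, cm, pig_specific_rule=rule).group == expected


def test_groups_partition_and_threshold_monotonicity():
    ts, ch, cm = make_conservation_fixture((8, 1, 5, 6), seed=2)
    calls = [classify_conservation(t, ch, cm) for t in ts]
    counts = {g: sum(c.group == g for c in calls) for g in GROUPS}
    assert counts == {
        "human_pig_only": 8, "pig_mouse_only": 1, "all_three": 5, "pig_specific": 6
    }
    assert sum(counts.values()) == len(ts)
    prev_spec, prev_cons = -1, None
    for thr in (0.2, 0.5, 0.75, 0.9):
        calls = [classify_conservation(t, ch, cm, threshold=thr) for t in ts]
        n_spec = sum(c.group == "pig_specific" for c in calls)
        assert n_spec >= prev_spec  # pig_specific never shrinks
        cons = {
            g: sum(c.group in (g, "all_three") for c in calls)
            for g in ("human_pig_only", "pig_mouse_only")
        }
        if prev_cons is not None:
            for g in cons:  # per-species conserved totals never grow
                assert cons[g] <= prev_cons[g]
        prev_spec, prev_cons = n_spec, cons


def test_venn_summary_all_one_group():
    ts, ch, cm = make_conservation_fixture((0, 0, 0, 5), seed=1)
    venn = venn_summary([classify_conservation(t, ch, cm) for t in ts])
    by_group = venn.set_index("group")
    assert by_group.loc["pig_specific", "percent"] == 100.0
    assert by_group.loc["human_pig_only", "count"] == 0
    assert venn.percent.sum() == pytest.approx(100.0, abs=0.2)


def test_venn_summary_empty_is_undefined():
    with pytest.raises(ValueError):
        venn_summary([])


def test_transcript_homology_cutoff():
    hits = {
        "human": {"t1": [("h1", 1e-4, 120)], "t2": [("h2", 0.02, 120)]},
        "mouse": {},
    }
    calls, table = transcript_homology(hits, ["t1", "t2", "t3"])
    by_id = {c.transcript_id: c for c in calls}
    assert by_id["t1"].aligned_human is True
    assert by_id["t2"].aligned_human is False  # E above 0.01 cutoff
    assert by_id["t3"].aligned_human is False
    human_row = table.set_index("species").loc["human"]
    assert human_row.aligned == 1 and human_row.percent == pytest.approx(33.3)


def test_transcript_homology_min_length_floor():
    hits = {"human": {"t1": [("h1", 1e-4, 30)]}, "mouse": {}}
    calls, _ = transcript_homology(hits, ["t1"], min_aligned_length=50)
    assert calls[0].aligned_human is False


def test_score_track_means():
    regions = RegionSet(
        [Region("chr1", 0, 100, "exon", "a"), Region("chr1", 200, 300, "exon", "b"),
         Region("chr2", 0, 50, "exon", "c")]
    )
    track = {"chr1": [(0, 100, 0.8), (200, 250, 1.0), (250, 300, 0.0)]}
    per_region, cumulative = score_track_summary(regions, track)
    means = per_region.set_index("owner_id").mean_score
    assert means["a"] == pytest.approx(0.8)
    assert means["b"] == pytest.approx(0.5)
    assert np.isnan(means["c"])  # no covered base -> missing
    assert len(cumulative) == 101
    # fraction of scored exons (0.5 and 0.8) at grid points
    assert cumulative.exon.iloc[0] == 0.0
    assert cumulative.exon.iloc[-1] == 1.0


def test_track_cumulative_curves_ordered_by_planted_means(default_bundle):
    from lncscan.io_formats import read_score_track
    from lncscan.transcript_model import regions_for

    truth = default_bundle.truth.transcripts
    lnc_ids = set(truth[truth.category == "lnc"].transcript_id)
    lnc = [t for t in default_bundle.assembled if t.id in lnc_ids]
    track = read_score_track(default_bundle.paths["track"])
    regions = regions_for(lnc, classes=("exon", "intron"))
    _, cumulative = score_track_summary(regions, track)
    # exons planted more conserved than introns: exon CDF lies at/below intron CDF
    assert (cumulative.exon <= cumulative.intron + 1e-12).all()
    assert (cumulative.exon < cumulative.intron).any()
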