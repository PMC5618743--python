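"""GC content, SNP density, rank tests and qPCR arithmetic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncscan.feature_stats import (
    class_summaries,
    delta_delta_ct,
    expression_summary,
    format_pvalue,
    gc_content,
    gc_content_region,
    mann_whitney_u,
    snp_density,
)
from lncscan.io_formats import GenomeSequence, SNPSet
from lncscan.transcript_model import Region, RegionSet

DNA = st.text(alphabet="ACGTN", min_size=0, max_size=200)


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GCGCGCAT", 0.75), ("ANNNG", 0.5), ("atgc", 0.5)],
)
def test_gc_content_examples(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_all_n_is_missing():
    assert math.isnan(gc_content("NNNN"))
    assert math.isnan(gc_content(""))


@settings(derandomize=True, max_examples=100)
@given(DNA)
def test_gc_invariant_under_reverse_complement(seq):
    rc = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    a, b = gc_content(seq), gc_content(rc)
    assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=50).map("".join),
       st.lists(st.sampled_from("ACGT"), min_size=1, max_size=50).map("".join))
def test_gc_of_concatenation_is_length_weighted_mean(a, b):
    combined = gc_content(a + b)
    weighted = (gc_content(a) * len(a) + gc_content(b) * len(b)) / (len(a) + len(b))
    assert combined == pytest.approx(weighted)


def test_gc_region_bounds_error():
    genome = GenomeSequence({"chr1": "ACGT" * 10})
    with pytest.raises(IndexError):
        gc_content_region(genome, "chr1", 30, 50)


def test_snp_density_examples():
    snps = SNPSet({"chr1": np.arange(100, 150)})  # 50 SNPs
    regions = RegionSet([Region("chr1", 0, 2000, "exon", "t")])
    assert snp_density(regions, snps) == pytest.approx(25.0)
    empty = RegionSet([Region("chr2", 0, 500, "exon", "t")])
    assert snp_density(empty, snps) == 0.0


def test_snp_density_boundary_membership():
    # SNP at p belongs to [start, end) iff start <= p < end
    snps = SNPSet({"chr1": np.array([100, 199, 200])})
    regions = RegionSet([Region("chr1", 100, 200, "exon", "t")])
    assert snp_density(regions, snps) == pytest.approx(1000 * 2 / 100)


def test_snp_density_matches_per_base_oracle(rng):
    positions = np.sort(rng.choice(5000, size=400, replace=False))
    snps = SNPSet({"chr1": positions})
    regions = []
    for i in range(100):
        start = int(rng.integers(0, 4900))
        end = start + int(rng.integers(10, 100))
        regions.append(Region("chr1", start, end, "random", f"w{i}"))
    rs = RegionSet(regions)
    oracle_count = sum(
        1 for r in regions for p in positions if r.start <= p < r.end
    )
    expected = 1000.0 * oracle_count / rs.total_length
    assert snp_density(rs, snps) == pytest.approx(expected)


def test_pooled_density_invariant_to_order_and_split():
    snps = SNPSet({"chr1": np.array([5, 50, 75, 150])})
    whole = RegionSet([Region("chr1", 0, 200, "exon", "t")])
    split = RegionSet(
        [Region("chr1", 80, 200, "exon", "t"), Region("chr1", 0, 80, "exon", "t")]
    )
    assert snp_density(whole, snps) == pytest.approx(snp_density(split, snps))


def test_snp_density_zero_length_missing():
    assert math.isnan(snp_density(RegionSet([]), SNPSet({})))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _enumeration_oracle(x, y):
    """Independent route: U from pairwise win counts; p from the full
    permutation-null distribution of U."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)

    def u_of(a, b):
        return sum(
            1.0 if ai > bj else 0.5 if ai == bj else 0.0 for ai in a for bj in b
        )

    u_obs = u_of(x, y)
    pooled = x + y
    dist = []
    for combo in itertools.combinations(range(n + m), n):
        mask = set(combo)
        xa = [pooled[i] for i in mask]
        yb = [pooled[i] for i in range(n + m) if i not in mask]
        dist.append(u_of(xa, yb))
    center = n * m / 2
    d = abs(u_obs - center)
    p = sum(1 for u in dist if abs(u - center) >= d - 1e-9) / len(dist)
    return u_obs, p


def test_mwu_separated_samples_exact():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mwu_identical_multisets_p_one():
    _, p = mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_mwu_empty_input_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_mwu_exact_agrees_with_enumeration_oracle(rng):
    for n in range(1, 6):
        for m in range(1, 6):
            if n + m > 10:
                continue
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.integers(0, 6, size=m).astype(float)
            u_mine, p_mine = mann_whitney_u(x, y)
            u_oracle, p_oracle = _enumeration_oracle(x, y)
            assert u_mine == pytest.approx(u_oracle)
            assert p_mine == pytest.approx(p_oracle)


def test_mwu_exact_agrees_with_scipy_on_tie_free_data(rng):
    for n, m in [(3, 3), (4, 5), (2, 7), (6, 6)]:
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        u_mine, p_mine = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u_mine == pytest.approx(float(ref.statistic))
        assert p_mine == pytest.approx(float(ref.pvalue))


def test_format_pvalue_floor():
    assert format_pvalue(1e-20) == "< 2.2e-16"
    assert format_pvalue(0.035) == "0.035"


# ---------------------------------------------------------------------------
# class summaries and expression
# ---------------------------------------------------------------------------


def test_class_summaries_recover_generator_targets(default_bundle):
    bundle = default_bundle
    truth = bundle.truth
    lnc_ids = set(
        truth.transcripts[truth.transcripts.category == "lnc"].transcript_id
    )
    lnc = [t for t in bundle.assembled if t.id in lnc_ids]
    table = class_summaries(
        {"lnc": lnc, "pcg": bundle.reference},
        bundle.genome,
        bundle.snps,
        random_n=0,
    ).set_index(["category", "feature_class"])
    for category in ("lnc", "pcg"):
        for fclass in ("exon", "intron", "upstream", "downstream"):
            row = table.loc[(category, fclass)]
            assert row.gc_fraction == pytest.approx(
                truth.planted_gc(category, fclass), abs=1e-9
            )
            assert row.snp_density == pytest.approx(
                truth.planted_snp_density(category, fclass), abs=1e-9
            )


def test_class_summaries_empty_category_dropped(default_bundle):
    table = class_summaries(
        {"empty": [], "pcg": default_bundle.reference[:3]},
        default_bundle.genome,
        default_bundle.snps,
        random_n=0,
    )
    assert set(table.category) == {"pcg"}


def test_expression_summary_rejects_negative():
    with pytest.raises(ValueError):
        expression_summary({"lnc": [1.0, -2.0]})
    table = expression_summary({"lnc": [1.0, 3.0], "pcg": [10.0]})
    assert table.set_index("category").loc["lnc", "mean_fpkm"] == pytest.approx(2.0)


@pytest.mark.parametrize(
    "cts,expected",
    [
        ((25, 20, 24, 20), 0.5),
        ((20, 20, 20, 20), 1.0),
        ((18, 20, 20, 20), 4.0),
    ],
)
def test_delta_delta_ct(cts, expected):
    assert delta_delta_ct(*cts) == pytest.approx(expected)


def test_delta_delta_ct_requires_finite():
    with pytest.raises(ValueError):
        delta_delta_ct(float("nan"), 20, 20, 20)
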