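"""Transcript arithmetic: lengths, introns, flanks, overlap, random windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncscan.io_formats import GenomeSequence
from lncscan.transcript_model import (
    TranscriptModel,
    exonic_overlap,
    flanks,
    introns,
    random_windows,
    regions_for,
    spliced_length,
)


def _t(exons, strand="+", tid="t", chrom="chr1"):
    return TranscriptModel(tid, tid, chrom, strand, tuple(exons))


@st.composite
def exon_lists(draw):
    n = draw(st.integers(1, 6))
    cursor = draw(st.integers(0, 50))
    exons = []
    for _ in range(n):
        length = draw(st.integers(1, 200))
        exons.append((cursor, cursor + length))
        cursor += length + draw(st.integers(1, 100))
    return exons


def test_invalid_transcripts_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        _t([(10, 10)])
    with pytest.raises(ValueError, match="overlap or abut"):
        _t([(0, 100), (100, 200)])
    with pytest.raises(ValueError):
        _t([])


@pytest.mark.parametrize(
    "exons,expected",
    [([(0, 100), (200, 350)], 250), ([(5, 206)], 201)],
)
def test_spliced_length_examples(exons, expected):
    assert spliced_length(_t(exons)) == expected


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(0, 100), (200, 350)], [(100, 200)]),
        ([(5, 206)], []),
        ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
    ],
)
def test_introns_examples(exons, expected):
    assert introns(_t(exons)) == expected


@settings(derandomize=True, max_examples=100)
@given(exon_lists())
def test_exons_and_introns_tile_the_span(exons):
    t = _t(exons)
    span_s, span_e = t.span
    assert spliced_length(t) + sum(e - s for s, e in introns(t)) == span_e - span_s
    pieces = sorted(list(t.exons) + introns(t))
    cursor = span_s
    for s, e in pieces:  # no overlap, no gap
        assert s == cursor
        cursor = e
    assert cursor == span_e


@pytest.mark.parametrize(
    "strand,expected",
    [
        ("+", ((4000, 5000), (6000, 7000))),
        ("-", ((6000, 7000), (4000, 5000))),
    ],
)
def test_flanks_are_strand_aware(strand, expected):
    up, down = flanks(_t([(5000, 6000)], strand=strand), size=1000)
    assert (up, down) == expected


def test_flanks_clip_at_chromosome_bounds():
    up, down = flanks(_t([(300, 900)]), size=1000, chrom_length=1100)
    assert up == (0, 300)
    assert down == (900, 1100)
    up, down = flanks(_t([(0, 900)]), size=1000, chrom_length=5000)
    assert up is None  # clipped to zero length


@settings(derandomize=True, max_examples=60)
@given(exon_lists())
def test_flank_strand_symmetry_and_disjointness(exons):
    plus, minus = _t(exons, "+"), _t(exons, "-")
    up_p, down_p = flanks(plus, size=137)
    up_m, down_m = flanks(minus, size=137)
    assert (up_p, down_p) == (down_m, up_m)
    span = plus.span
    for iv in (up_p, down_p):
        if iv is not None:
            assert iv[1] <= span[0] or iv[0] >= span[1]


def test_exonic_overlap_boundaries():
    ref = [_t([(100, 200)], tid="r")]
    assert exonic_overlap(_t([(199, 300)]), ref, strand_mode="any")
    assert not exonic_overlap(_t([(200, 300)]), ref, strand_mode="any")  # abutment
    minus_ref = [_t([(100, 200)], strand="-", tid="r")]
    assert exonic_overlap(_t([(150, 250)], strand="+"), minus_ref, strand_mode="any")
    assert not exonic_overlap(_t([(150, 250)], strand="+"), minus_ref, strand_mode="same")


def test_exonic_overlap_matches_quadratic_oracle(rng):
    def random_transcripts(n, prefix):
        out = []
        for i in range(n):
            n_ex = int(rng.integers(1, 4))
            cursor = int(rng.integers(0, 5000))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(10, 300))
                exons.append((cursor, cursor + length))
                cursor += length + int(rng.integers(1, 200))
            out.append(_t(exons, tid=f"{prefix}{i}", strand="+-"[int(rng.integers(2))]))
        return out

    queries = random_transcripts(200, "q")
    reference = random_transcripts(50, "r")

    def oracle(t, mode):
        for r in reference:
            if r.chrom != t.chrom or (mode == "same" and r.strand != t.strand):
                continue
            for qs, qe in t.exons:
                for rs, re_ in r.exons:
                    if max(qs, rs) < min(qe, re_):
                        return True
        return False

    for mode in ("any", "same"):
        got = [exonic_overlap(t, reference, strand_mode=mode) for t in queries]
        assert got == [oracle(t, mode) for t in queries]


def test_spliced_length_matches_per_base_oracle(rng):
    for _ in range(100):
        n_ex = int(rng.integers(1, 6))
        cursor = int(rng.integers(0, 100))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(1, 150))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(1, 50))
        t = _t(exons)
        member = sum(
            1 for base in range(cursor + 10) if any(s <= base < e for s, e in t.exons)
        )
        assert spliced_length(t) == member


def test_random_windows_deterministic_and_in_bounds():
    genome = GenomeSequence({"chr1": "A" * 10_000})
    a = random_windows(genome, n=5, width=1000, seed=7)
    b = random_windows(genome, n=5, width=1000, seed=7)
    assert [tuple(r) for r in a] == [tuple(r) for r in b]
    assert len(a) == 5
    for r in a:
        assert 0 <= r.start and r.end <= 10_000 and r.length == 1000
    assert len(random_windows(genome, n=0, width=1000, seed=7)) == 0


def test_random_windows_error_when_genome_too_short():
    genome = GenomeSequence({"chr1": "ACGT" * 10})
    with pytest.raises(ValueError, match="at least"):
        random_windows(genome, n=1, width=1000, seed=0)


def test_random_window_starts_are_uniform():
    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=10_000_000)].tobytes().decode()
    genome = GenomeSequence({"chr1": seq})
    windows = random_windows(genome, n=5000, width=1000, seed=11)
    starts = np.array([r.start for r in windows])
    counts, _ = np.histogram(starts, bins=20, range=(0, 10_000_000 - 1000))
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


def test_regions_for_assembles_all_classes():
    t = _t([(5000, 5400), (5600, 6000)])
    regions = regions_for([t], flank_size=1000, chrom_lengths={"chr1": 100_000})
    by_class = {fc: [(r.start, r.end) for r in regions.by_class(fc)] for fc in
                ("exon", "intron", "upstream", "downstream")}
    assert by_class["exon"] == [(5000, 5400), (5600, 6000)]
    assert by_class["intron"] == [(5400, 5600)]
    assert by_class["upstream"] == [(4000, 5000)]
    assert by_class["downstream"] == [(6000, 7000)]
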