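"""Transcript-structure arithmetic.

Spliced lengths, introns, strand-aware flanking regions, exonic overlap
against a reference annotation, and random genomic windows. Everything is
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "Region",
    "RegionSet",
    "FEATURE_CLASSES",
    "spliced_length",
    "introns",
    "flanks",
    "exonic_overlap",
    "ReferenceExonIndex",
    "random_windows",
    "regions_for",
    "transcript_sequence",
]

FEATURE_CLASSES = ("exon", "intron", "upstream", "downstream", "random")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exon intervals on a chromosome strand.

    Exons must be sorted, pairwise non-overlapping and non-adjacent
    (consecutive exons are separated by >= 1 bp of intron).
    """

    id: str
    locus_id: str
    chrom: str
    strand: str  # '+', '-' or '.' (unstranded, treated as '+' with a warning)
    exons: tuple[tuple[int, int], ...]
    fpkm: float | None = None
    source: str = "assembled"

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"transcript {self.id}: no exons")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        if self.strand == ".":
            logger.warning("transcript %s is unstranded; '+' convention applies", self.id)
        for s, e in exons:
            if not s < e:
                raise ValueError(f"transcript {self.id}: degenerate exon [{s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.id}: exons [{s1},{e1}) and [{s2},{e2}) "
                    "overlap or abut"
                )
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError(f"transcript {self.id}: negative FPKM")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    feature_class: str
    owner_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Labeled genomic intervals grouped by feature class."""

    records: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if not r.start < r.end:
                raise ValueError(f"degenerate region {r}")
            if r.feature_class not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {r.feature_class!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_class(self, feature_class: str) -> "RegionSet":
        return RegionSet([r for r in self.records if r.feature_class == feature_class])

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def extend(self, other: "RegionSet") -> None:
        self.records.extend(other.records)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def spliced_length(t: TranscriptModel) -> int:
    """Transcript length in nt: the sum of exon interval lengths."""
    return sum(e - s for s, e in t.exons)


def introns(t: TranscriptModel) -> list[tuple[int, int]]:
    """Gaps between consecutive exons (empty for single-exon transcripts)."""
    return [(e1, s2) for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])]


def flanks(
    t: TranscriptModel,
    size: int = 1000,
    chrom_length: int | None = None,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Strand-aware (upstream, downstream) flanking intervals of ``size`` bp.

    Upstream precedes the 5' end in transcription direction; for '-' strand
    the two flanks mirror. Intervals are clipped to ``[0, chrom_length)``;
    a flank clipped to zero length is returned as ``None``.
    """
    if size <= 0:
        raise ValueError("flank size must be positive")
    span_s, span_e = t.span
    left = (max(0, span_s - size), span_s)
    right = (span_e, span_e + size)
    if chrom_length is not None:
        right = (right[0], min(right[1], chrom_length))
        if span_e > chrom_length:
            raise ValueError(f"transcript {t.id} extends past chromosome end")
    left_iv = left if left[0] < left[1] else None
    right_iv = right if right[0] < right[1] else None
    if t.strand == "-":
        return right_iv, left_iv
    return left_iv, right_iv


class ReferenceExonIndex:
    """Interval index over the exons of a reference annotation."""

    def __init__(self, reference: Iterable[TranscriptModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in reference:
            key = (t.chrom, t.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e)

    def overlaps(self, chrom: str, start: int, end: int, strand: str | None = None) -> bool:
        keys = (
            [(chrom, strand)]
            if strand is not None
            else [k for k in self._trees if k[0] == chrom]
        )
        return any(k in self._trees and self._trees[k].overlaps(start, end) for k in keys)


def exonic_overlap(
    t: TranscriptModel,
    reference: Iterable[TranscriptModel] | ReferenceExonIndex,
    strand_mode: str = "any",
) -> bool:
    """True iff any exon of ``t`` shares >= 1 bp with a reference exon.

    ``strand_mode='same'`` restricts to reference transcripts on ``t``'s
    strand; ``'any'`` (default, the stricter filter) ignores strand.
    """
    if strand_mode not in ("any", "same"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    index = reference if isinstance(reference, ReferenceExonIndex) else ReferenceExonIndex(reference)
    strand = t.strand if strand_mode == "same" else None
    return any(index.overlaps(t.chrom, s, e, strand) for s, e in t.exons)


# ---------------------------------------------------------------------------
# random windows and region assembly
# ---------------------------------------------------------------------------


def random_windows(
    genome,
    n: int = 5000,
    width: int = 1000,
    seed: int | np.random.Generator = 0,
    exclude_n_runs: bool = False,
) -> RegionSet:
    """Sample ``n`` random genomic windows of exactly ``width`` bp.

    The chromosome is chosen with probability proportional to its length
    (among chromosomes at least ``width`` long) and the start uniformly in
    ``[0, L - width]``; windows are drawn with replacement and may overlap.
    With ``exclude_n_runs`` a window containing N is redrawn (up to 1000
    attempts per window).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = genome.lengths
    chroms = [c for c, L in lengths.items() if L >= width]
    if not chroms:
        raise ValueError(f"no chromosome is at least {width} bp long")
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    records: list[Region] = []
    for i in range(n):
        for _ in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, lengths[chrom] - width + 1))
            if exclude_n_runs and "N" in genome.fetch(chrom, start, start + width):
                continue
            break
        else:
            raise ValueError("could not draw an N-free window after 1000 attempts")
        records.append(Region(chrom, start, start + width, "random", f"random_{i}"))
    return RegionSet(records)


def regions_for(
    transcripts: Iterable[TranscriptModel],
    classes: Sequence[str] = ("exon", "intron", "upstream", "downstream"),
    flank_size: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> RegionSet:
    """Assemble exon/intron/upstream/downstream region records per transcript."""
    records: list[Region] = []
    for t in transcripts:
        clen = chrom_lengths.get(t.chrom) if chrom_lengths else None
        if "exon" in classes:
            records += [Region(t.chrom, s, e, "exon", t.id) for s, e in t.exons]
        if "intron" in classes:
            records += [Region(t.chrom, s, e, "intron", t.id) for s, e in introns(t)]
        if "upstream" in classes or "downstream" in classes:
            up, down = flanks(t, size=flank_size, chrom_length=clen)
            if "upstream" in classes and up is not None:
                records.append(Region(t.chrom, up[0], up[1], "upstream", t.id))
            if "downstream" in classes and down is not None:
                records.append(Region(t.chrom, down[0], down[1], "downstream", t.id))
    return RegionSet(records)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def transcript_sequence(genome, t: TranscriptModel) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    if t.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq
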