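"""Cross-species conservation of lncRNAs from pairwise alignment chains.

A transcript is conserved in a species when at least half of its exonic
nucleotides fall inside aligned chain blocks (coverage >= 0.5, boundary
inclusive). The two per-species calls partition transcripts into four
groups: conserved with human only, with mouse only, with both, or
pig-specific. Transcript-level homology is called separately from blastn
hits against the other species' lncRNA catalogs, and per-base conservation
scores (phastCons-style, values in [0,1]) are summarized per region.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ChainAlignmentSet, ScoreTable
from .transcript_model import RegionSet, TranscriptModel, spliced_length

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationCall",
    "HomologyCall",
    "GROUPS",
    "chain_coverage",
    "classify_conservation",
    "venn_summary",
    "transcript_homology",
    "score_track_summary",
]

GROUPS = ("human_pig_only", "pig_mouse_only", "all_three", "pig_specific")


@dataclass(frozen=True)
class ConservationCall:
    transcript_id: str
    coverage_human: float
    coverage_mouse: float
    group: str

    def __post_init__(self) -> None:
        for cov in (self.coverage_human, self.coverage_mouse):
            if not 0.0 <= cov <= 1.0:
                raise ValueError(f"coverage out of [0,1]: {cov}")
        if self.group not in GROUPS + ("unclassified",):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class HomologyCall:
    transcript_id: str
    aligned_human: bool
    aligned_mouse: bool


# ---------------------------------------------------------------------------
# chain coverage
# ---------------------------------------------------------------------------


def _covered_in(merged: list[tuple[int, int]], start: int, end: int) -> int:
    """Bases of [start,end) inside the merged (disjoint, sorted) intervals."""
    if not merged:
        return 0
    covered = 0
    starts = [s for s, _ in merged]
    i = max(0, bisect.bisect_right(starts, start) - 1)
    for s, e in merged[i:]:
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            covered += hi - lo
    return covered


def chain_coverage(
    t: TranscriptModel, chains: ChainAlignmentSet, unique_only: bool = False
) -> float:
    """Fraction of exonic bases of ``t`` covered by aligned chain blocks.

    Each base counts at most once even when several chains overlap it.
    With ``unique_only`` a base covered by more than one chain is excluded
    (the stricter reading of 'uniquely intersected'). A chromosome absent
    from the chain set yields coverage 0.
    """
    denom = spliced_length(t)
    if t.chrom not in chains.blocks:
        logger.info(
            "chromosome %s absent from %s chains; coverage 0 for %s",
            t.chrom, chains.species_label, t.id,
        )
        return 0.0
    if unique_only:
        covered = _singly_covered(t, chains)
    else:
        merged = chains.merged_intervals(t.chrom)
        covered = sum(_covered_in(merged, s, e) for s, e in t.exons)
    return covered / denom


def _singly_covered(t: TranscriptModel, chains: ChainAlignmentSet) -> int:
    # sweep over block endpoints counting depth-1 overlap with exons
    events: list[tuple[int, int]] = []
    for s, e, _ in chains.blocks[t.chrom]:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    covered = 0
    depth = 0
    prev = None
    for pos, delta in events:
        if prev is not None and depth == 1:
            covered += sum(
                max(0, min(e, pos) - max(s, prev)) for s, e in t.exons
            )
        depth += delta
        prev = pos
    return covered


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_conservation(
    t: TranscriptModel,
    chains_human: ChainAlignmentSet,
    chains_mouse: ChainAlignmentSet,
    threshold: float = 0.5,
    pig_specific_rule: str = "below_threshold_both",
) -> ConservationCall:
    """Four-way conservation call for one transcript.

    Conserved in a species iff chain coverage >= ``threshold`` (boundary
    inclusive). Under ``below_threshold_both`` (default) every transcript
    below threshold in both species is pig-specific, so the four groups
    partition the input; under ``zero_overlap_both`` only transcripts with
    zero coverage in both chains are pig-specific and transcripts with
    0 < coverage < threshold in both are ``unclassified``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if pig_specific_rule not in ("below_threshold_both", "zero_overlap_both"):
        raise ValueError(f"unknown pig_specific_rule {pig_specific_rule!r}")
    cov_h = chain_coverage(t, chains_human)
    cov_m = chain_coverage(t, chains_mouse)
    in_h, in_m = cov_h >= threshold, cov_m >= threshold
    if in_h and in_m:
        group = "all_three"
    elif in_h:
        group = "human_pig_only"
    elif in_m:
        group = "pig_mouse_only"
    elif pig_specific_rule == "below_threshold_both":
        group = "pig_specific"
    elif cov_h == 0.0 and cov_m == 0.0:
        group = "pig_specific"
    else:
        group = "unclassified"
    return ConservationCall(t.id, cov_h, cov_m, group)


def venn_summary(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    """Group counts and percentages (one decimal, of all calls).

    Raises on empty input: percentages of nothing are undefined.
    """
    if not calls:
        raise ValueError("venn_summary of empty call set is undefined")
    total = len(calls)
    rows = []
    for group in GROUPS + ("unclassified",):
        n = sum(1 for c in calls if c.group == group)
        if group == "unclassified" and n == 0:
            continue
        rows.append(
            {"group": group, "count": n, "percent": round(100.0 * n / total, 1)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transcript-level homology
# ---------------------------------------------------------------------------


def transcript_homology(
    scores_or_hits: ScoreTable | Mapping[str, Mapping[str, list[tuple[str, float, int]]]],
    transcript_ids: Sequence[str],
    evalue_cutoff: float = 0.01,
    min_aligned_length: int = 0,
    species: tuple[str, str] = ("human", "mouse"),
) -> tuple[list[HomologyCall], pd.DataFrame]:
    """Per-transcript homology calls from species-labeled blastn hit tables.

    A transcript is aligned to a species iff it has at least one hit at
    E <= ``evalue_cutoff`` (and aligned length >= ``min_aligned_length``)
    against that species' lncRNA set. Returns the calls plus a per-species
    totals table with percentages over all input transcripts.
    """
    hits_by_species = (
        scores_or_hits.blastn_hits
        if isinstance(scores_or_hits, ScoreTable)
        else scores_or_hits
    )

    def aligned(sp: str, tid: str) -> bool:
        return any(
            e <= evalue_cutoff and ln >= min_aligned_length
            for _, e, ln in hits_by_species.get(sp, {}).get(tid, [])
        )

    sp_h, sp_m = species
    calls = [
        HomologyCall(tid, aligned(sp_h, tid), aligned(sp_m, tid))
        for tid in transcript_ids
    ]
    total = len(calls)
    rows = []
    for sp, attr in ((sp_h, "aligned_human"), (sp_m, "aligned_mouse")):
        n = sum(1 for c in calls if getattr(c, attr))
        rows.append(
            {
                "species": sp,
                "aligned": n,
                "total": total,
                "percent": round(100.0 * n / total, 1) if total else float("nan"),
            }
        )
    return calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conservation-score track summaries
# ---------------------------------------------------------------------------


def score_track_summary(
    regions: RegionSet,
    track: Mapping[str, list[tuple[int, int, float]]],
    grid_points: int = 101,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean conservation score per region plus cumulative curves per class.

    The per-region mean averages track values over the region's covered
    bases only; a region with no covered base gets NaN and is excluded
    from its class's cumulative curve. The cumulative table gives, on a
    fixed score grid of ``grid_points`` points spanning [0, 1], the
    fraction of scored regions in each feature class with mean <= score.
    """
    rows = []
    for r in regions:
        ivs = track.get(r.chrom, [])
        total = 0.0
        covered = 0
        for s, e, v in ivs:
            if s >= r.end:
                break
            lo, hi = max(s, r.start), min(e, r.end)
            if lo < hi:
                covered += hi - lo
                total += v * (hi - lo)
        mean = total / covered if covered else float("nan")
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "feature_class": r.feature_class,
                "owner_id": r.owner_id,
                "covered_bases": covered,
                "mean_score": mean,
            }
        )
    per_region = pd.DataFrame(rows)
    grid = np.linspace(0.0, 1.0, grid_points)
    cum: dict[str, np.ndarray] = {"score": grid}
    if not per_region.empty:
        for fc, sub in per_region.groupby("feature_class"):
            vals = sub["mean_score"].dropna().to_numpy()
            if vals.size == 0:
                continue
            cum[fc] = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return per_region, pd.DataFrame(cum)
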