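"""GC content, SNP density and expression statistics per feature class.

The feature classes mirror the characterization layout: per-transcript
exons, introns, 1 kb upstream and 1 kb downstream regions for each
transcript category (lncRNA / protein-coding), plus random genomic windows.
Group differences are assessed with the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, SNPSet
from .transcript_model import RegionSet, TranscriptModel, random_windows, regions_for

logger = logging.getLogger(__name__)

__all__ = [
    "gc_content",
    "gc_content_region",
    "snp_density",
    "per_region_values",
    "mann_whitney_u",
    "format_pvalue",
    "ClassSummary",
    "class_summaries",
    "expression_summary",
    "delta_delta_ct",
]

EXACT_MWU_LIMIT = 14  # exact enumeration when n + m is at most this


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes are excluded from
    both numerator and denominator. All-N (or empty) input yields NaN."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    informative = gc + seq.count("A") + seq.count("T")
    if informative == 0:
        return float("nan")
    return gc / informative


def gc_content_region(genome: GenomeSequence, chrom: str, start: int, end: int) -> float:
    return gc_content(genome.fetch(chrom, start, end))


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------


def snp_density(regions: RegionSet, snps: SNPSet, pooled: bool = True):
    """SNPs per kilobase over a region set.

    Pooled: ``1000 * (sum over regions of the SNP count inside that
    region) / total region length``; a SNP inside two listed regions is
    counted once per region. Non-pooled returns the per-region density
    vector (regions ordered as given). Zero total length yields NaN.
    """
    counts = np.array([snps.count_in(r.chrom, r.start, r.end) for r in regions], dtype=float)
    lengths = np.array([r.length for r in regions], dtype=float)
    if pooled:
        if lengths.sum() == 0:
            return float("nan")
        return 1000.0 * counts.sum() / lengths.sum()
    return 1000.0 * counts / lengths


def per_region_values(
    regions: RegionSet, genome: GenomeSequence | None = None, snps: SNPSet | None = None
) -> pd.DataFrame:
    """Per-region GC fraction and SNP density, for rank tests."""
    rows = []
    for r in regions:
        row: dict[str, object] = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "feature_class": r.feature_class,
            "owner_id": r.owner_id,
            "length": r.length,
        }
        if genome is not None:
            row["gc"] = gc_content_region(genome, r.chrom, r.start, r.end)
        if snps is not None:
            n = snps.count_in(r.chrom, r.start, r.end)
            row["snp_count"] = n
            row["snp_density"] = 1000.0 * n / r.length
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples.

    Returns ``(U, p)`` with U computed for ``x``. Small samples
    (n + m <= 14) use exact enumeration of all C(n+m, n) label assignments
    on the pooled midranks, two-sided by distance from the null mean
    nm/2 (the permutation-null U distribution is symmetric about nm/2,
    ties included). Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    if n + m <= EXACT_MWU_LIMIT:
        return _mwu_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _mwu_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    center = n * m / 2.0
    d_obs = abs(u_obs - center)
    total = 0
    hits = 0
    offset = n * (n + 1) / 2
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - center) >= d_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def format_pvalue(p: float, floor: float = 2.2e-16) -> str:
    """Report convention: p-values below machine-precision floor print as
    an inequality rather than a misleading tiny number."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"


# ---------------------------------------------------------------------------
# class summaries
# ---------------------------------------------------------------------------


@dataclass
class ClassSummary:
    category: str
    feature_class: str
    n_regions: int
    total_length: int
    gc_fraction: float
    snp_density: float  # pooled, SNPs/kb
    mean_gc: float
    median_gc: float
    mean_snp_density: float
    median_snp_density: float

    def as_dict(self) -> dict[str, object]:
        return dict(self.__dict__)


def _summarize(category: str, regions: RegionSet, genome, snps) -> list[ClassSummary]:
    out = []
    for fc in ("exon", "intron", "upstream", "downstream", "random"):
        sub = regions.by_class(fc)
        if len(sub) == 0:
            continue
        df = per_region_values(sub, genome=genome, snps=snps)
        seq_gc_num = 0
        seq_gc_den = 0
        for r in sub:
            seq = genome.fetch(r.chrom, r.start, r.end).upper()
            gc = seq.count("G") + seq.count("C")
            seq_gc_num += gc
            seq_gc_den += gc + seq.count("A") + seq.count("T")
        pooled_gc = seq_gc_num / seq_gc_den if seq_gc_den else float("nan")
        out.append(
            ClassSummary(
                category=category,
                feature_class=fc,
                n_regions=len(sub),
                total_length=sub.total_length,
                gc_fraction=pooled_gc,
                snp_density=snp_density(sub, snps, pooled=True),
                mean_gc=float(df["gc"].mean()),
                median_gc=float(df["gc"].median()),
                mean_snp_density=float(df["snp_density"].mean()),
                median_snp_density=float(df["snp_density"].median()),
            )
        )
    return out


def class_summaries(
    transcripts_by_category: Mapping[str, Sequence[TranscriptModel]],
    genome: GenomeSequence,
    snps: SNPSet,
    flank_size: int = 1000,
    random_n: int = 5000,
    random_width: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GC and SNP-density table per category and feature class.

    One row per (category, feature class) plus a ``random`` category of
    ``random_n`` genomic windows. Categories with zero transcripts are
    dropped with a log message.
    """
    summaries: list[ClassSummary] = []
    for category, transcripts in transcripts_by_category.items():
        if not transcripts:
            logger.info("category %s has no transcripts; row omitted", category)
            continue
        regions = regions_for(
            transcripts, flank_size=flank_size, chrom_lengths=genome.lengths
        )
        summaries.extend(_summarize(category, regions, genome, snps))
    if random_n > 0:
        rnd = random_windows(genome, n=random_n, width=random_width, seed=seed)
        summaries.extend(_summarize("random", rnd, genome, snps))
    return pd.DataFrame([s.as_dict() for s in summaries])


def expression_summary(
    fpkm_by_category: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Mean/median FPKM per transcript category."""
    rows = []
    for category, values in fpkm_by_category.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            continue
        if (arr < 0).any():
            raise ValueError(f"negative FPKM in category {category}")
        rows.append(
            {
                "category": category,
                "n": arr.size,
                "mean_fpkm": float(arr.mean()),
                "median_fpkm": float(np.median(arr)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR arithmetic
# ---------------------------------------------------------------------------


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression fold change, 2^-ddCt.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)
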