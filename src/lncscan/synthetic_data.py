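"""Seeded generator for every input the pipeline consumes.

The generator emits a toy genome, a reference (protein-coding) annotation,
an assembled-transcript GTF containing true lncRNAs plus deliberate noise,
SNPs, two pairwise-alignment chain files, coding-potential score tables, an
FPKM table, a conservation-score track, and bookkeeping ground truth for
all of it.

Planting is exact-count wherever a downstream statistic is asserted
exactly: each feature-class region receives ``round(density * length /
1000)`` SNPs at distinct positions and a sequence with ``round(gc *
length)`` G/C bases; chain blocks cover an exact number of exonic bases per
transcript. Per-transcript feature regions (span plus 1 kb flanks) are laid
out pairwise disjoint so per-class tallies cannot bleed into each other.
Statistics asserted only directionally (lengths, exon counts, FPKM) are
drawn from per-category distributions whose defaults emulate the reported
contrasts between lncRNAs and protein-coding genes.

All randomness flows from a single ``numpy`` Generator keyed by the seed;
two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import ChainAlignmentSet, GenomeSequence, SNPSet
from .transcript_model import (
    Region,
    RegionSet,
    TranscriptModel,
    flanks,
    introns,
    spliced_length,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedBundle",
    "simulate",
    "make_conservation_fixture",
    "make_labeled_sequences",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (np.uint8(b) for b in b"ACGT")


@dataclass
class SimulationConfig:
    """Knobs for the synthetic input bundle.

    Defaults are the desk-scale study conditions: GC and SNP-density
    targets per feature class, mean length / exon count / FPKM contrasts
    between lncRNAs and protein-coding genes (PCGs), the four-way
    conservation split, and the transcript-level homology fractions all
    follow the reported pig-genome analysis; the genome itself is two
    1.25 Mb chromosomes so the full pipeline runs in seconds.
    """

    seed: int = 42
    # genome
    n_chroms: int = 2
    chrom_length: int = 1_250_000
    background_gc: float = 0.4173
    # annotation
    n_pcg: int = 300
    n_lnc: int = 200
    n_noise: int = 100
    lnc_length_mean: float = 1082.7
    lnc_length_sd: float = 300.0
    pcg_length_mean: float = 1982.9
    pcg_length_sd: float = 400.0
    lnc_extra_exons_mean: float = 0.38  # exon count = 2 + Poisson(mean)
    pcg_extra_exons_mean: float = 6.71
    intron_length_range: tuple[int, int] = (60, 120)
    flank_size: int = 1000
    # per-(category, class) GC targets
    gc_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("lnc", "exon"): 0.4815,
            ("lnc", "intron"): 0.4367,
            ("lnc", "upstream"): 0.4738,
            ("lnc", "downstream"): 0.4382,
            ("pcg", "exon"): 0.5159,
            ("pcg", "intron"): 0.4480,
            ("pcg", "upstream"): 0.4700,
            ("pcg", "downstream"): 0.4400,
        }
    )
    # per-(category, class) SNP densities, SNPs/kb; exact-count planting
    snp_densities: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("lnc", "exon"): 28.06,
            ("lnc", "intron"): 29.22,
            ("lnc", "upstream"): 27.96,
            ("lnc", "downstream"): 30.56,
            ("pcg", "exon"): 19.00,
            ("pcg", "intron"): 24.59,
            ("pcg", "upstream"): 23.98,
            ("pcg", "downstream"): 25.42,
        }
    )
    intergenic_snp_density: float = 28.45
    # coding-potential score structure
    lnc_score_mean: float = -2.0
    lnc_score_sd: float = 0.7
    coding_score_mean: float = 2.0
    coding_score_sd: float = 0.7
    lnc_cpat_coding_fraction: float = 0.011  # fraction of lncRNAs CPAT flags
    lnc_pfam_prob: float = 0.01
    lnc_blastx_prob: float = 0.01
    coding_pfam_prob: float = 0.7
    coding_blastx_prob: float = 0.8
    # conservation structure over true lncRNAs
    conservation_fractions: tuple[float, float, float] = (0.381, 0.017, 0.246)
    # (human_pig_only, pig_mouse_only, all_three); remainder pig-specific
    conserved_coverage: float = 0.8
    nonconserved_coverage: float = 0.1
    pcg_coverage: float = 0.9
    # transcript-level homology fractions over true lncRNAs
    homology_fractions: dict[str, float] = field(
        default_factory=lambda: {"human": 0.607, "mouse": 0.402}
    )
    # expression (FPKM lognormal, parameterized by desired mean with sigma)
    lnc_fpkm_mean: float = 1.93
    pcg_fpkm_mean: float = 10.4
    noise_fpkm_mean: float = 1.0
    fpkm_sigma: float = 1.0
    # conservation-score track values per (category, class)
    track_values: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("pcg", "exon"): 0.80,
            ("pcg", "intron"): 0.40,
            ("lnc", "exon"): 0.50,
            ("lnc", "intron"): 0.30,
            ("lnc", "upstream"): 0.35,
            ("lnc", "downstream"): 0.30,
        }
    )

    def validate(self) -> None:
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0,1)")
        for key, gc in self.gc_targets.items():
            if not 0.0 <= gc <= 1.0:
                raise ValueError(f"GC target out of [0,1] for {key}")
        for key, d in self.snp_densities.items():
            if d < 0 or d > 1000:
                raise ValueError(f"infeasible SNP density for {key}: {d}")
        if not 0 <= self.intergenic_snp_density <= 1000:
            raise ValueError("infeasible intergenic SNP density")
        for cov in (self.conserved_coverage, self.nonconserved_coverage, self.pcg_coverage):
            if not 0.0 <= cov <= 1.0:
                raise ValueError("coverage targets must lie in [0,1]")
        if sum(self.conservation_fractions) > 1.0 + 1e-9:
            raise ValueError("conservation fractions exceed 1")
        for frac in self.homology_fractions.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("homology fractions must lie in [0,1]")
        if not 0.0 <= self.lnc_cpat_coding_fraction <= 1.0:
            raise ValueError("lnc_cpat_coding_fraction must lie in [0,1]")


@dataclass
class GroundTruth:
    """Bookkeeping of everything that was planted."""

    transcripts: pd.DataFrame  # one row per emitted transcript
    regions: pd.DataFrame  # one row per planted feature-class region
    expected_survivors: list[str]  # ids the cascade should keep, given planted scores
    group_counts: dict[str, int]  # planted conservation-group sizes

    def planted_snp_density(self, category: str, feature_class: str) -> float:
        sub = self.regions[
            (self.regions.category == category)
            & (self.regions.feature_class == feature_class)
        ]
        return 1000.0 * sub.snp_count.sum() / sub.length.sum()

    def planted_gc(self, category: str, feature_class: str) -> float:
        sub = self.regions[
            (self.regions.category == category)
            & (self.regions.feature_class == feature_class)
        ]
        return sub.gc_bases.sum() / sub.length.sum()


@dataclass
class SimulatedBundle:
    paths: dict[str, Path]
    truth: GroundTruth
    genome: GenomeSequence
    reference: list[TranscriptModel]
    assembled: list[TranscriptModel]
    snps: SNPSet


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _exact_gc_bases(rng: np.random.Generator, length: int, gc_target: float) -> np.ndarray:
    """Sequence with exactly round(gc_target * length) G/C bases, shuffled."""
    n_gc = int(round(gc_target * length))
    arr = np.empty(length, dtype=np.uint8)
    arr[:n_gc] = np.where(rng.random(n_gc) < 0.5, _G, _C)
    arr[n_gc:] = np.where(rng.random(length - n_gc) < 0.5, _A, _T)
    return arr[rng.permutation(length)]


_STOP_RECODE = {b"TAA": b"ATA", b"TAG": b"AGT", b"TGA": b"GAT"}
_RC = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _RC[_x] = _y


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


def _recode_orf(seq: np.ndarray) -> np.ndarray:
    """Force a full-length frame-0 ORF while preserving base composition
    up to the fixed start/stop codons: in-frame stop codons are replaced by
    in-place permutations of their own three letters."""
    seq = seq.copy()
    n_codons = len(seq) // 3
    seq[0:3] = np.frombuffer(b"ATG", dtype=np.uint8)
    for i in range(1, n_codons - 1):
        codon = seq[3 * i : 3 * i + 3].tobytes()
        if codon in _STOP_RECODE:
            seq[3 * i : 3 * i + 3] = np.frombuffer(_STOP_RECODE[codon], dtype=np.uint8)
    seq[3 * (n_codons - 1) : 3 * n_codons] = np.frombuffer(b"TAA", dtype=np.uint8)
    return seq


# ---------------------------------------------------------------------------
# structure generation
# ---------------------------------------------------------------------------


def _draw_structure(
    rng: np.random.Generator, cfg: SimulationConfig, category: str
) -> tuple[int, list[int], list[int]]:
    """(spliced_length, exon_lengths, intron_lengths) for one transcript."""
    if category == "lnc":
        n_exons = 2 + int(rng.poisson(cfg.lnc_extra_exons_mean))
        total = int(np.clip(rng.normal(cfg.lnc_length_mean, cfg.lnc_length_sd), 300, 4000))
    elif category == "pcg":
        n_exons = 2 + int(rng.poisson(cfg.pcg_extra_exons_mean))
        total = int(np.clip(rng.normal(cfg.pcg_length_mean, cfg.pcg_length_sd), 600, 5000))
    else:
        raise ValueError(category)
    base = total // n_exons
    exon_lengths = [base] * n_exons
    exon_lengths[-1] += total - base * n_exons
    lo, hi = cfg.intron_length_range
    intron_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons - 1)]
    return total, exon_lengths, intron_lengths


def _place(
    cursors: list[int],
    chrom_names: list[str],
    chrom_length: int,
    span: int,
    margin: int,
) -> tuple[str, int]:
    """Allocate a disjoint slot (span plus margins both sides) on the first
    chromosome with room; returns (chrom, span_start)."""
    for ci, name in enumerate(chrom_names):
        start = cursors[ci] + margin
        if start + span + margin <= chrom_length:
            cursors[ci] = start + span + margin
            return name, start
    raise ValueError(
        "genome too small for the requested annotation: increase chrom_length "
        "or reduce transcript counts"
    )


def _build_exons(span_start: int, exon_lengths: list[int], intron_lengths: list[int]):
    exons = []
    pos = span_start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return exons


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate(cfg: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Generate the full input bundle under ``outdir`` and return it with
    ground truth. Deterministic: same config and seed give identical bytes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    arrays = {
        c: _random_bases(rng, cfg.chrom_length, cfg.background_gc) for c in chrom_names
    }
    cursors = [100] * cfg.n_chroms
    margin = cfg.flank_size + 50  # keeps span+flanks of neighbours disjoint

    # --- transcript structures -------------------------------------------
    reference: list[TranscriptModel] = []
    assembled: list[TranscriptModel] = []
    categories: dict[str, str] = {}

    def new_transcript(tid, locus, category, source):
        total, exon_lengths, intron_lengths = _draw_structure(rng, cfg, category)
        span = sum(exon_lengths) + sum(intron_lengths)
        chrom, start = _place(cursors, chrom_names, cfg.chrom_length, span, margin)
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel(
            id=tid,
            locus_id=locus,
            chrom=chrom,
            strand=strand,
            exons=tuple(_build_exons(start, exon_lengths, intron_lengths)),
            source=source,
        )
        categories[tid] = category
        return t

    for i in range(cfg.n_pcg):
        reference.append(
            new_transcript(f"ENSSSCT{i:08d}", f"ENSSSCG{i:08d}", "pcg", "reference")
        )
    for i in range(cfg.n_lnc):
        assembled.append(
            new_transcript(f"CUFF.{i + 1}.1", f"CUFF.{i + 1}", "lnc", "assembled")
        )

    # --- noise transcripts ------------------------------------------------
    n_single = cfg.n_noise * 2 // 5
    n_short = cfg.n_noise * 3 // 10
    n_overlap = cfg.n_noise - n_single - n_short
    noise_id = itertools.count(cfg.n_lnc + 1)
    for _ in range(n_single):
        length = int(rng.integers(300, 801))
        chrom, start = _place(cursors, chrom_names, cfg.chrom_length, length, 50)
        i = next(noise_id)
        t = TranscriptModel(
            f"CUFF.{i}.1", f"CUFF.{i}", chrom, "+", ((start, start + length),)
        )
        categories[t.id] = "noise_single"
        assembled.append(t)
    for _ in range(n_short):
        total = int(rng.integers(120, 200))  # spliced length <= 200: fails step 2
        half = total // 2
        gap = int(rng.integers(60, 121))
        chrom, start = _place(cursors, chrom_names, cfg.chrom_length, total + gap, 50)
        i = next(noise_id)
        t = TranscriptModel(
            f"CUFF.{i}.1",
            f"CUFF.{i}",
            chrom,
            "+",
            ((start, start + half), (start + half + gap, start + total + gap)),
        )
        categories[t.id] = "noise_short"
        assembled.append(t)
    for k in range(n_overlap):
        host = reference[int(rng.integers(0, len(reference)))]
        hs, he = host.exons[0]
        i = next(noise_id)
        # two exons, the first sharing sequence with a known exon
        e1 = (hs, he)
        gap = int(rng.integers(60, 121))
        e2 = (he + gap, he + gap + 200)
        t = TranscriptModel(f"CUFF.{i}.1", f"CUFF.{i}", host.chrom, host.strand, (e1, e2))
        categories[t.id] = "noise_overlap"
        assembled.append(t)

    # --- plant sequence per feature-class region --------------------------
    region_rows: list[dict[str, object]] = []
    planted_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def plant_region(t: TranscriptModel, category: str, fclass: str, start: int, end: int):
        if (category, fclass) in cfg.gc_targets and fclass != "exon":
            arrays[t.chrom][start:end] = _exact_gc_bases(
                rng, end - start, cfg.gc_targets[(category, fclass)]
            )

    for t, category in [(x, "pcg") for x in reference] + [
        (x, categories[x.id]) for x in assembled
    ]:
        if category not in ("pcg", "lnc"):
            continue  # noise keeps background sequence and gets no planted regions
        # spliced sequence with the exon GC target; PCGs get a clean ORF
        L = spliced_length(t)
        seq = _exact_gc_bases(rng, L, cfg.gc_targets[(category, "exon")])
        if category == "pcg":
            seq = _recode_orf(seq)
        genome_seq = _revcomp(seq) if t.strand == "-" else seq
        offset = 0
        for s, e in t.exons:
            arrays[t.chrom][s:e] = genome_seq[offset : offset + e - s]
            offset += e - s
        for s, e in introns(t):
            plant_region(t, category, "intron", s, e)
        up, down = flanks(t, size=cfg.flank_size, chrom_length=cfg.chrom_length)
        for fclass, iv in (("upstream", up), ("downstream", down)):
            if iv is not None:
                plant_region(t, category, fclass, iv[0], iv[1])
        # record regions for SNP planting and bookkeeping
        for s, e in t.exons:
            region_rows.append(
                dict(chrom=t.chrom, start=s, end=e, feature_class="exon",
                     owner_id=t.id, category=category)
            )
        for s, e in introns(t):
            region_rows.append(
                dict(chrom=t.chrom, start=s, end=e, feature_class="intron",
                     owner_id=t.id, category=category)
            )
        for fclass, iv in (("upstream", up), ("downstream", down)):
            if iv is not None:
                region_rows.append(
                    dict(chrom=t.chrom, start=iv[0], end=iv[1], feature_class=fclass,
                         owner_id=t.id, category=category)
                )

    # --- SNP planting (exact counts per region; background elsewhere) ----
    snp_positions: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    for row in region_rows:
        length = row["end"] - row["start"]
        density = cfg.snp_densities[(row["category"], row["feature_class"])]
        n_snps = int(round(density * length / 1000.0))
        if n_snps > length:
            raise ValueError(
                f"region of {length} bp cannot hold {n_snps} SNPs "
                f"({row['category']}/{row['feature_class']})"
            )
        pos = rng.choice(length, size=n_snps, replace=False) + row["start"]
        snp_positions[row["chrom"]].append(np.sort(pos))
        row["snp_count"] = n_snps
        row["length"] = length
        planted_intervals[row["chrom"]].append((row["start"], row["end"]))
        seq = arrays[row["chrom"]][row["start"] : row["end"]]
        row["gc_bases"] = int(np.count_nonzero((seq == _G) | (seq == _C)))

    for chrom in chrom_names:
        ivs = sorted(planted_intervals[chrom])
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps, prev = [], 0
        for s, e in merged:
            if s > prev:
                gaps.append((prev, s))
            prev = e
        if cfg.chrom_length > prev:
            gaps.append((prev, cfg.chrom_length))
        for s, e in gaps:
            n_snps = int(round(cfg.intergenic_snp_density * (e - s) / 1000.0))
            if n_snps:
                pos = rng.choice(e - s, size=min(n_snps, e - s), replace=False) + s
                snp_positions[chrom].append(np.sort(pos))

    snps = SNPSet(
        {
            c: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
            for c, parts in snp_positions.items()
        }
    )

    # --- conservation groups and chain files ------------------------------
    n_lnc = cfg.n_lnc
    f_hp, f_pm, f_all = cfg.conservation_fractions
    n_hp, n_pm, n_all = (int(round(f * n_lnc)) for f in (f_hp, f_pm, f_all))
    n_spec = n_lnc - n_hp - n_pm - n_all
    if n_spec < 0:
        raise ValueError("conservation fractions exceed the lncRNA count")
    group_of: dict[str, str] = {}
    order = rng.permutation(n_lnc)
    labels = (
        ["human_pig_only"] * n_hp + ["pig_mouse_only"] * n_pm
        + ["all_three"] * n_all + ["pig_specific"] * n_spec
    )
    lnc_transcripts = [t for t in assembled if categories[t.id] == "lnc"]
    for idx, t in zip(order, lnc_transcripts):
        group_of[t.id] = labels[idx]

    cov_hi, cov_lo = cfg.conserved_coverage, cfg.nonconserved_coverage
    coverage_targets = {
        "human_pig_only": (cov_hi, cov_lo),
        "pig_mouse_only": (cov_lo, cov_hi),
        "all_three": (cov_hi, cov_hi),
        "pig_specific": (0.0, 0.0),
    }

    def covered_exonic_prefix(t: TranscriptModel, fraction: float) -> list[tuple[int, int]]:
        n_cov = int(round(fraction * spliced_length(t)))
        ivs, remaining = [], n_cov
        for s, e in t.exons:
            if remaining <= 0:
                break
            take = min(e - s, remaining)
            ivs.append((s, s + take))
            remaining -= take
        return ivs

    chain_specs: dict[str, list[tuple[str, int, list[tuple[int, int]]]]] = {
        "human": [], "mouse": []
    }
    planted_cov: dict[str, tuple[float, float]] = {}
    for t in lnc_transcripts:
        tgt_h, tgt_m = coverage_targets[group_of[t.id]]
        for species, tgt in (("human", tgt_h), ("mouse", tgt_m)):
            ivs = covered_exonic_prefix(t, tgt)
            if ivs:
                chain_specs[species].append((t.chrom, cfg.chrom_length, ivs))
        sl = spliced_length(t)
        planted_cov[t.id] = (
            round(tgt_h * sl) / sl,
            round(tgt_m * sl) / sl,
        )
    for t in reference:  # PCGs are deeply conserved in both species
        ivs = covered_exonic_prefix(t, cfg.pcg_coverage)
        if ivs:
            chain_specs["human"].append((t.chrom, cfg.chrom_length, ivs))
            chain_specs["mouse"].append((t.chrom, cfg.chrom_length, ivs))

    # --- scores ------------------------------------------------------------
    score_rows = {"cpc": {}, "cnci": {}, "cpat": {}, "pfam": set(), "blastx": {}}
    for t in assembled:
        coding_like = categories[t.id] != "lnc"
        mean = cfg.coding_score_mean if coding_like else cfg.lnc_score_mean
        sd = cfg.coding_score_sd if coding_like else cfg.lnc_score_sd
        score_rows["cpc"][t.id] = rng.normal(mean, sd)
        score_rows["cnci"][t.id] = rng.normal(mean, sd)
        if coding_like:
            score_rows["cpat"][t.id] = rng.uniform(0.6, 1.0)
            if rng.random() < cfg.coding_pfam_prob:
                score_rows["pfam"].add(t.id)
            if rng.random() < cfg.coding_blastx_prob:
                score_rows["blastx"][t.id] = 10.0 ** rng.uniform(-30, -10)
        else:
            if rng.random() < cfg.lnc_cpat_coding_fraction:
                score_rows["cpat"][t.id] = rng.uniform(0.5, 1.0)
            else:
                score_rows["cpat"][t.id] = rng.uniform(0.0, 0.45)
            if rng.random() < cfg.lnc_pfam_prob:
                score_rows["pfam"].add(t.id)
            if rng.random() < cfg.lnc_blastx_prob:
                score_rows["blastx"][t.id] = 10.0 ** rng.uniform(-10, -6)

    # --- homology hits ------------------------------------------------------
    homology: dict[str, set[str]] = {}
    for species, frac in cfg.homology_fractions.items():
        n_aligned = int(round(frac * n_lnc))
        chosen = rng.permutation(n_lnc)[:n_aligned]
        homology[species] = {lnc_transcripts[i].id for i in chosen}

    # --- FPKM ---------------------------------------------------------------
    def lognormal_mean(mean: float, n: int) -> np.ndarray:
        mu = np.log(mean) - cfg.fpkm_sigma**2 / 2
        return rng.lognormal(mu, cfg.fpkm_sigma, size=n)

    fpkm: dict[str, float] = {}
    for group, mean in (
        (reference, cfg.pcg_fpkm_mean),
        (lnc_transcripts, cfg.lnc_fpkm_mean),
        ([t for t in assembled if categories[t.id] != "lnc"], cfg.noise_fpkm_mean),
    ):
        vals = lognormal_mean(mean, len(group))
        for t, v in zip(group, vals):
            fpkm[t.id] = float(v)

    # --- write files --------------------------------------------------------
    genome = GenomeSequence({c: arrays[c].tobytes().decode("ascii") for c in chrom_names})
    paths = {
        "genome": outdir / "genome.fa",
        "reference_gtf": outdir / "reference.gtf",
        "assembled_gtf": outdir / "assembled.gtf",
        "snps_vcf": outdir / "snps.vcf",
        "chain_human": outdir / "susToHuman.chain",
        "chain_mouse": outdir / "susToMouse.chain",
        "cpc": outdir / "cpc.txt",
        "cnci": outdir / "cnci.txt",
        "cpat": outdir / "cpat.txt",
        "pfam": outdir / "pfam.txt",
        "blastx": outdir / "blastx.tsv",
        "blastn_human": outdir / "blastn_human.tsv",
        "blastn_mouse": outdir / "blastn_mouse.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "track": outdir / "conservation.bedgraph",
        "ground_truth": outdir / "ground_truth.tsv",
        "ground_truth_regions": outdir / "ground_truth_regions.tsv",
    }
    iof.write_fasta(genome, paths["genome"])
    iof.write_gtf(reference, paths["reference_gtf"], source="ensembl")
    iof.write_gtf(assembled, paths["assembled_gtf"], source="Cufflinks")
    iof.write_vcf(snps, paths["snps_vcf"])
    iof.write_chain(chain_specs["human"], "hg_chrQ", paths["chain_human"])
    iof.write_chain(chain_specs["mouse"], "mm_chrQ", paths["chain_mouse"])

    with open(paths["cpc"], "w") as fh:
        for t in assembled:
            label = "coding" if score_rows["cpc"][t.id] >= 0 else "noncoding"
            fh.write(f"{t.id}\t{spliced_length(t)}\t{label}\t{score_rows['cpc'][t.id]:.6f}\n")
    with open(paths["cnci"], "w") as fh:
        fh.write("Transcript ID\tindex\tscore\n")
        for t in assembled:
            label = "coding" if score_rows["cnci"][t.id] >= 0 else "noncoding"
            fh.write(f"{t.id}\t{label}\t{score_rows['cnci'][t.id]:.6f}\n")
    with open(paths["cpat"], "w") as fh:
        fh.write("ID\tmRNA_size\tORF_size\tFickett_score\tHexamer_score\tcoding_prob\n")
        for t in assembled:
            fh.write(
                f"{t.id}\t{spliced_length(t)}\t0\t0.0\t0.0\t{score_rows['cpat'][t.id]:.6f}\n"
            )
    with open(paths["pfam"], "w") as fh:
        fh.write("# transcript_id\tdomain\tE-value\n")
        for t in assembled:
            if t.id in score_rows["pfam"]:
                fh.write(f"{t.id}\tPF00001.21\t1e-10\n")

    def blast6_row(qid, sid, evalue, length=100):
        return (
            f"{qid}\t{sid}\t98.0\t{length}\t2\t0\t1\t{length}\t1\t{length}"
            f"\t{evalue:.3g}\t180\n"
        )

    with open(paths["blastx"], "w") as fh:
        for t in assembled:
            if t.id in score_rows["blastx"]:
                fh.write(blast6_row(t.id, "UniRef90_P12345", score_rows["blastx"][t.id]))
    for species in ("human", "mouse"):
        with open(paths[f"blastn_{species}"], "w") as fh:
            for t in lnc_transcripts:
                if t.id in homology[species]:
                    fh.write(blast6_row(t.id, f"NONCODE_{species}_{t.id}", 1e-5))
    with open(paths["fpkm"], "w") as fh:
        fh.write("transcript_id\tfpkm\n")
        for t in reference + assembled:
            fh.write(f"{t.id}\t{fpkm[t.id]:.6f}\n")

    track_rows = sorted(
        (r["chrom"], r["start"], r["end"], cfg.track_values[(r["category"], r["feature_class"])])
        for r in region_rows
        if (r["category"], r["feature_class"]) in cfg.track_values
    )
    with open(paths["track"], "w") as fh:
        for chrom, s, e, v in track_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.3f}\n")

    # --- ground truth -------------------------------------------------------
    def expected_survivor(t: TranscriptModel) -> bool:
        if categories[t.id] != "lnc":
            # noise fails structure/overlap steps or carries coding scores
            return (
                t.exon_count >= 2
                and spliced_length(t) > 200
                and categories[t.id] != "noise_overlap"
                and score_rows["cpc"][t.id] < 0
                and score_rows["cnci"][t.id] < 0
                and t.id not in score_rows["pfam"]
                and score_rows["blastx"].get(t.id, 1.0) > 1e-5
            )
        return (
            score_rows["cpc"][t.id] < 0
            and score_rows["cnci"][t.id] < 0
            and t.id not in score_rows["pfam"]
            and score_rows["blastx"].get(t.id, 1.0) > 1e-5
        )

    t_rows = []
    for t in reference + assembled:
        cat = categories[t.id]
        row = dict(
            transcript_id=t.id,
            category=cat,
            chrom=t.chrom,
            strand=t.strand,
            exon_count=t.exon_count,
            spliced_length=spliced_length(t),
            fpkm=fpkm[t.id],
            cpc_score=score_rows["cpc"].get(t.id, np.nan),
            cnci_score=score_rows["cnci"].get(t.id, np.nan),
            cpat_coding_prob=score_rows["cpat"].get(t.id, np.nan),
            pfam_hit=t.id in score_rows["pfam"],
            blastx_evalue=score_rows["blastx"].get(t.id, np.nan),
            conservation_group=group_of.get(t.id, ""),
            coverage_human=planted_cov.get(t.id, (np.nan, np.nan))[0],
            coverage_mouse=planted_cov.get(t.id, (np.nan, np.nan))[1],
            homolog_human=t.id in homology.get("human", set()),
            homolog_mouse=t.id in homology.get("mouse", set()),
            expected_survivor=t.source == "assembled" and expected_survivor(t),
        )
        t_rows.append(row)
    truth_transcripts = pd.DataFrame(t_rows)
    truth_regions = pd.DataFrame(region_rows)
    truth = GroundTruth(
        transcripts=truth_transcripts,
        regions=truth_regions,
        expected_survivors=[
            r["transcript_id"] for r in t_rows if r["expected_survivor"]
        ],
        group_counts={
            "human_pig_only": n_hp,
            "pig_mouse_only": n_pm,
            "all_three": n_all,
            "pig_specific": n_spec,
        },
    )
    truth_transcripts.to_csv(paths["ground_truth"], sep="\t", index=False)
    truth_regions.to_csv(paths["ground_truth_regions"], sep="\t", index=False)

    return SimulatedBundle(
        paths=paths,
        truth=truth,
        genome=genome,
        reference=reference,
        assembled=assembled,
        snps=snps,
    )


# ---------------------------------------------------------------------------
# focused fixtures
# ---------------------------------------------------------------------------


def make_conservation_fixture(
    group_sizes: tuple[int, int, int, int], seed: int = 0
) -> tuple[list[TranscriptModel], ChainAlignmentSet, ChainAlignmentSet]:
    """Transcripts plus human/mouse chain sets engineered so that
    classification at threshold 0.5 reproduces ``group_sizes`` exactly
    (human+pig, pig+mouse, all three, pig-specific).

    Conserved coverage is planted at 0.8, non-conserved at 0.1 and
    pig-specific at 0.0, on single-exon transcripts of 1000 nt.
    """
    n_hp, n_pm, n_all, n_spec = group_sizes
    if min(group_sizes) < 0:
        raise ValueError("group sizes must be non-negative")
    targets = (
        [(0.8, 0.1)] * n_hp + [(0.1, 0.8)] * n_pm + [(0.8, 0.8)] * n_all
        + [(0.0, 0.0)] * n_spec
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    transcripts = []
    blocks: dict[str, dict[str, list[tuple[int, int, int]]]] = {
        "human": {"chrF": []}, "mouse": {"chrF": []}
    }
    for i, idx in enumerate(order):
        cov_h, cov_m = targets[idx]
        start = 100 + i * 1500
        t = TranscriptModel(
            id=f"fix_{i}", locus_id=f"fix_{i}", chrom="chrF", strand="+",
            exons=((start, start + 1000),),
        )
        transcripts.append(t)
        for species, cov in (("human", cov_h), ("mouse", cov_m)):
            n_cov = int(round(cov * 1000))
            if n_cov:
                blocks[species]["chrF"].append((start, start + n_cov, i + 1))
    chains_h = ChainAlignmentSet("human", blocks["human"])
    chains_m = ChainAlignmentSet("mouse", blocks["mouse"])
    return transcripts, chains_h, chains_m


_PREFERRED_CODONS = [
    "GCC", "CGC", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC", "ATC",
    "CTG", "AAG", "TTC", "CCC", "AGC", "ACC", "TAC", "GTG", "TGG", "ATG",
]
_ALL_SENSE = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


def make_labeled_sequences(
    n_coding: int = 200, n_noncoding: int = 200, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Labeled training/test sequences for the built-in coding scorer.

    Coding sequences are a clean ~900 nt ORF (ATG .. TAA) of codons drawn
    with a strong preferred-codon bias; noncoding sequences are 500 nt of
    i.i.d. bases at GC 0.45 (short enough that a spurious >=300 nt ORF is
    rare).
    """
    rng = np.random.default_rng(seed)
    weights = np.array([8.0 if c in _PREFERRED_CODONS else 1.0 for c in _ALL_SENSE])
    weights /= weights.sum()
    coding = []
    for _ in range(n_coding):
        body = "".join(
            _ALL_SENSE[i] for i in rng.choice(len(_ALL_SENSE), size=298, p=weights)
        )
        coding.append("ATG" + body + "TAA")
    noncoding = [
        _random_bases(rng, 500, 0.45).tobytes().decode("ascii")
        for _ in range(n_noncoding)
    ]
    return coding, noncoding
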