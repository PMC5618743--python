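"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally. GTF (1-based closed) and
VCF (1-based positions) are converted on read and reconverted on write; BED,
bedGraph and UCSC chain reference coordinates are already 0-based half-open
and pass through unchanged. Soft-masked (lowercase) bases are uppercased on
read; ``N`` is retained.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .transcript_model import RegionSet, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "SNPSet",
    "ChainAlignmentSet",
    "ScoreTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_chain",
    "write_chain",
    "read_snps",
    "write_vcf",
    "read_fpkm",
    "read_score_track",
    "read_score_tables",
    "write_bed",
    "write_tsv_report",
]


class FormatError(ValueError):
    """A file violated the format contract of its reader."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A genome as uppercase nucleotide strings keyed by chromosome name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` on ``chrom``; out-of-bounds raises."""
        seq = self.sequences.get(chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"region {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class SNPSet:
    """Per-chromosome sorted arrays of 0-based SNP positions."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, pos in self.positions.items():
            arr = np.unique(np.asarray(pos, dtype=np.int64))
            clean[chrom] = arr
        self.positions = clean

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of SNPs with start <= pos < end."""
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        lo, hi = np.searchsorted(arr, [start, end], side="left")
        return int(hi - lo)

    @property
    def total(self) -> int:
        return int(sum(len(a) for a in self.positions.values()))


@dataclass
class ChainAlignmentSet:
    """Reference-side aligned-block intervals from one pairwise chain file.

    ``blocks[chrom]`` is a list of ``(start, end, chain_id)`` half-open
    intervals sorted by start. Query-side coordinates are not retained: only
    reference-side coverage is needed for the conservation rule.
    """

    species_label: str
    blocks: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, blks in self.blocks.items():
            for s, e, _ in blks:
                if not s < e:
                    raise ValueError(f"degenerate chain block [{s},{e}) on {chrom}")
            self.blocks[chrom] = sorted(blks)

    def merged_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Union of all block intervals on ``chrom`` (each base once)."""
        merged: list[tuple[int, int]] = []
        for s, e, _ in self.blocks.get(chrom, []):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @property
    def total_block_length(self) -> int:
        return sum(e - s for blks in self.blocks.values() for s, e, _ in blks)


_SCORE_FIELDS = ("cpc_score", "cnci_score", "cpat_coding_prob", "pfam_hit", "blastx_min_evalue")


@dataclass
class ScoreTable:
    """Per-transcript coding-potential evidence merged from tool outputs.

    Missing evidence is ``None``. ``blastn_hits`` maps a subject-species
    label to per-transcript hit lists ``(subject_id, evalue, aligned_length)``
    and feeds transcript-level homology calls.
    """

    cpc_score: dict[str, float] = field(default_factory=dict)
    cnci_score: dict[str, float] = field(default_factory=dict)
    cpat_coding_prob: dict[str, float] = field(default_factory=dict)
    pfam_hit: dict[str, bool] = field(default_factory=dict)
    blastx_min_evalue: dict[str, float] = field(default_factory=dict)
    blastn_hits: dict[str, dict[str, list[tuple[str, float, int]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, p in self.cpat_coding_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cpat_coding_prob out of [0,1] for {tid}: {p}")
        for tid, e in self.blastx_min_evalue.items():
            if e < 0:
                raise ValueError(f"negative E-value for {tid}: {e}")

    def get(self, field_name: str, transcript_id: str):
        if field_name not in _SCORE_FIELDS:
            raise KeyError(field_name)
        return getattr(self, field_name).get(transcript_id)

    def update(self, other: "ScoreTable") -> None:
        for f in _SCORE_FIELDS:
            getattr(self, f).update(getattr(other, f))
        for species, hits in other.blastn_hits.items():
            self.blastn_hits.setdefault(species, {}).update(hits)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(
    path: str | Path,
    dialect: str = "ensembl",
    source: str = "reference",
) -> list[TranscriptModel]:
    """Read exon records from a GTF file into transcript models.

    Both the Ensembl and Cufflinks attribute dialects use quoted
    ``transcript_id``/``gene_id`` pairs; the locus key is ``gene_id``.
    GTF 1-based closed intervals are converted to 0-based half-open.
    """
    if dialect not in ("ensembl", "cufflinks"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, locus)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: exon start > end")
            attr = _parse_gtf_attributes(attrs)
            tid = attr.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            locus = attr.get("gene_id", tid)
            exons.setdefault(tid, []).append((start1 - 1, end1))
            prev = meta.setdefault(tid, (chrom, strand, locus))
            if prev[0] != chrom:
                raise FormatError(f"{path}:{lineno}: transcript {tid} spans chromosomes")
    out = []
    for tid, ivs in exons.items():
        chrom, strand, locus = meta[tid]
        out.append(
            TranscriptModel(
                id=tid,
                locus_id=locus,
                chrom=chrom,
                strand=strand,
                exons=sorted(ivs),
                source=source,
            )
        )
    return out


def write_gtf(
    transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "lncscan"
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'gene_id "{t.locus_id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------


def read_chain(path: str | Path, species_label: str | None = None) -> ChainAlignmentSet:
    """Parse a UCSC chain file into reference-side block intervals.

    A chain header is ``chain score tName tSize tStrand tStart tEnd qName
    qSize qStrand qStart qEnd id`` followed by block lines ``size dt dq``
    (the last line carries ``size`` only). Each ungapped block contributes
    the reference interval ``[cursor, cursor+size)``; the cursor then
    advances by ``size + dt``.
    """
    label = species_label or Path(path).stem
    blocks: dict[str, list[tuple[int, int, int]]] = {}
    chrom = None
    cursor = t_end = 0
    chain_id = 0
    n_anonymous = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) < 12:
                    raise FormatError(f"{path}:{lineno}: truncated chain header")
                chrom = parts[2]
                t_start, t_end = int(parts[5]), int(parts[6])
                if parts[4] != "+":
                    raise FormatError(f"{path}:{lineno}: reference strand must be +")
                cursor = t_start
                if len(parts) >= 13:
                    chain_id = int(parts[12])
                else:
                    n_anonymous += 1
                    chain_id = -n_anonymous
                continue
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: block line before any chain header")
            parts = line.split()
            size = int(parts[0])
            dt = int(parts[1]) if len(parts) > 1 else 0
            dq = int(parts[2]) if len(parts) > 2 else 0
            if size < 0 or dt < 0 or dq < 0:
                raise FormatError(f"{path}:{lineno}: negative size/dt/dq")
            if size > 0:
                blocks.setdefault(chrom, []).append((cursor, cursor + size, chain_id))
            cursor += size + dt
            if cursor > t_end:
                raise FormatError(
                    f"{path}:{lineno}: chain blocks run past tEnd ({cursor} > {t_end})"
                )
    return ChainAlignmentSet(species_label=label, blocks=blocks)


def write_chain(
    chains: Sequence[tuple[str, int, list[tuple[int, int]]]],
    query_label: str,
    path: str | Path,
) -> None:
    """Write chains as ``(tName, tSize, [reference block intervals])`` tuples.

    The query side is synthetic bookkeeping (gap sizes mirrored) since only
    reference-side coverage is consumed downstream.
    """
    with open(path, "w") as fh:
        for cid, (chrom, tsize, ivs) in enumerate(chains, start=1):
            if not ivs:
                continue
            ivs = sorted(ivs)
            t_start, t_end = ivs[0][0], ivs[-1][1]
            span = t_end - t_start
            fh.write(
                f"chain 1000 {chrom} {tsize} + {t_start} {t_end} "
                f"{query_label} {span} + 0 {span} {cid}\n"
            )
            for i, (s, e) in enumerate(ivs):
                if i + 1 < len(ivs):
                    dt = ivs[i + 1][0] - e
                    fh.write(f"{e - s} {dt} {dt}\n")
                else:
                    fh.write(f"{e - s}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# SNPs (VCF v4 positions, or BED3)
# ---------------------------------------------------------------------------


def read_snps(path: str | Path) -> SNPSet:
    """Read SNP positions from a VCF (POS is 1-based) or 3+-column BED.

    The format is sniffed: a ``##fileformat=VCF`` header or a ``#CHROM``
    line marks VCF; otherwise the file is treated as BED with the SNP at
    the (0-based) start of each record.
    """
    path = Path(path)
    is_vcf = path.suffix == ".vcf"
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "VCF" in line or line.startswith("#CHROM"):
                    is_vcf = True
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            chrom = fields[0]
            try:
                raw = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            pos = raw - 1 if is_vcf else raw
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: negative position")
            positions.setdefault(chrom, []).append(pos)
    return SNPSet({c: np.asarray(p, dtype=np.int64) for c, p in positions.items()})


def write_vcf(snps: SNPSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in sorted(snps.positions):
            for pos in snps.positions[chrom]:
                fh.write(f"{chrom}\t{pos + 1}\t.\tN\tN\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# expression table, score track
# ---------------------------------------------------------------------------


def read_fpkm(path: str | Path) -> dict[str, float]:
    """Two-column TSV ``transcript_id<TAB>FPKM`` (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            tid, _, val = line.partition("\t")
            try:
                fpkm = float(val)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise FormatError(f"{path}:{lineno}: non-numeric FPKM")
            if fpkm < 0:
                raise FormatError(f"{path}:{lineno}: negative FPKM")
            out[tid] = fpkm
    return out


def read_score_track(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """bedGraph -> per-chromosome sorted ``(start, end, value)`` intervals."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if not s < e:
                raise FormatError(f"{path}:{lineno}: degenerate interval")
            track.setdefault(chrom, []).append((s, e, v))
    for chrom in track:
        track[chrom].sort()
    return track


# ---------------------------------------------------------------------------
# coding-potential score tables
# ---------------------------------------------------------------------------

_KNOWN_KINDS = {"cpc", "cnci", "cpat", "pfam", "blastx", "blastn"}


def _read_two_col_scores(path: str | Path, skip_header_tokens: tuple[str, ...]) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip() in skip_header_tokens:
                continue
            try:
                score = float(fields[-1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            tid = fields[0]
            if tid in out:
                # conflicting duplicate: keep the extreme (max score)
                logger.warning("duplicate score rows for %s in %s; keeping max", tid, path)
                score = max(score, out[tid])
            out[tid] = score
    return out


def _read_cpat(path: str | Path) -> dict[str, float]:
    """CPAT tabular output; coding probability is the last column."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                prob = float(fields[-1])
            except ValueError:
                if lineno == 1:
                    continue  # CPAT header row
                raise FormatError(f"{path}:{lineno}: non-numeric coding probability")
            out[fields[0]] = prob
    return out


def _read_pfam(path: str | Path) -> dict[str, bool]:
    """Pfam domain-hit table: transcript id in the first whitespace column."""
    out: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out[line.split()[0]] = True
    return out


def _read_blast6(path: str | Path) -> dict[str, list[tuple[str, float, int]]]:
    """BLAST tabular outfmt 6 -> per-query hit lists (subject, E, aln length)."""
    hits: dict[str, list[tuple[str, float, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 outfmt-6 columns")
            evalue = float(fields[10])
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            hits.setdefault(fields[0], []).append((fields[1], evalue, int(fields[3])))
    return hits


def read_score_tables(paths: Mapping[str, str | Path]) -> ScoreTable:
    """Merge per-tool tabular outputs into one ScoreTable.

    Keys are ``cpc``, ``cnci``, ``cpat``, ``pfam``, ``blastx`` and
    ``blastn`` or ``blastn_<species>`` (e.g. ``blastn_human``). A transcript
    absent from a file gets a missing value for that field.
    """
    table = ScoreTable()
    for kind, path in paths.items():
        base, _, species = kind.partition("_")
        if base not in _KNOWN_KINDS:
            raise ValueError(f"unknown score-table kind {kind!r}")
        if base == "cpc":
            table.cpc_score.update(_read_two_col_scores(path, ("ID", "seq_id")))
        elif base == "cnci":
            table.cnci_score.update(_read_two_col_scores(path, ("Transcript ID",)))
        elif base == "cpat":
            table.cpat_coding_prob.update(_read_cpat(path))
        elif base == "pfam":
            table.pfam_hit.update(_read_pfam(path))
        elif base == "blastx":
            for tid, hitlist in _read_blast6(path).items():
                best = min(h[1] for h in hitlist)
                if tid in table.blastx_min_evalue:
                    logger.warning("duplicate blastx rows for %s; keeping min E", tid)
                    best = min(best, table.blastx_min_evalue[tid])
                table.blastx_min_evalue[tid] = best
        elif base == "blastn":
            label = species or "default"
            dest = table.blastn_hits.setdefault(label, {})
            for tid, hitlist in _read_blast6(path).items():
                dest.setdefault(tid, []).extend(hitlist)
    # re-validate invariants after merge
    ScoreTable.__post_init__(table)
    return table


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """BED6 with the name column encoding ``owner_id|feature_class``."""
    with open(path, "w") as fh:
        for r in regions.records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.owner_id}|{r.feature_class}\t0\t.\n")


def write_tsv_report(rows: Iterable[Mapping[str, object]], path: str | Path, header: Sequence[str] | None = None) -> None:
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    cols = list(header) if header else list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in cols) + "\n")


def _fmt(v: object) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
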