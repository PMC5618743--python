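"""End-to-end orchestration: identification, characterization, conservation.

``run_all`` composes the three analysis stages on one input bundle and
writes the report files; each stage is also callable on its own and the
CLI subcommands are thin wrappers over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conservation as cons
from . import feature_stats as fstats
from . import io_formats as iof
from . import lncrna_filter as lf
from .transcript_model import TranscriptModel, regions_for

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    assembled_gtf: str
    reference_gtf: str
    genome_fasta: str
    snps: str
    score_tables: dict[str, str] = field(default_factory=dict)
    fpkm: str | None = None
    chain_human: str | None = None
    chain_mouse: str | None = None
    score_track: str | None = None
    outdir: str = "lncscan_out"
    seed: int = 0
    flank_size: int = 1000
    random_n: int = 5000
    conservation_threshold: float = 0.5
    pig_specific_rule: str = "below_threshold_both"
    homology_evalue_cutoff: float = 0.01
    filter: lf.FilterConfig = field(default_factory=lf.FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fcfg = lf.FilterConfig(**raw.pop("filter", {}))
        return cls(filter=fcfg, **raw)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise StageError(name, FileNotFoundError(f"config field {name} not set"))
            if isinstance(value, str) and not Path(value).exists():
                raise StageError(name, FileNotFoundError(value))


def run_all(cfg: PipelineConfig) -> dict[str, object]:
    """Run identification, characterization and conservation; write the
    report bundle under ``cfg.outdir`` and return the in-memory results."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    # ----- load ------------------------------------------------------------
    cfg.require("assembled_gtf", "reference_gtf", "genome_fasta", "snps")
    try:
        assembled = iof.read_gtf(cfg.assembled_gtf, dialect="cufflinks", source="assembled")
        reference = iof.read_gtf(cfg.reference_gtf, dialect="ensembl", source="reference")
        genome = iof.read_fasta(cfg.genome_fasta)
        snps = iof.read_snps(cfg.snps)
        scores = iof.read_score_tables(cfg.score_tables)
        fpkm = iof.read_fpkm(cfg.fpkm) if cfg.fpkm else {}
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise StageError("load", exc) from exc

    # ----- identification --------------------------------------------------
    try:
        survivors, report = lf.apply_cascade(assembled, reference, scores, cfg.filter)
        cpat_fraction, flagged = lf.cpat_validation(survivors, scores, cfg.filter)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("filter", exc) from exc
    iof.write_gtf(survivors, out / "survivors.gtf")
    iof.write_tsv_report(report.to_rows(), out / "filter_report.tsv")
    iof.write_tsv_report(
        [{"transcript_id": tid, "reason": reason} for tid, reason in report.removed.items()],
        out / "removals.tsv",
        header=["transcript_id", "reason"],
    )
    results.update(
        survivors=survivors, filter_report=report,
        cpat_noncoding_fraction=cpat_fraction, cpat_flagged=flagged,
    )

    # ----- characterization -------------------------------------------------
    try:
        by_cat = {"lncRNA": survivors, "PCG": reference}
        summaries = fstats.class_summaries(
            by_cat, genome, snps,
            flank_size=cfg.flank_size, random_n=cfg.random_n, seed=cfg.seed,
        )
        expr = fstats.expression_summary(
            {
                cat: [fpkm[t.id] for t in ts if t.id in fpkm]
                for cat, ts in by_cat.items()
            }
        )
    except Exception as exc:
        raise StageError("characterize", exc) from exc
    summaries.to_csv(out / "class_summaries.tsv", sep="\t", index=False)
    expr.to_csv(out / "expression_summary.tsv", sep="\t", index=False)
    regions = regions_for(survivors, flank_size=cfg.flank_size, chrom_lengths=genome.lengths)
    iof.write_bed(regions, out / "lncrna_regions.bed")
    results.update(class_summaries=summaries, expression_summary=expr)

    # ----- conservation -----------------------------------------------------
    if cfg.chain_human and cfg.chain_mouse:
        cfg.require("chain_human", "chain_mouse")
        try:
            chains_h = iof.read_chain(cfg.chain_human, species_label="human")
            chains_m = iof.read_chain(cfg.chain_mouse, species_label="mouse")
            calls = [
                cons.classify_conservation(
                    t, chains_h, chains_m,
                    threshold=cfg.conservation_threshold,
                    pig_specific_rule=cfg.pig_specific_rule,
                )
                for t in survivors
            ]
            venn = cons.venn_summary(calls) if calls else None
        except StageError:
            raise
        except Exception as exc:
            raise StageError("conserve", exc) from exc
        iof.write_tsv_report(
            [
                {
                    "transcript_id": c.transcript_id,
                    "coverage_human": c.coverage_human,
                    "coverage_mouse": c.coverage_mouse,
                    "group": c.group,
                }
                for c in calls
            ],
            out / "conservation_calls.tsv",
        )
        if venn is not None:
            venn.to_csv(out / "venn_summary.tsv", sep="\t", index=False)
        results.update(conservation_calls=calls, venn_summary=venn)

        if any(k.startswith("blastn") for k in cfg.score_tables):
            hcalls, htable = cons.transcript_homology(
                scores, [t.id for t in survivors], evalue_cutoff=cfg.homology_evalue_cutoff
            )
            htable.to_csv(out / "homology_summary.tsv", sep="\t", index=False)
            results.update(homology_calls=hcalls, homology_summary=htable)

        if cfg.score_track:
            track = iof.read_score_track(cfg.score_track)
            per_region, cumulative = cons.score_track_summary(regions, track)
            cumulative.to_csv(out / "conservation_cumulative.tsv", sep="\t", index=False)
            results.update(score_track_per_region=per_region, score_track_cumulative=cumulative)
    elif cfg.chain_human or cfg.chain_mouse:
        raise StageError(
            "conserve",
            ValueError("both chain_human and chain_mouse are required for conservation"),
        )

    _write_summary(out / "summary.txt", cfg, assembled, results)
    results["outdir"] = out
    return results


def _write_summary(path: Path, cfg: PipelineConfig, assembled, results) -> None:
    report: lf.FilterReport = results["filter_report"]
    lines = [
        f"# lncscan summary (seed={cfg.seed})",
        f"assembled transcripts: {len(assembled)}",
        f"putative lncRNAs: {len(report.survivor_ids)} at {report.n_loci} loci",
    ]
    frac = results.get("cpat_noncoding_fraction")
    if frac is not None:
        lines.append(f"CPAT validation: {100 * frac:.1f}% of survivors noncoding")
    venn = results.get("venn_summary")
    if venn is not None:
        for _, row in venn.iterrows():
            lines.append(f"conservation {row['group']}: {row['count']} ({row['percent']}%)")
    homology = results.get("homology_summary")
    if homology is not None:
        for _, row in homology.iterrows():
            lines.append(
                f"homology {row['species']}: {row['aligned']}/{row['total']}"
                f" ({row['percent']}%)"
            )
    summ = results.get("class_summaries")
    if summ is not None and not summ.empty:
        for _, row in summ.iterrows():
            lines.append(
                f"{row['category']} {row['feature_class']}: GC "
                f"{100 * row['gc_fraction']:.2f}%, {row['snp_density']:.2f} SNPs/kb"
            )
    path.write_text("\n".join(lines) + "\n")
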