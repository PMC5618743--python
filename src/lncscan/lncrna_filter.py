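"""The seven-step lncRNA identification cascade.

Assembled transcripts are screened in order: (1) multiexonic, (2) length
> 200 nt, (3) no exonic overlap with known genes, (4) CPC score < 0,
(5) CNCI score < 0, (6) no Pfam protein-domain hit, (7) no blastx hit
against a protein database at E <= 1e-5. Survivors are putative lncRNAs.
A post-hoc CPAT check reports the fraction of survivors scored noncoding
without removing anything.

Boundary conventions: length exactly 200 fails step 2; a CPC or CNCI score
of exactly 0 fails its step; a blastx hit at exactly the E-value cutoff
causes removal. Transcripts with a missing CPC/CNCI score are removed
(only evidence-backed noncoding calls survive) unless
``missing_score_policy='keep'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import ScoreTable
from .transcript_model import (
    ReferenceExonIndex,
    TranscriptModel,
    exonic_overlap,
    spliced_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "CASCADE_STEPS",
    "noncoding_consensus",
    "apply_cascade",
    "cpat_validation",
    "builtin_coding_score",
    "HexamerModel",
    "longest_orf_length",
]

CASCADE_STEPS = (
    "multiexonic",
    "length_gt_200",
    "no_known_gene_overlap",
    "cpc_noncoding",
    "cnci_noncoding",
    "no_pfam_domain",
    "no_blastx_hit",
)


@dataclass
class FilterConfig:
    min_exons: int = 2
    min_length: int = 201  # '>200 nt': spliced length must be >= 201
    cpc_max: float = 0.0  # strict <
    cnci_max: float = 0.0  # strict <
    blastx_evalue_cutoff: float = 1e-5  # hits at E <= cutoff removed
    require_no_pfam: bool = True
    cpat_coding_cutoff: float = 0.5
    overlap_strand_mode: str = "any"
    missing_score_policy: str = "remove"  # or 'keep'

    def __post_init__(self) -> None:
        if self.min_exons < 1:
            raise ValueError("min_exons must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.blastx_evalue_cutoff <= 0:
            raise ValueError("blastx_evalue_cutoff must be positive")
        if not 0.0 <= self.cpat_coding_cutoff <= 1.0:
            raise ValueError("cpat_coding_cutoff must lie in [0,1]")
        if self.missing_score_policy not in ("remove", "keep"):
            raise ValueError("missing_score_policy must be 'remove' or 'keep'")


@dataclass
class FilterStep:
    name: str
    n_input: int
    n_surviving: int
    removed_ids: list[str] = field(default_factory=list)
    removal_reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class FilterReport:
    steps: list[FilterStep]
    survivor_ids: list[str]
    n_loci: int

    def __post_init__(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.n_surviving != b.n_input:
                raise ValueError("step counts do not chain")
        counts = [s.n_surviving for s in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("survivor counts must be non-increasing")

    @property
    def removed(self) -> dict[str, str]:
        """Removed transcript id -> reason (the first failing step)."""
        out: dict[str, str] = {}
        for step in self.steps:
            out.update(step.removal_reasons)
        return out

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {"step": s.name, "input": s.n_input, "surviving": s.n_surviving,
             "removed": s.n_input - s.n_surviving}
            for s in self.steps
        ]


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------


def noncoding_consensus(
    cpc_score: float | None, cnci_score: float | None, cfg: FilterConfig | None = None
) -> bool | None:
    """True iff both CPC and CNCI scores fall strictly below their cutoffs.

    Returns ``None`` (undetermined) when either score is missing; the
    cascade then removes the transcript with reason ``missing score``
    under the default conservative policy.
    """
    cfg = cfg or FilterConfig()
    if cpc_score is None or cnci_score is None:
        return None
    return cpc_score < cfg.cpc_max and cnci_score < cfg.cnci_max


def _step_predicate(name: str, cfg: FilterConfig, scores: ScoreTable, ref_index):
    if name == "multiexonic":
        return lambda t: t.exon_count >= cfg.min_exons
    if name == "length_gt_200":
        return lambda t: spliced_length(t) >= cfg.min_length
    if name == "no_known_gene_overlap":
        return lambda t: not exonic_overlap(t, ref_index, strand_mode=cfg.overlap_strand_mode)

    def score_pred(t: TranscriptModel, field_name: str, cutoff: float) -> bool:
        val = scores.get(field_name, t.id)
        if val is None:
            return cfg.missing_score_policy == "keep"
        return val < cutoff

    if name == "cpc_noncoding":
        return lambda t: score_pred(t, "cpc_score", cfg.cpc_max)
    if name == "cnci_noncoding":
        return lambda t: score_pred(t, "cnci_score", cfg.cnci_max)
    if name == "no_pfam_domain":
        if not cfg.require_no_pfam:
            return lambda t: True
        return lambda t: not bool(scores.pfam_hit.get(t.id, False))
    if name == "no_blastx_hit":

        def blast_pred(t: TranscriptModel) -> bool:
            e = scores.blastx_min_evalue.get(t.id)
            return e is None or e > cfg.blastx_evalue_cutoff

        return blast_pred
    raise KeyError(name)


def apply_cascade(
    transcripts: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel] | ReferenceExonIndex,
    scores: ScoreTable,
    cfg: FilterConfig | None = None,
    step_order: Sequence[str] = CASCADE_STEPS,
) -> tuple[list[TranscriptModel], FilterReport]:
    """Run the filter cascade; return survivors and the per-step report.

    Each removed transcript carries exactly one removal reason: the first
    step it fails. Steps 3-7 are pure per-transcript predicates, so their
    relative order changes only the attribution of reasons, never the
    survivor set.
    """
    if reference is None:
        raise ValueError("a reference annotation is required for the overlap step")
    cfg = cfg or FilterConfig()
    if set(step_order) != set(CASCADE_STEPS):
        raise ValueError("step_order must be a permutation of the seven cascade steps")
    ref_index = (
        reference
        if isinstance(reference, ReferenceExonIndex)
        else ReferenceExonIndex(reference)
    )
    current = list(transcripts)
    steps: list[FilterStep] = []
    for name in step_order:
        pred = _step_predicate(name, cfg, scores, ref_index)
        kept, removed = [], []
        for t in current:
            (kept if pred(t) else removed).append(t)
        reasons = {}
        for t in removed:
            if name in ("cpc_noncoding", "cnci_noncoding") and scores.get(
                {"cpc_noncoding": "cpc_score", "cnci_noncoding": "cnci_score"}[name], t.id
            ) is None:
                reasons[t.id] = "missing score"
                logger.warning("transcript %s removed at %s: missing score", t.id, name)
            else:
                reasons[t.id] = name
        steps.append(
            FilterStep(name, len(current), len(kept), [t.id for t in removed], reasons)
        )
        current = kept
    survivors = current
    n_loci = len({t.locus_id for t in survivors})
    report = FilterReport(steps, [t.id for t in survivors], n_loci)
    return survivors, report


def cpat_validation(
    survivors: Iterable[TranscriptModel],
    scores: ScoreTable,
    cfg: FilterConfig | None = None,
) -> tuple[float | None, list[str]]:
    """Post-hoc CPAT check on cascade survivors.

    Returns the fraction of survivors with coding probability below the
    cutoff and the ids flagged at/above it. Survivors without a CPAT score
    are excluded from the denominator; an empty denominator yields ``None``.
    Flagged transcripts are reported, not removed.
    """
    cfg = cfg or FilterConfig()
    n_scored = 0
    n_noncoding = 0
    flagged: list[str] = []
    for t in survivors:
        prob = scores.cpat_coding_prob.get(t.id)
        if prob is None:
            logger.warning("survivor %s has no CPAT score; excluded from validation", t.id)
            continue
        n_scored += 1
        if prob < cfg.cpat_coding_cutoff:
            n_noncoding += 1
        else:
            flagged.append(t.id)
    if n_scored == 0:
        return None, flagged
    return n_noncoding / n_scored, flagged


# ---------------------------------------------------------------------------
# built-in stand-in coding scorer
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
ORF_THRESHOLD = 300  # nt; ORFs shorter than this score negative


def longest_orf_length(sequence: str) -> int:
    """Length in nt of the longest complete ORF (ATG..stop, stop included).

    Only the forward strand is scanned. Returns 0 when no complete ORF
    exists.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


class HexamerModel:
    """Hexamer log-likelihood model separating coding from noncoding sequence.

    Frequencies are estimated from labeled training sequences with add-one
    smoothing; ``score`` returns the mean per-hexamer log2 likelihood ratio
    (coding over noncoding), positive for coding-like composition.
    """

    def __init__(self, log_ratios: dict[str, float]):
        self.log_ratios = log_ratios

    @classmethod
    def fit(cls, coding: Iterable[str], noncoding: Iterable[str]) -> "HexamerModel":
        import itertools
        import math

        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
        counts = {label: dict.fromkeys(kmers, 1) for label in ("c", "n")}
        for label, seqs in (("c", coding), ("n", noncoding)):
            tab = counts[label]
            for seq in seqs:
                seq = seq.upper()
                for i in range(len(seq) - 5):
                    k = seq[i : i + 6]
                    if k in tab:
                        tab[k] += 1
        tot = {label: sum(counts[label].values()) for label in ("c", "n")}
        log_ratios = {
            k: math.log2((counts["c"][k] / tot["c"]) / (counts["n"][k] / tot["n"]))
            for k in kmers
        }
        return cls(log_ratios)

    def score(self, sequence: str) -> float:
        seq = sequence.upper()
        vals = [
            self.log_ratios[seq[i : i + 6]]
            for i in range(len(seq) - 5)
            if seq[i : i + 6] in self.log_ratios
        ]
        if not vals:
            return 0.0
        return float(sum(vals) / len(vals))


def builtin_coding_score(
    sequence: str, hexamer_model: HexamerModel | None = None
) -> tuple[float, float]:
    """Stand-in (pseudo-CPC, pseudo-CNCI) scores so the cascade can run
    without the external coding-potential tools. Not a reimplementation of
    either tool.

    pseudo-CPC is ``(longest ORF nt - 300) / 300`` and exactly ``-1`` when
    the sequence contains no complete ORF (in particular, no ATG).
    pseudo-CNCI is the hexamer model's mean log2 likelihood ratio, or 0.0
    when no model is supplied. Both negative implies noncoding under the
    consensus rule.
    """
    if not sequence:
        raise ValueError("empty sequence")
    orf = longest_orf_length(sequence)
    pseudo_cpc = -1.0 if orf == 0 else (orf - ORF_THRESHOLD) / ORF_THRESHOLD
    pseudo_cnci = hexamer_model.score(sequence) if hexamer_model is not None else 0.0
    return pseudo_cpc, pseudo_cnci
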