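# Methods

## The identification cascade

The screen treats lncRNA calling as sequential evidence filtering. Input is
a set of assembled transcript models (exon chains on a genome) plus a
reference annotation and per-transcript coding-potential evidence. The seven
steps, in order: (1) at least two exons; (2) spliced length > 200 nt;
(3) no exonic overlap with a known gene; (4) CPC score < 0; (5) CNCI score
< 0; (6) no Pfam protein-domain hit; (7) no blastx protein hit at
E ≤ 10⁻⁵. Steps 3–7 are pure per-transcript predicates, so the survivor set
is invariant to their order; only the attribution of removal reasons (the
first failing step) depends on it. The CPAT coding probability is a post-hoc
validation of the survivors, not an eighth removal step: transcripts at or
above the cutoff are flagged and reported but retained.

Boundary conventions, fixed once and tested:

- "> 200 nt" means spliced (exonic) length ≥ 201. Spliced length, not
  genomic span, is what assemblers report as transcript length and what the
  length filter operates on; a boundary transcript of exactly 200 nt fails.
- "score < 0" is strict; a CPC or CNCI score of exactly 0 fails its step.
- The blastx cutoff is inclusive on the hit side: a hit at exactly
  E = 10⁻⁵ causes removal, as is conventional for a reporting cutoff.
- Overlap with known genes uses exonic overlap on either strand by default
  (`strand_mode="any"`), the stricter of the two defensible readings for a
  strand-ambiguous assembly; same-strand-only is available.
- Transcripts with a missing CPC or CNCI score are removed with reason
  "missing score": only evidence-backed noncoding calls survive. The
  permissive policy (`missing_score_policy="keep"`) is exposed for score
  tables known to be incomplete.

### The built-in stand-in scorer

`builtin_coding_score` exists so the cascade is runnable without the
external coding-potential tools. It is not a reimplementation of any of
them. Its pseudo-CPC is `(longest complete ORF in nt − 300) / 300`
(forward-strand ORFs, ATG through stop inclusive), exactly −1 when no
complete ORF exists; 300 nt (100 codons) is the conventional floor below
which ORFs are uninformative. Its pseudo-CNCI is the mean per-hexamer log2
likelihood ratio under coding vs noncoding hexamer tables fitted (add-one
smoothing) to labeled training sequences, e.g. the generator's
`make_labeled_sequences`. Both negative ⇒ noncoding under the consensus
rule. On held-out generator sequences the consensus rule classifies ≈99%
correctly; the residual errors are noncoding sequences that contain a
spurious ≥ 300 nt ORF, which is why the generator's noncoding training
sequences default to 500 nt (the chance of a long spurious ORF grows
quickly with length).

## Feature-class statistics

For each transcript the region classes are: exons; introns (the gaps
between consecutive exons); and 1 kb upstream/downstream flanks, assigned
strand-awarely (upstream precedes the 5′ end in transcription direction)
and clipped at chromosome bounds. Flank direction matters because the
reported GC asymmetry between upstream and downstream regions is only
meaningful relative to transcription direction. Exons contribute per
transcript without cross-transcript merging, matching the per-transcript
region framing of the analysis; a caller wanting merged regions can
deduplicate the `RegionSet`. Background is 5,000 random 1 kb windows,
chromosome chosen proportional to length, start uniform, sampled with
replacement and allowed to overlap genes (no exclusions by default; N-free
redrawing is a flag).

GC content is (G+C)/(A+C+G+T) with N excluded from numerator and
denominator; an all-N region is missing, not zero. SNP density is
1000 × count / length; a SNP at position p belongs to [start, end) iff
start ≤ p < end. Both pooled (sum of counts over sum of lengths) and
per-region values are computed, because group comparisons use rank tests on
per-region distributions while headline numbers are pooled.

The Mann–Whitney U test uses exact enumeration of all C(n+m, n) label
assignments on pooled midranks when n+m ≤ 14, two-sided by distance from
the null mean nm/2 — valid with ties because the permutation-null U
distribution is symmetric about nm/2 regardless of the tie pattern. Larger
samples use the tie-corrected normal approximation with continuity
correction (via scipy). p-values below 2.2 × 10⁻¹⁶ are printed as
"< 2.2e-16" in reports. The 2^−ΔΔCt computation is the standard relative
expression arithmetic: ΔΔCt = (Ct_target − Ct_ref)_sample −
(Ct_target − Ct_ref)_calibrator.

## Conservation

Chain files are parsed on the reference side only: each ungapped block
contributes the interval [cursor, cursor+size), the cursor advancing by
size + dt. Query-side coordinates are parsed for validation and discarded —
the conservation rule needs only which reference bases are covered, never a
liftover. Coverage of a transcript is covered exonic bases over spliced
length; the denominator is exonic because the transcript's nucleotides are
its exons. Each base counts once even under overlapping chains; the
stricter reading ("covered by exactly one chain") is available as
`unique_only`.

Conserved-in-species means coverage ≥ 0.5, boundary inclusive. The default
pig-specific rule is *below threshold in both species*, so the four groups
partition the input — the reported group counts sum to the input size,
which a literal zero-overlap rule could not reproduce (transcripts with
0 < coverage < 50% in both species would be unclassified). The literal rule
is retained as `pig_specific_rule="zero_overlap_both"`, under which such
transcripts are labeled `unclassified`.

Transcript-level homology is called per species from blastn tabular hits:
aligned iff ≥ 1 hit at E ≤ 0.01 (any alignment length by default; a
minimum-length floor is exposed, since the precise "can be aligned"
criterion admits both readings). Score-track summaries average per-base
scores over each region's covered bases only and report a 101-point
cumulative fraction-of-regions-≤-score table per feature class.

## The synthetic-data generator

The generator defines the desk-scale study conditions. Defaults: two
1.25 Mb chromosomes at background GC 41.73%; 300 protein-coding genes
(spliced length ~N(1982.9, 400) nt, exon count 2 + Poisson(6.71)); 200 true
lncRNAs (~N(1082.7, 300) nt, 2 + Poisson(0.38) exons); 100 noise
transcripts (40 single-exon, 30 short multiexonic ≤ 200 nt, 30 overlapping
a known exon); per-class GC targets 48.15/43.67/47.38/43.82%
(lncRNA exon/intron/upstream/downstream), 51.59% for PCG exons; per-class
SNP densities 28.06/29.22/27.96/30.56 SNPs/kb (lncRNA) and
19.00/24.59/23.98/25.42 (PCG) with 28.45 intergenic; FPKM lognormal with
means 1.93 (lncRNA) vs 10.4 (PCG); a conservation split of
38.1/1.7/24.6% (human+pig / pig+mouse / all three) with the remainder
pig-specific, at planted coverages 0.8 (conserved) / 0.1 / 0.0; homology
fractions 60.7% (human) and 40.2% (mouse). The mean values mirror the
characterized contrasts of the pig lncRNA catalog; the PCG intron/flank GC
targets (44.8/47.0/44.0%), for which no exact figure is reported, were
chosen once to preserve the reported orderings. The genome is sized so that
every transcript's span plus both 1 kb flanks occupies a pairwise-disjoint
slot — the property that makes exact-count planting recoverable — with
~100 kb of slack; two 1 Mb chromosomes would not hold 600 disjoint slots at
these lengths.

Planting is exact-count where tests assert equality: each region gets
`round(density × length / 1000)` SNPs at distinct positions and a sequence
with `round(gc × length)` G/C bases; chain blocks cover
`round(coverage × spliced length)` exonic bases, taken from the 5′-most
exons. PCG spliced sequences additionally carry a full-length clean ORF:
after exact-GC generation the first codon is set to ATG, the last to TAA,
and in-frame stop codons are replaced by permutations of their own three
letters (TAA→ATA, TAG→AGT, TGA→GAT), which preserves base composition
except for the two fixed terminal codons (≤ ~2 bases per transcript, well
inside the ±0.01 recovery tolerance). Ground truth records the *realized*
per-region GC and SNP counts, so recovery tests compare against exact
bookkeeping rather than the real-valued targets, which per-region rounding
cannot hit exactly.

All draws come from one `numpy.random.Generator` keyed by the seed, in a
fixed documented order (genome, structures, planting, chains, scores,
homology, FPKM), giving byte-identical bundles for identical configs.
Everything flagged noise carries coding-like score-table entries
(N(+2, 0.7) CPC/CNCI vs N(−2, 0.7) for lncRNAs), so the expected cascade
survivor set is computable from the bookkeeping alone, and the end-to-end
test asserts set equality against it.

### What the generator does not emulate

Real genomes have repeats, assembly gaps, GC isochores, splice-site motifs
and overlapping transcription; real chain files carry query coordinates,
inversions and chain scores; real coding-potential scores correlate with
each other and with transcript length. Passing tests therefore demonstrate
that the *arithmetic and bookkeeping* of each stage are correct under
controlled conditions — not that the default thresholds are optimal for any
particular real dataset, nor that the headline numbers of any real survey
(which depend on its genome build, SNP build and chain files) would be
reproduced at this scale.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; GTF and VCF are
  converted on read and reconverted on write, eliminating off-by-one
  classes at module boundaries.
- Unstranded ('.') transcripts are accepted with a warning and follow the
  '+' convention for flank extraction.
- A flank fully clipped away (transcript at a chromosome edge) is `None`,
  not a zero-length interval; empty survivor sets give a missing CPAT
  fraction, not 0; `venn_summary` of an empty call set raises; a transcript
  whose chromosome is absent from a chain set has coverage 0 (logged), not
  an error, since chain files legitimately omit unaligned chromosomes.
- Duplicate score-table rows keep the extreme value (max score, min
  E-value) with a warning.
- Percentages are rounded to one decimal at the reporting boundary only;
  internal fractions are never rounded.

## Problem sizes

The default bundle (2 × 1.25 Mb genome, 600 genes, ~63k SNPs, 5,000 random
windows) generates in under a second and the full pipeline runs in about
one; the whole test suite, including 100-fixture brute-force oracle sweeps
and a 1,000-replicate null calibration of the rank test, completes in well
under a minute. These sizes were chosen so a contributor can iterate
locally; all of them scale linearly through `SimulationConfig`.
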