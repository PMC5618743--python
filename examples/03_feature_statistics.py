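"""GC content and SNP density per feature class, with rank tests.

For each transcript category the exons, introns and 1 kb flanking regions
are summarized; 5,000 random 1 kb windows give a genomic background. The
Mann-Whitney U test compares per-region distributions between groups.
"""

from lncscan import (
    SimulationConfig,
    class_summaries,
    delta_delta_ct,
    mann_whitney_u,
    simulate,
)
from lncscan.feature_stats import format_pvalue, per_region_values
from lncscan.transcript_model import regions_for

bundle = simulate(SimulationConfig(seed=42), "scratch_example_bundle")
truth = bundle.truth.transcripts
lnc_ids = set(truth[truth.category == "lnc"].transcript_id)
lnc = [t for t in bundle.assembled if t.id in lnc_ids]

table = class_summaries(
    {"lncRNA": lnc, "PCG": bundle.reference}, bundle.genome, bundle.snps, seed=0
)
cols = ["category", "feature_class", "n_regions", "gc_fraction", "snp_density"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# rank test on per-exon GC: lncRNA exons vs protein-coding exons
gc = {
    name: per_region_values(
        regions_for(ts, classes=("exon",)), genome=bundle.genome
    ).gc.to_numpy()
    for name, ts in (("lncRNA", lnc), ("PCG", bundle.reference))
}
u, p = mann_whitney_u(gc["lncRNA"], gc["PCG"])
print(f"lncRNA vs PCG exon GC: U={u:.0f}, p {format_pvalue(p)}")
# GC fractions mirror the planted contrast (lncRNA exons ~0.48 vs PCG ~0.52)
# and SNP densities the planted 28.06 vs 19.00 SNPs/kb.

# qPCR arithmetic: fold change of a target gene relative to a reference
fold = delta_delta_ct(25.0, 20.0, 24.0, 20.0)
print(f"2^-ddCt fold change for Ct (25,20) vs calibrator (24,20): {fold}")
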