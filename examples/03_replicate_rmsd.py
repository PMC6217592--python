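"""Quantify replicate cohesion with root mean squared distance (RMSD).

RMSD between two samples' log2-ratio profiles measures how far apart the
replicates sit; the summary aggregates replicate pairs per chemical, all 36
within-MOA pairs per MOA, and the five MOA averages into a platform score.
Smaller is tighter.
"""

from xplat.preprocess import cpm_log2, filter_low_count_genes, log2_ratio
from xplat.rmsd import summarize_rmsd
from xplat.simulate import default_truth, make_three_platform_bundle

truth = default_truth(n_genes=2000, seed=7)
bundle = make_three_platform_bundle(truth, n_genes=2000)

counts = filter_low_count_genes(bundle.temposeq_counts, threshold=214)
print(f"low-count filter: {bundle.temposeq_counts.n_genes} -> {counts.n_genes} genes")
ratio = log2_ratio(cpm_log2(counts), bundle.design)

summary = summarize_rmsd(ratio, bundle.design)
print(f"pairs computed: {len(summary.pairwise)} (36 per MOA)")
for moa, value in sorted(summary.moa_rmsd.items()):
    print(f"  MOA-RMSD {moa:<11s} {value:.3f}")
print(f"average chemical-RMSD: {summary.avg_chemical_rmsd:.3f}  "
      "(replicate-pair agreement within chemicals)")
print(f"platform-RMSD:         {summary.platform_rmsd:.3f}  "
      "(also includes chemical-to-chemical spread within MOAs)")
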