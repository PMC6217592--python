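"""Generate the default synthetic three-platform bundle and look inside it.

The bundle renders one simulated rat-liver MOA experiment (5 modes of action
x 3 chemicals x 3 replicates + vehicle controls) as microarray-like log2
intensities, RNA-Seq-like transcript counts with lengths, and TempO-Seq-like
targeted panel counts, linked by a shared cluster-ID map.
"""

from xplat.simulate import default_truth, make_three_platform_bundle

truth = default_truth(n_genes=2000, seed=7)
bundle = make_three_platform_bundle(truth, n_genes=2000)

design = bundle.design
print(f"samples: {len(design.table)} ({len(design.treated)} treated, "
      f"{len(design.controls)} controls)")
print(f"MOAs: {', '.join(design.moas)}")
print(f"microarray probes: {bundle.microarray.n_genes} (scale {bundle.microarray.scale})")
print(f"rnaseq transcripts: {bundle.rnaseq_counts.n_genes} "
      f"(median length {int(bundle.rnaseq_lengths.median())} nt)")
print(f"temposeq panel genes: {bundle.temposeq_counts.n_genes}")
print(f"true variance split: {truth.variance_fractions}")
print(f"differentially expressed genes: {len(truth.de_gene_ids)} "
      f"at +-{truth.effect_size} log2 units")

# The three matrices describe the same underlying biology: the ID map ties
# each platform's feature IDs back to the shared cluster genes.
shared = bundle.id_map.cluster_ids("temposeq")
print(f"temposeq panel covered by microarray: "
      f"{len(shared & bundle.id_map.cluster_ids('microarray'))}/{len(shared)}")
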