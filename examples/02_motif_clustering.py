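"""Deconvolve a two-allele peptide mixture into its binding motifs.

A sample expressing two HLA alleles yields a mixture of motifs.  The Gibbs
sampler partitions the peptides for K = 1..3 clusters and selects K by the
KLD objective; the consensus sequences show the recovered anchors.
"""

from introspect import GibbsConfig, MotifSpec, cluster_peptides, sample_motif_peptides, solution_report

allele_a = MotifSpec(anchors={2: ("L", 0.8), 9: ("V", 0.8)})
allele_b = MotifSpec(anchors={2: ("K", 0.8), 9: ("R", 0.8)})
pep_a, _ = sample_motif_peptides(allele_a, 100, 0.05, seed=1)
pep_b, _ = sample_motif_peptides(allele_b, 100, 0.05, seed=2)

result = cluster_peptides(
    pep_a + pep_b, GibbsConfig(cluster_range=(1, 3), n_seeds=2, rng_seed=11)
)
for K in sorted(result.solutions):
    print(solution_report(result.solutions[K]))
    print()
print(f"selected number of clusters: {result.selected_K}")
print(
    "\nThe selected K=2 solution's consensus sequences carry the planted\n"
    "anchors (x-L-...-V and x-K-...-R); low-scoring outliers sit in trash."
)
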