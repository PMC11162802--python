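"""Assembly statistics and quality classification.

Builds three synthetic assemblies — one long chromosome, one decent
draft, one fragmented draft — and classifies them under both published
QC policies.
"""

import numpy as np

import netenrich as ne

rng = np.random.default_rng(0)


def random_contig(length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


assemblies = {
    # one 6 Mb chromosome: N50 > 5 Mb -> HQ under the results policy
    "closed_genome": [random_contig(6_000_000 // 1000) * 1000],
    # 20 contigs of ~300 kb: < 50 contigs, N50 > 100 kb -> MQ everywhere
    "draft_genome": [random_contig(300_000 // 100) * 100 for _ in range(20)],
    # 120 short contigs -> LQ
    "fragmented_genome": [random_contig(30_000 // 10) * 10 for _ in range(120)],
}

for genome_id, contigs in assemblies.items():
    stats = ne.assembly_stats(contigs, genome_id)
    results_class = ne.classify_quality(stats, "results_policy")
    methods_class = ne.classify_quality(stats, "methods_policy",
                                        assembly_level="scaffold")
    print(f"{genome_id}: {stats.n_contigs} contigs, "
          f"N50={stats.n50:,} bp, GC={stats.gc_fraction:.3f} "
          f"-> results_policy={results_class}, methods_policy={methods_class}")

# The two policies differ on the closed genome: the methods policy wants
# a declared 'complete genome'/'chromosome' assembly level for HQ, while
# the results policy infers quality from N50 alone.
stats = ne.assembly_stats(assemblies["closed_genome"], "closed_genome")
print("closed genome with declared level 'complete genome':",
      ne.classify_quality(stats, "methods_policy", "complete genome"))
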