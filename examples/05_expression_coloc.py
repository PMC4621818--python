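"""Microarray DE filtering and DEG-SNP co-localization.

Simulates the 2 genotypes x 2 tissues x 2 treatments x 3 replicates array
design with planted DEGs, quantile-normalizes, tests drought vs control per
genotype x tissue (Welch t + BH-FDR), calls DEGs at fold change >= 2 and
FDR <= 0.01, and finally links DEGs to significant SNPs through a genetic
map (< 2 cM) and ortholog physical positions (<= 1.8 Mb).
"""

import pandas as pd

from drylysim import coloc, expression, synth

ids = [f"UG{i:05d}" for i in range(30)]
truth = synth.ExpressionTruth(
    true_degs={("B47", "leaf"): {g: (2.5 if i % 2 else -2.5)
                                 for i, g in enumerate(ids)}}
)
sim = synth.simulate_expression(n_genes=1500, truth=truth, seed=8, rep_sd=0.08)
print(f"design: {sim.matrix.shape[1]} hybridizations "
      f"({sim.annotations.genotype.nunique()} genotypes x "
      f"{sim.annotations.tissue.nunique()} tissues x "
      f"{sim.annotations.treatment.nunique()} treatments x 3 replicates)")

norm = expression.quantile_normalize(sim.matrix)
qc = expression.replicate_qc(norm, sim.annotations)
print(f"replicate correlations: {qc.r.min():.3f}-{qc.r.max():.3f}")

de = expression.de_test(norm, sim.annotations, "B47", "leaf")
degs = expression.call_degs(de)
hit = len(set(degs.unigene_id) & set(ids))
print(f"DEGs called in B47 leaf: {len(degs)} ({hit}/{len(ids)} planted recovered)")

maps = synth.simulate_maps(n_deg=100, n_snp=39, planted_pairs=7, seed=8)
genetic = coloc.genetic_colocalize(maps.deg_map, maps.snp_map)
physical = coloc.physical_colocalize(
    coloc.best_ortholog(maps.deg_hits), coloc.best_ortholog(maps.snp_hits)
)
combined = coloc.combine_candidates(genetic, physical)
print(f"\ncandidate genes: {len(genetic)} genetic (< 2 cM), "
      f"{len(physical)} physical (<= 1.8 Mb), {len(combined)} deduplicated pairs")
print(combined.head(8).to_string(index=False))
print("\nPlanted co-localizations are recovered exactly; all other "
      "placements were generated outside both LD windows.")
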