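"""Matched-null permutation enrichment of lead SNPs near panel genes.

Null SNP sets are matched to the leads on MAF, LD-buddy count, gene
distance and gene density; the one-tailed permutation p compares the
observed panel-gene overlap (500 kb radius) with the matched expectation.
"""

import numpy as np

from lvgwas import (
    SimulationConfig,
    gene_panel_overlap,
    matched_null_sets,
    matching_properties,
    permutation_enrichment_p,
    simulate_genotypes,
)
from lvgwas.synthetic import make_gene_map

cfg = SimulationConfig(n_samples=500, n_variants=400, n_causal=12, seed=5)
panel = simulate_genotypes(cfg)
causal = np.random.default_rng(5).choice(400, 12, replace=False)
# panel genes placed on top of the causal variants -> a true enrichment
gmap = make_gene_map(panel, n_genes=80, n_panel_genes=12,
                     panel_near_variants=causal, seed=5)
panel_genes = gmap.loc[gmap["panel_flag"] == 1, "gene"].tolist()

props = matching_properties(panel, gmap, window_kb=250)
leads = causal[:6]  # pretend these causal variants were found as lead SNPs
nulls_idx = matched_null_sets(leads, props, n_sets=999, seed=5)

chrom = panel.variants["chrom"].to_numpy()
pos = panel.variants["pos"].to_numpy()
obs = gene_panel_overlap(chrom[leads], pos[leads], gmap, panel_genes, 250)
nulls = np.array(
    [gene_panel_overlap(chrom[s], pos[s], gmap, panel_genes, 250) for s in nulls_idx]
)
p = permutation_enrichment_p(obs, nulls)
print(f"observed overlap: {obs} of {len(leads)} leads")
print(f"matched-null mean: {nulls.mean():.2f} (sd {nulls.std():.2f})")
print(f"one-tailed permutation p = {p:.4g}  (add-one convention, 999 sets)")
# Leads placed on panel genes overlap more than their matched nulls, giving
# a small p; with no true signal the p is calibrated (super-uniform).
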