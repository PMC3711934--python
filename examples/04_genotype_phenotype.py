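"""Relate genetic relatedness to morphological similarity.

Genetic distance between strains = fraction of SNP sites that differ;
phenotypic similarity = Pearson correlation of their leading phenotypic
PC scores.  The Spearman correlation over all strain pairs asks whether
closer kin look more alike; the gPC x pPC screen asks whether any axis of
genetic population structure aligns with any phenotypic axis.  In this
synthetic dataset phenotype is generated independently of genotype, so
both analyses should find (approximately) nothing.
"""

import phenonoise as pn

cfg = pn.SimConfig(
    n_strains=12, n_reps=5, n_cells=60, n_base_traits=24, n_other=7,
    n_sites=2000, n_subpopulations=3, seed=11,
)
ds = pn.generate(cfg)
traits = pn.summarize_cells(ds.cells, ds.catalogue)
rs = pn.ranksum_transform(traits)
pca = pn.pca_ranksum(rs)

pairs = pn.pairwise_set(ds.genotypes, pca.scores, k=10)
rho = pn.distance_similarity_correlation(pairs)
print(f"strain pairs: {pairs.n_pairs}")
print(f"Spearman rho (similarity vs genetic distance): {rho:+.3f}"
      " (phenotype simulated independently of genotype -> expect ~0)")

clean = ds.annotations.clean_lineage_strains
if len(clean) >= 3:
    rho_clean = pn.distance_similarity_correlation(pairs, subset=clean)
    print(f"clean-lineage subset ({len(clean)} non-mosaic strains): rho = {rho_clean:+.3f}")

scr = pn.gpc_ppc_screen(ds.genotypes, rs, B=200, target_fdr=0.05, seed=4)
print(f"gPC x pPC Spearman correlations in [{scr.min_rho:+.3f}, {scr.max_rho:+.3f}]")
print(f"any pair significant at FDR {scr.target_fdr}: {scr.any_significant}")
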