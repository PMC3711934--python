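"""Explore the morphospace: rank-sum PCA, chance threshold, AU clustering.

The trait table is rank-sum transformed (per trait, each strain gets the
sum of its replicate ranks), decomposed by PCA, and compared against the
variance share any component would capture by chance under independent
column permutation.  Strains are then clustered by the angle between
their component-score vectors, with multiscale-bootstrap AU support per
cluster: clusters at AU > 0.95 would be called significant groups.
"""

import numpy as np

import phenonoise as pn

cfg = pn.SimConfig(
    n_strains=12, n_reps=5, n_cells=60, n_base_traits=24, n_other=7,
    n_sites=100, seed=11,
)
ds = pn.generate(cfg)
traits = pn.summarize_cells(ds.cells, ds.catalogue)

rs = pn.ranksum_transform(traits)
print(f"rank-sum matrix: {rs.values.shape[0]} strains x {rs.values.shape[1]} params;"
      f" every column sums to {rs.column_sum}")

pca = pn.pca_ranksum(rs)
chance = pn.pc_chance_threshold(rs, B=300, seed=2)
pca.chance_threshold = chance.expected_max
print(f"top variance shares: {np.round(pca.proportions[:5], 3)}")
print(f"chance max share:    {chance.expected_max:.3f} "
      f"-> {pca.n_above_chance()} components above chance")

dend = pn.au_cluster(rs, B=400, seed=3)
sig = dend.significant_clusters()
print(f"clusters assessed: {len(dend.clusters)}; at AU > 0.95: {len(sig)}")
for c in sorted(sig, key=lambda c: len(c.members)):
    print(f"  AU={c.au:.3f}  {c.members}")
# AU extrapolates bootstrap support across resampling sizes; it estimates
# the probability the cluster is real rather than a finite-sample artefact.
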