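"""Fruit chemistry: PCA, hierarchical clustering, and the comparison of
chemical proximity with the species phylogeny.

Taxonomy need not predict chemistry: the generator's default chemical
tree places cherry away from strawberry even though both are Rosaceae.
The Ward dendrogram of fruit samples recovers the planted chemical
structure, and its Robinson-Foulds distance to the phylogeny is
therefore positive.
"""

import metaboflow as mf

config = mf.make_default_config(seed=1)
table, _ = mf.simulate(config)
fruit = table.split_kinds()["fruit"]

scaled = mf.scale_matrix(fruit)
res = mf.pca(scaled, n_components=3)
pct = 100 * res.variance_explained
print(f"fruit PCA: dim1 {pct[0]:.1f}%, dim2 {pct[1]:.1f}%, dim3 {pct[2]:.1f}% of variance")
print("dim1 sample scores (blackcurrant separates first):")
print(res.scores["PC1"].round(1).to_string())

dend = mf.hclust_dendrogram(scaled)
diets = {s: fruit.samples.loc[s, "diet"] for s in scaled.index}
print(f"\nchemical dendrogram (diet level): {mf.diet_tree_newick(dend, diets)}")
print(f"species phylogeny:                 {mf.PHYLOGENY_NEWICK}")
rf = mf.topology_distance(dend, mf.PHYLOGENY_NEWICK, diets)
print(f"rooted Robinson-Foulds distance: {rf} (> 0: taxonomy does not predict chemistry)")
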