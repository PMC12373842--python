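"""PCA morphospace of a screen: loadings and control separation.

Features are z-scored per variable, PCA is run, and loadings are
reported as eigenvector * sqrt(eigenvalue) so each entry is the
correlation between a feature and a component.
"""

from morphoscreen import (
    cumulative_variance,
    example_screen_config,
    pca_morphospace,
    pearson_matrix,
    simulate_screen,
)

features, _ = simulate_screen(example_screen_config(seed=4, n_compounds=200))

corr = pearson_matrix(features)
print("pairwise Pearson correlation (first 4 features):")
print(corr.iloc[:4, :4].round(2).to_string())

pca = pca_morphospace(features)
print("\nexplained variance ratio:", [f"{v:.3f}" for v in pca.explained_variance_ratio])
print(f"first 2 components explain {100 * cumulative_variance(pca, 2):.1f}% of variance")
print("\nPC loadings (eigenvector * sqrt(eigenvalue)):")
print(pca.loadings.iloc[:, :2].round(3).to_string())

roles = features.data.set_index(["plate_id", "well"]).loc[pca.scores.index, "role"]
for role in ("dmso", "positive"):
    sub = pca.scores[roles.to_numpy() == role]
    print(f"\n{role} wells: PC1 mean {sub['PC1'].mean():+.2f}, PC2 mean {sub['PC2'].mean():+.2f}")
# The positive (cystic) controls sit far from the DMSO (spiky) cluster
# along the leading components: the morphospace resolves the phenotype
# the screen selects for.
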