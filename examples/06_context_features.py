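"""Build local-composition and niche context features for single-cell data.

For each cell, the cell-type frequencies among its 30 nearest neighbours
describe the immediate microenvironment; k-means over these composition
vectors finds recurrent mesoscale niches.  Both can join gene-level columns
in a predictor matrix so that fitted coefficients separate gene-intrinsic,
neighbourhood and niche contributions to a target's expression.  The two
tissue regions below have disjoint type mixes, so two niches recover them.
"""

import numpy as np

import s3reg as s

rng = np.random.default_rng(4)
left = rng.uniform([0, 0], [1, 1], size=(150, 2))
right = rng.uniform([3, 0], [4, 1], size=(150, 2))
coords = np.vstack([left, right])
labels = (["epithelial"] * 100 + ["immune"] * 50
          + ["stromal"] * 100 + ["endothelial"] * 50)

features = s.build_context_features(coords, labels, k_neighbors=30,
                                    k_niches=2, seed=4)
print(f"cell types observed: {features.celltype_names}")
print(f"composition rows sum to one: "
      f"{np.allclose(features.local_composition.sum(axis=1), 1.0)}")
region = np.r_[np.zeros(150, dtype=int), np.ones(150, dtype=int)]
ari = s.adjusted_rand_index(region, features.niche_labels)
print(f"niche labels vs true regions: ARI = {ari:.2f} "
      f"(1 = niches exactly recover the two regions)")
for niche in range(2):
    mean_comp = features.local_composition[features.niche_labels == niche].mean(axis=0)
    desc = ", ".join(f"{t}={v:.2f}" for t, v in
                     zip(features.celltype_names, mean_comp))
    print(f"niche {niche + 1} mean composition: {desc}")
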