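"""Attribute a gene's spot-level expression to cell types.

On mixed-resolution platforms each spot aggregates several cells, so a
gene's measured expression is a proportion-weighted blend of cell-type
programs.  Regressing expression on deconvolved proportions with spatially
varying coefficients yields a per-spot, per-cell-type attribution; biology
imposes that attributions are non-negative and vanish where a cell type is
absent.  Here keratinocytes truly express the gene at level 2, the other
types not at all.
"""

import numpy as np

import s3reg as s

rng = np.random.default_rng(0)
n = 200
celltypes = ["keratinocyte", "fibroblast", "macrophage"]
proportions = rng.dirichlet([1.0, 1.0, 1.0], size=n) * rng.uniform(0.7, 1.0, (n, 1))
proportions[proportions < 0.05] = 0.0
true_levels = np.array([2.0, 0.0, 0.0])
expression = proportions @ true_levels + rng.normal(scale=0.05, size=n)
coords = rng.uniform(size=(n, 2))

graph = s.build_knn_graph(coords, k=7)
attribution = s.attribute_celltypes(
    expression, proportions, coords, graph,
    spot_ids=[f"spot{i:03d}" for i in range(n)],
    celltype_names=celltypes,
    opt=s.OptimizerConfig(max_iter=2500, seed=0),
    seed=0,
)

for k, ct in enumerate(celltypes):
    col = attribution.values[:, k]
    active = col > 0
    mean_level = col[active].mean() if active.any() else 0.0
    print(f"{ct:>13}: attributed in {active.mean():5.1%} of spots, "
          f"mean level where attributed = {mean_level:.3f} "
          f"(truth: {true_levels[k]:.1f})")
print("non-negativity and presence constraints hold by construction: "
      f"{(attribution.values >= 0).all()} / "
      f"{not ((attribution.values > 0) & (proportions == 0)).any()}")
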