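"""Choose the penalty triple by spatially blocked cross-validation.

Spatial data leaks information across random CV splits through spatial
autocorrelation, so folds hold out whole spatially coherent blocks.  Each
trial samples (lambda1, lambda2, lambda3) on a log scale over [1e-6, 1e2]
and is scored by mean squared prediction error on held-out blocks.
"""

import s3reg as s

dataset, _ = s.simulate_dataset(n=200, p=10, n_active=2, n_clusters=2, seed=7)
work, _ = s.standardize_dataset(dataset)

scheme = s.make_spatial_blocks(dataset.coords, n_blocks=10, seed=7)
print(f"{scheme.n_blocks} spatial blocks in {len(scheme.folds)} folds")

result = s.tune_hyperparameters(
    work, scheme, n_trials=20, seed=7,
    opt=s.OptimizerConfig(max_iter=300),
    sampler="adaptive",
)
l1, l2, l3 = result.best
best_mse = dict(result.trials)[result.best]
print(f"best penalties: lambda1={l1:.2e}, lambda2={l2:.2e}, lambda3={l3:.2e}")
print(f"mean validation MSE of the best triple: {best_mse:.3f} "
      f"(lower is better; the response variance is "
      f"{float(work.response.var()):.3f}, the score of a null model)")
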