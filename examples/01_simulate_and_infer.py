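"""Simulate a spatial scene with planted gradients and infer them back.

Builds a 30×30 spot lattice where 100 genes carry a planted linear
expression gradient (negative-binomial counts, mean 1, dispersion 0.5,
pattern running from absent to 3× the baseline mean) and 400 genes are
spatially random.  Individual sparse genes are too noisy for window-level
regression, so — as in pathway-level analyses — the genes are aggregated
into gene lists whose per-cell recovery scores become the features for
gradient inference.
"""

from pathlib import Path

import numpy as np

from lsgi import (
    LsgiConfig,
    SimulationSpec,
    SpatialProfile,
    build_grid_scaffold,
    infer_gradients,
    run_pipeline,
    score_gene_lists,
    simulate_scene,
)

spec = SimulationSpec(
    n_spots=900, n_patterned_genes=100, n_random_genes=400,
    n_gradient_lists=5, n_random_lists=5, seed=11,
)
profile, truth = simulate_scene(spec)
print(f"scene: {profile.n_units} spots × {profile.n_features} genes "
      f"({int(truth.patterned.sum())} with planted gradients, "
      f"{len(truth.gene_lists)} gene lists)")

scores = score_gene_lists(profile, truth.gene_lists)
score_profile = SpatialProfile(
    profile.unit_ids, profile.coords, scores.to_numpy(), list(scores.columns)
)

config = LsgiConfig(r2_cutoff=0.3, min_grid_frac=0.05, seed=1)
scaffold = build_grid_scaffold(score_profile, config)
field = infer_gradients(score_profile, scaffold, config)
print(f"grid: {scaffold.p} windows of {scaffold.q} spots "
      f"(each spot in ~{scaffold.q / config.s:.0f} windows)")

frac = {
    name: float((field.fits.loc[field.fits["feature"] == name, "r2"]
                 >= config.r2_cutoff).mean())
    for name in scores.columns
}
grad = np.mean([frac[n] for n in frac if truth.gradated[n]])
rand = np.mean([frac[n] for n in frac if not truth.gradated[n]])
print(f"fraction of windows called gradient (R² ≥ {config.r2_cutoff}): "
      f"{grad:.3f} for gradated lists vs {rand:.3f} for random lists — "
      "planted list-level gradients stand out against list-score noise")
print(f"retained features (gradients in ≥5% of grids): "
      f"{sorted(field.retained_features)}")

out = run_pipeline(score_profile, config, Path("scratch/example01"))
print(f"full pipeline outputs (tables, arrow map, manifest) in {out}/")
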