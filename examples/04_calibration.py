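"""Window-size calibration against a coordinate-shuffled null.

Simulates a lattice scene, destroys its spatial structure by shuffling
coordinates, and compares the false-positive rate of gradient calls across
window sizes Q.  Shuffled data should yield (almost) no fits with R² ≥ 0.4
once Q is 25 or larger; small windows overfit noise.
"""

from lsgi import SimulationSpec, calibration_sweep

spec = SimulationSpec(
    n_spots=1000, n_patterned_genes=20, n_random_genes=80,
    n_gradient_lists=4, n_random_lists=4, seed=2,
)
table = calibration_sweep(spec, q_values=[10, 25, 50], r2_grid=[0.4, 0.6])

print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
shuffled = table[table["scene"] == "shuffled"].set_index("q")
print(
    f"\nshuffled-scene fraction of fits with R² ≥ 0.4: "
    f"{shuffled.loc[10, 'frac_ge_0.4']:.2%} at Q=10 vs "
    f"{shuffled.loc[25, 'frac_ge_0.4']:.2%} at Q=25 — a 25-spot window "
    "with a 0.4–0.6 cutoff rejects spatially random noise, while Q=10 "
    "calls many false gradients."
)
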