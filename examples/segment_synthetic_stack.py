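"""Render a ground-truth confocal stack and recover its aggregate sizes.

Draw aggregate sizes from a known geometric law, render them as clusters of
1-µm fluorescent spheres in a depth-attenuated, noisy 16-bit z-stack, then
run the full segmentation chain (anchor-slice depth calibration, per-slice
rescaling, 3D labeling, singlet normalisation) and compare the recovered
volume-weighted mean and ECDF against the exact rendered truth.

A reduced imaging volume is used so the example runs in a few seconds; the
test suite exercises the full 200 x 200 x 40 µm, 113-slice geometry.
"""

import numpy as np

import gutfloc as g

spec = g.FixtureSpec(
    size_law="geometric", law_params={"p": 0.4},
    n_aggregates=120,
    stack_shape=(56, 384, 384), volume_um=(20.0, 100.0, 100.0),
    attenuation=(1.0, 0.5),          # front-to-back linear intensity decay
    noise=(800.0, 120.0, 5.0),       # background mean/sd + shot-noise scale
    seed=7,
)

rng = np.random.default_rng(spec.seed)
truth_table = g.sample_aggregate_sizes(spec, rng)
stack, _ = g.render_stack(truth_table, spec, rng)
print(f"rendered {len(truth_table)} aggregates "
      f"({int(truth_table.sizes.sum())} particles) into a "
      f"{stack.voxels.shape} stack")

result = g.segment_stack(stack)
true_vw = g.volume_weighted_mean(truth_table)
rec_vw = g.volume_weighted_mean(result.table)
f_true = g.volume_weighted_ecdf(truth_table)
f_rec = g.volume_weighted_ecdf(result.table)
grid = np.unique(np.concatenate([f_true.atoms, f_rec.atoms]))
ks = float(np.max(np.abs(f_true(grid) - f_rec(grid))))

print(f"objects found:              {len(result.table)}")
print(f"singlet volume estimate:    {result.singlet_volume:.3f} µm³ "
      f"(ideal 1-µm sphere: {4 / 3 * np.pi * 0.5**3:.3f} µm³)")
print(f"volume-weighted mean <N>:   true {true_vw:.2f}  recovered {rec_vw:.2f}")
print(f"ECDF Kolmogorov distance:   {ks:.3f}")
print()
print("The recovered size table matches the generating truth closely; the")
print("depth calibration has corrected the two-fold front-to-back dimming.")
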