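"""Calibrate the residual variance for a target plot heritability and verify
it on simulated, unselected inbred-line plots.

Run:  python examples/heritability_calibration.py
"""
import numpy as np

import breedsim as bs

rng = np.random.default_rng(2)
gmap = bs.build_genome_map(1, 3.0, 500, qtl_every_n=10)
raw = bs.sample_qtl_effects(gmap.n_qtl, rng=rng)
pool = bs.simulate_founder_population(bs.FounderConfig(), gmap, raw, rng)

target_h2_plot, ns, n_plots = 0.2, 20, 5000
lines = bs.sample_base_population(pool, n_plots, inbred=True, rng=rng)
dosage = lines[:, :, gmap.qtl_indices].sum(axis=1)
# fully inbred lines carry twice the Hardy-Weinberg additive variance
effects, _ = bs.standardize_effects(raw, dosage, 2.0)
g = bs.compute_tbv(dosage, effects[0])

sigma_e2 = bs.calibrate_residual_variance(sigma_g2=1.0, h2_plot=target_h2_plot,
                                          ns=ns, homozygosity=1.0)
plot_tbv = ns * g
plot_phe = plot_tbv + rng.normal(0, np.sqrt(sigma_e2), (n_plots, ns)).sum(axis=1)
realized = np.corrcoef(plot_tbv, plot_phe)[0, 1] ** 2

print(f"target plot heritability: {target_h2_plot}")
print(f"calibrated residual variance sigma_e2: {sigma_e2:.1f}")
print(f"realized plot heritability over {n_plots} plots: {realized:.3f}")
print("The closed form converts a plot-level heritability prior into the")
print("per-plant residual variance the simulator should add; the realized")
print("squared correlation between plot TBV sums and phenotype sums matches.")
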