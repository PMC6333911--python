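"""Optimum-contribution selection: trade genetic merit against the rate of
relationship (inbreeding) gain by sweeping the penalty weight omega.

Run:  python examples/ocs_tradeoff.py
"""
import numpy as np

import breedsim as bs

rng = np.random.default_rng(4)
ped = bs.Pedigree()
base = [ped.add_base(False) for _ in range(6)]
cands = [ped.add_cross(int(rng.integers(6)), int(rng.integers(6)), 1, 1, 1)
         for _ in range(12)]
A = ped.relationship_matrix(cands)
ebv = rng.normal(0, 1, len(cands))

print(f"{len(cands)} candidates; omega sweeps merit vs mean relationship:")
print(f"{'omega':>8} {'merit c-a':>10} {'c-A-c':>8} {'n used':>7}")
for omega in (0.0, 0.5, 2.0, 10.0, 100.0):
    c, matings = bs.ocs_select(ebv, A, omega=omega, n_matings=20)
    print(f"{omega:8.1f} {c @ ebv:10.3f} {c @ A @ c:8.3f} {(c > 1e-6).sum():7d}")
print("omega = 0 puts everything on the single best candidate; large omega")
print("spreads contributions to minimize average relationship, giving up merit.")
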