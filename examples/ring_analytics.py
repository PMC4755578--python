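"""Closed-form ring-model results and their numerical verification.

Builds the toy hypercolumn (M output neurons with cosine tuning on a ring),
evaluates the infomax objective for pure-cosine recurrent profiles of
increasing first-harmonic amplitude k1, and compares with the closed form
eps(k1) - eps(0) = 2 ln(1 - gamma0 k1 / 2).  The objective plunges toward
-infinity as k1 approaches the critical amplitude 2/gamma0 = 8: the optimal
network sits at the edge of the pattern-forming instability.
"""

import numpy as np

from infomaxnet import (
    analytic_objective_shift,
    build_ring,
    cosine_interaction,
    critical_k1,
    objective,
    optimal_ring_K,
)

M = 41
GAMMA0 = 0.25
params = build_ring(M)
x = np.array([[1e-4, 0.0]])          # near-zero contrast probe

eps0 = objective(params, x, tol=1e-12).epsilon
print(f"ring with M={M} neurons, logistic gain gamma0={GAMMA0}")
print(f"critical first-harmonic amplitude k1c = {critical_k1(GAMMA0):g}")
print(f"{'k1':>5} {'numeric shift':>14} {'closed form':>12}")
for k1 in [0.0, 2.0, 4.0, 6.0, 7.5]:
    eps = objective(params.with_K(cosine_interaction(M, k1)), x,
                    tol=1e-12).epsilon
    print(f"{k1:5.1f} {eps - eps0:14.6f} "
          f"{analytic_objective_shift(k1, GAMMA0):12.6f}")

K_opt = optimal_ring_K(M, GAMMA0)
print(f"\noptimal profile amplitude, M * max K = {M * K_opt[0].max():.3f}")
print("(a pure cosine: each neuron excites similar orientations and")
print(" inhibits opposite ones, poised exactly at the critical amplitude)")
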