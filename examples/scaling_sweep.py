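"""Criticality diagnostics as the learned interactions are rescaled.

Takes the analytically optimal ring interaction matrix and multiplies it by
a scale factor c.  Three metrics are tracked: the infomax objective (minimal
at the trained scale), the convergence time of the dynamics (diverging near
the critical scale — critical slowing down), and the population-vector
magnitude of the zero-input response (jumping from ~0 to large once the
network crosses into the attractor / "hallucination" regime).
"""

import numpy as np

from infomaxnet import RingSpec, build_ring, optimal_ring_K, sample_ring_inputs
from infomaxnet.metrics import scaling_sweep

M = 41
params = build_ring(M).with_K(optimal_ring_K(M, 0.25))
spec = RingSpec(M=M, mean_contrast=0.1)
inputs = sample_ring_inputs(spec, 50, seed=3)

scales = np.arange(0.5, 1.2001, 0.05)
res = scaling_sweep(params, scales, inputs, tol=1e-9, seed=3)

print(f"{'scale':>6} {'epsilon':>10} {'steps':>8} {'popvec':>10}")
for c, e, st, pv in zip(res.scales, res.epsilon, res.convergence_steps,
                        res.popvec_magnitude):
    print(f"{c:6.2f} {e:10.4f} {st:8.0f} {pv:10.4f}")
print(f"\nobjective minimized at scale {res.argmin_scale:.2f}")
print("(just inside the critical point: at finite contrast the optimum")
print(" sits slightly below the zero-contrast critical amplitude)")
print("convergence time peaks and the population vector switches on near")
print("scale 1: the optimum sits at the phase transition")
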