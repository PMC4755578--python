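"""Infomax learning in the ecological hypercolumn model.

Trains the recurrent interactions of a network whose feedforward filters
are Gabors (shared center and frequency, orientations spanning 0-180 deg)
driven by whitened patches of synthetic 1/f^2 textures.  The learned
interaction profile, plotted against preferred-orientation difference, has
a Mexican-hat shape: excitation between similar orientations, inhibition at
larger orientation differences.  A shortened run; the hat deepens with a
longer budget.
"""

import numpy as np

from infomaxnet import TrainingConfig, fourier_profile, train
from infomaxnet.images import build_texture_pipeline

pipe = build_texture_pipeline(seed=0)
config = TrainingConfig(eta0=0.01, batch_size=50, max_steps=200, seed=0)
state = train(pipe.params, pipe.code_sampler(), config)

M = pipe.params.M
prof = fourier_profile(state.params.K)
dpo = np.degrees(prof.offsets) / 2.0       # ring offset -> delta PO
wrap = np.minimum(dpo, 180.0 - dpo)        # orientation distance, 0..90

near = M * prof.profile[wrap < 15].mean()
far = M * prof.profile[(wrap >= 45) & (wrap <= 90)].mean()
print(f"trained {state.step} steps; objective "
      f"{state.objective_history[0][1]:.3f} -> "
      f"{state.objective_history[-1][2]:.3f} nats")
print(f"mean M*K at |dPO| < 15 deg : {near:+.3f}  (excitation)")
print(f"mean M*K at 45-90 deg      : {far:+.3f}  (inhibition)")
print("positive near / negative far = Mexican-hat lateral connectivity")
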