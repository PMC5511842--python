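"""Forward-model a regional TAC and fit the 1T2K compartment model.

Demonstrates parameter recovery from a noise-free curve, the exact delay
recovery on the 1 s grid, and the scale mechanism: shrinking a TAC by 20%
moves the fitted K1 by about -20% while leaving k2 nearly unchanged.
"""

import numpy as np

import petacbias as pb

inputs = pb.synth_input_functions()
schedule = pb.default_frame_schedule()
true = pb.KineticParams(K1=0.054, k2=0.077, Vb=0.05, delay_s=3.0)

tac = pb.model_tac(true, inputs, schedule)
fit = pb.fit_1t2k(tac, inputs, schedule)
p = fit.params
print(f"true:   K1={true.K1:.4f}  k2={true.k2:.4f}  VT={true.VT:.4f}  delay={true.delay_s:.0f}s")
print(f"fitted: K1={p.K1:.4f}  k2={p.k2:.4f}  VT={p.VT:.4f}  delay={p.delay_s:.0f}s")

scaled = pb.fit_1t2k(0.8 * tac, inputs, schedule).params
print(f"after x0.8 TAC scale: K1 shift {(scaled.K1 / p.K1 - 1) * 100:+.1f}%, "
      f"k2 shift {(scaled.k2 / p.k2 - 1) * 100:+.1f}%")
# A pure concentration-scale error (what a wrong attenuation map produces)
# is absorbed almost entirely by K1; the washout rate k2 barely moves.

rng = np.random.default_rng(0)
noisy = np.clip(tac * (1 + 0.05 * rng.standard_normal(tac.size)), 0, None)
pn = pb.fit_1t2k(noisy, inputs, schedule).params
print(f"5% frame noise:       K1={pn.K1:.4f}  k2={pn.k2:.4f}  VT={pn.VT:.4f}")
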