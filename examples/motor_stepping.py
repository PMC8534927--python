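"""Internal ATP kinetics of a single motor and its jump-length rates.

Builds one motor under high-load kinetics, simulates its attachment /
detachment chain, and compares the measured per-MCS jump-length frequencies
of a free (unobstructed) motor against the closed-form rates R1..R4.
"""

import numpy as np

from dynasep import (
    BoundaryRates, KineticsParams, LatticeConfig, MotorState, RunConfig,
    closed_form_rates, secondary_stationary_dist, update_internal_state, run,
)

kin = KineticsParams.high_load(Px=1.0, Py=0.0)
print(f"high-load kinetics: Patt={kin.Patt} Pdet={kin.Pdet} "
      f"Satt={kin.Satt} Sdet={kin.Sdet}")

# stationary law of the secondary (load) sites: Binomial(3, 0.8)
dist = secondary_stationary_dist(kin)
rng = np.random.default_rng(0)
state, counts = MotorState(), np.zeros(4)
for _ in range(50_000):
    state = update_internal_state(state, kin, rng)
    counts[state.s] += 1
print("\nP(s) analytic :", np.round(dist, 4))
print("P(s) simulated:", np.round(counts / counts.sum(), 4))

# free-motor jump-length rates: R_i = P(fueled) * P(s = 4 - i)
rates = closed_form_rates(kin)
cfg = RunConfig(lattice=LatticeConfig(Lx=5000, Ly=1), kinetics=kin,
                boundary=BoundaryRates(0, 0), periodic=True, n_init=1,
                warmup=500, sampling=200_000, n_blocks=1, seed=1)
res = run(cfg)
measured = res.hist_x[1:] / res.sampling
print("\njump length   :      1       2       3       4")
print("R_i closed    :", np.round(rates.as_array(), 4))
print("R_i measured  :", np.round(measured, 4))
print("\nA heavily loaded motor (s ~ 2.4 bound ATPs) mostly takes single "
      "steps;\nthe total hop rate sums to the fueled fraction "
      f"{rates.as_array().sum():.2f} per MCS.")
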