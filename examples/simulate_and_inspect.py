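"""Generate synthetic motor-imagery EEG and verify its ERD structure.

Builds a small two-class set (left/right-hand-like), epochs the imagery
window, and measures mu-band power at the class-1 ERD channel: trials of
class 1 should show roughly (1 - erd_depth)^2 = 0.16 of the power that
class-2 trials show there.
"""

import numpy as np
from scipy.signal import welch

from mibci import SyntheticConfig, simulate_trialset, epoch_trialset

cfg = SyntheticConfig(n_trials_per_class=40, seed=0)  # erd_depth 0.6 default
ts = epoch_trialset(simulate_trialset(cfg), (4.0, 6.0))
print(f"{len(ts)} trials, {ts.n_channels} channels x {ts.n_samples} samples "
      f"at {ts.sample_rate_hz:g} Hz, classes {ts.class_set}")


def mu_power(trial):
    f, p = welch(trial.data[0], fs=ts.sample_rate_hz, nperseg=256)
    return p[(f >= 8) & (f <= 12)].sum()


p1 = np.mean([mu_power(t) for t in ts.trials if t.label == 1])
p2 = np.mean([mu_power(t) for t in ts.trials if t.label == 2])
print(f"mu-band power at channel 0: class 1 = {p1:.3f}, class 2 = {p2:.3f}")
print(f"ratio = {p1 / p2:.3f}  (ERD depth 0.6 predicts (1-0.6)^2 = 0.16)")
# The ratio near 0.16 confirms the generator attenuates the class-1 rhythm
# during imagery exactly as configured.
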