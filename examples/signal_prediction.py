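"""Autoregressive EEG modeling with a regression-head GRU.

A recurrent network with a linear readout is trained for one-step-ahead
prediction on a narrowband oscillation, then run free (each output fed
back as the next input).  A model that has captured the signal's dynamics
keeps oscillating at the source frequency.
"""

import numpy as np
from scipy.signal import periodogram

from mibci.rnn import (
    RNNConfig, autoregressive_predict, init_model, make_signal_slices,
    train_signal,
)

rate = 250.0
t = np.arange(1000) / rate
signal = np.sin(2 * np.pi * 10 * t)[None, :]  # 10 Hz mu-like tone

cfg = RNNConfig(cell="gru", unroll_len=25, hidden_width=24, dropout_rate=0.0,
                head="regression", seed=0, max_iterations=60, batch_size=64,
                learning_rate=3e-3)
x, y = make_signal_slices(signal, tau=25, stride=2)
model = init_model(cfg, input_rows=1)
model, losses = train_signal(model, x, y, cfg)
print(f"one-step prediction MSE after {cfg.max_iterations} epochs: "
      f"{losses[-1]:.2e}")

pred = autoregressive_predict(model, signal[:, :250], n_steps=500)
f, p = periodogram(pred[0], fs=rate)
print(f"free-running continuation: spectral peak at {f[np.argmax(p)]:.1f} Hz "
      "(source was 10 Hz)")
# A peak at 10 Hz means the unrolled network carries the oscillation's
# phase dynamics in its hidden state rather than decaying to a fixed point.
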