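"""Choosing the unroll depth (the "optimal number of hidden layers").

The slice length fed to the recurrent network equals its unroll depth, so
picking the depth that maximizes validation accuracy also fixes the
cropping size.  Here a coarse grid is swept on a small synthetic set.
"""

from mibci import PipelineConfig, RNNConfig, SyntheticConfig, run_pipeline
from mibci import simulate_trialset, epoch_trialset

ts = epoch_trialset(
    simulate_trialset(SyntheticConfig(n_trials_per_class=20, seed=5)),
    (4.0, 6.0),
)
cfg = PipelineConfig(
    m=1, tau_grid=[10, 20, 40], train_stride=25, eval_stride=10, seed=0,
    rnn=RNNConfig(cell="gru", hidden_width=16, max_iterations=10,
                  dropout_rate=0.2),
)
result = run_pipeline(ts, cfg)
for tau, rec in sorted(result.sweep_records.items()):
    print(f"  tau = {tau:3d}: validation accuracy {rec['val_accuracy']:.1%}, "
          f"cross-entropy {rec['val_cross_entropy']:.3f}")
print(f"optimal unroll depth: {result.tau} "
      f"(ties, if any, resolve to the smaller depth)")
print(f"validation error with that depth: {result.error_pct:.1f}%")
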