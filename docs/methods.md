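# Methods

## Signal model and pipeline

Epoched trials are matrices X ∈ R^{N×T} (N channels, T samples, µV) with
one class label each. The pipeline estimates, per frequency band b of a
filter bank, the average spatial covariance of each class from
channel-centered, trace-normalized per-trial covariances

    C̄_c = mean over trials of class c of  X Xᵀ / trace(X Xᵀ),

and finds spatial filters maximizing the class-1/class-2 band-power ratio
wᵀC̄₁w / wᵀC̄₂w. The equivalent symmetric problem C̄₁w = λ(C̄₁+C̄₂)w is
solved with `scipy.linalg.eigh` on the definite pencil (C̄₁, C̄₁+C̄₂);
eigenvalues lie in [0,1], λ and 1−λ describing the two class views, and
the filters of the m largest and m smallest λ are retained (M = 2m per
set). For more than two classes, one-versus-rest sets contrast each class
covariance against the trial-count-weighted pool of the others, giving
bands × classes sets in band-major order. Projected series Z = w*X are
stacked across sets into a D×T feature series whose rows are named by
(band, OVR class, component).

The cropping step turns each feature series into its T−τ stride-1
contiguous windows of length τ, every slice inheriting the trial label; a
stride parameter thins this set when training cost matters. A recurrent
network with hidden width H is unrolled over the τ columns of a slice and
read out at the final step through a softmax layer; trial-level decisions
average the probability vectors of all crops of the trial and take the
argmax (ties to the lowest class index). The unroll depth is the network's
"depth" in time, so the depth sweep that maximizes validation accuracy
simultaneously fixes the cropping size.

## Recurrent cells and training

Three cells are implemented in numpy/float64 with hand-derived BPTT
gradients (verified against central finite differences to <1e−4 relative
in the suite): a vanilla tanh cell; an LSTM with input/forget/output gates
and peephole connections (input and forget gates see the previous cell
state, the output gate the current one); and a GRU with update/reset
gates, state update h_t = (1−z)⊙h_{t−1} + z⊙h̃_t. Two activation regimes
are selectable: `conventional_sigmoid` (sigmoid gates, tanh cell
input/output) is the default because bounded gates keep long unrolls
stable; `relu_gates` uses ReLU gate activations with a sigmoid LSTM
cell-output activation and tanh cell input. Both regimes are gradient-
checked and trainable; ReLU gates can diverge at aggressive learning
rates, which is why they are not the default.

Weights start i.i.d. N(0, 0.2²), biases at zero. Training is mini-batch
(64 slices) BPTT with Adam (lr 1e−3, decays 0.9/0.999, ε 1e−8) on
categorical cross-entropy averaged over the batch (log arguments clipped
at 1e−12); for two classes this is exactly the binary form. One iteration
is one shuffled pass over the training slices; exactly `max_iterations`
epochs run with no early stopping (default 200). Dropout (default rate
0.2) multiplies inverted-dropout masks onto the non-recurrent connections
only — the inputs at every step and the pre-readout hidden state — during
training. All shuffling and masking derive from the config seed, so runs
are bit-reproducible; hidden width (default 32) is a free hyperparameter.

A regression head (linear readout, mean-squared error) supports one-step-
ahead signal modeling; `autoregressive_predict` then free-runs the model
by feeding each prediction back as input. This mode backs the depth-
selection story: a model whose unroll spans the oscillation's time scale
keeps its spectral peak when run free.

## Smoothing

The optional causal smoother replaces each feature sample by the mean of
itself and the previous ω samples. The divisor is ω+1 (the number of
terms), shrinking near the left edge so constants are fixed points and
ω = 0 is the identity; a `literal_divisor` flag exposes the
dimensionally-inconsistent sum/ω variant for comparison only. Window
sizes are in samples.

## Synthetic ERD generator

Each simulated trial spans 7 s at 250 Hz following the cue protocol:
rest, cue at 2 s, imagery through 6 s. Rhythm sources are unit-variance
narrowband noise (order-4 zero-phase Butterworth on white noise — more
realistic than sinusoids and free of filter-bank ringing artifacts) in
the μ (8–12 Hz) or β (18–25 Hz) band, one per (channel, rhythm) pair
named in the class specification, riding on 1/f background noise
(spectrally shaped white noise, default σ 0.5 relative to rhythm
amplitude 1). During the imagery interval the sources named by the
trial's class are scaled by 1−erd_depth (default depth 0.6), so the
[4, 6] s epoch shows a band-power ratio of (1−depth)² ≈ 0.16 between
modulated and unmodulated classes at the target channel. The default
montage is three channels with μ ERD at channel 0 for class 1 and
channel 2 for class 2 (a C3/Cz/C4, left/right-hand configuration);
mixing matrices can spread sources across channels to emulate volume
conduction. Trials are generated from per-trial seed sequences, so sets
are bit-reproducible and balanced by construction.

What the generator does **not** emulate: artifacts (EOG/EMG),
non-stationary drift, inter-subject variability, realistic head-model
mixing, or trial-to-trial latency jitter. Passing recovery tests on this
data therefore demonstrates that the pipeline's machinery is correct and
sensitive to band-power modulation of realistic depth at realistic SNR —
not that competition-grade error rates transfer to real recordings.

## Evaluation protocol

Splits: when trials carry two or more session ids, session 1 trains and
the rest validate; otherwise a seeded stratified split (default 50/50).
Misclassification is 100·(#wrong/n); variance is the sample variance of
per-fold (or per-session) rates. Method pairs are compared with a
classical two-sided paired t-test on per-subject rates (n−1 df); if the
differences have zero variance the p-value is 1 for zero mean difference
and 0 otherwise. SVM baselines use scikit-learn SVC with C = 1,
`gamma="scale"`, degree 3, one-versus-rest — the unstated-hyperparameter
defaults are recorded in the report objects.

## Problem sizes and numerical choices

The suite and the acceptance script keep runs desk-sized by choice:
recovery runs use 100 trials/class, τ = 20, training stride 16 (≈30
slices/trial), H = 16, 30 epochs; evaluation crops at stride 4. The
convergence comparison uses 120 synthetic slices, H = 16, 60 epochs, five
seeds. Chance-level accuracy over 100 validation trials has a binomial
standard deviation of ≈5 points, so the null-recovery measurement
averages three independent replicates of the same conditions. Filter
order is 4 everywhere (configurable), the notch is a Q = 30 second-order
IIR at 50 Hz, all filtering is forward-backward, and covariance shrinkage
(1−γ)C + γ(tr C/N)I with γ = 1e−6 guards near-singular composites.
Eigenvector signs are fixed (largest-magnitude coefficient positive) for
deterministic outputs.

## Known limitations

Single recurrent layer only (depth is temporal unrolling, not stacked
cells); no GPU path — numpy matmuls bound throughput, so full-scale
200-epoch stride-1 training on full competition datasets is slow though
correct; GDF import depends on MNE's reader and maps only integer-coded
annotations to labels; smoothing/cropping assume equally-spaced samples;
the band division is fixed rather than subject-optimized.
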