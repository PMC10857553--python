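# Methods

## Problem and pipeline

`oxipredict` forecasts a patient's near-future oxygen saturation (SpO₂,
percent) from their own recent 1 Hz pulse-oximetry history. The pipeline has
five stages:

1. **Gap segmentation.** Pulse oximeters discard readings that fail the
   device's signal-quality check, leaving timestamp gaps. A trace is split
   into *continuous data arrays*: maximal runs in which consecutive
   timestamps differ by at most `max_gap` = 3 s. A difference of exactly 3 s
   is still continuous ("3 s at most"); anything larger starts a new run.
   No imputation is performed — gaps are structural.
2. **Windowing.** Within each run, supervised rows are enumerated by sliding
   a start position `i` (1-based): inputs are the `w` values at
   `i, i+s, …, i+s·(w−1)` and the target is the value at `i + s·w + f` —
   one further stride past the last input, plus the horizon `f` (data points;
   seconds at 1 Hz). A run of length `n` yields `max(0, n − s·w − f)` rows,
   so the final row's target lands exactly on the run's last element, and
   runs shorter than the window yield none. Two consequences are load-bearing
   and tested: the row count depends on the spec only through `s·w + f`
   (hence ⟨w20,s5,f20⟩ and ⟨w10,s10,f20⟩ always tie), and no row ever mixes
   samples from both sides of a gap. The optional second channel appends the
   heart-rate values at the same input indices; the target is always future
   SpO₂.
3. **Training protocol.** Rows are partitioned 70/15/15 into
   train/validation/test uniformly at random. Inputs are standardized
   column-wise by the training split's mean and standard deviation
   (zero-variance columns fall back to std 1 with a warning); the target
   stays in saturation units. Training minimizes MSE and stops when
   validation MSE has not improved for `early_stop_patience` epochs, then
   restores the best-epoch weights. The whole procedure is repeated
   (default 10×) with re-randomized partitions; the per-metric mean and
   standard deviation over repeats are reported and the lowest-fitness
   repeat's weights are retained.
4. **Fitness-ranked grid selection.** Every registered architecture of every
   learning algorithm is trained on every candidate `(w, s, f)` dataset
   (|A|·|D| cells). Cells are ranked by the composite fitness

   `fit = MaxAE/α + β·MSE + γ·MAPE + δ·MAE`,  lower better,

   with defaults `(α, β, γ, δ) = (5, 2.5, 1.67, 1.25)`. MaxAE is divided by
   its weight because a single worst-case error (often a quantization or
   sensor artifact of 15–30 points) is on a much coarser scale than the mean
   errors; MAPE is in percent. Strict `<` comparison means ties break to the
   earlier cell in iteration order (algorithms, then architectures, then
   datasets as listed). Per-algorithm winners are then **re-scored on their
   entire dataset** (not just the test split) and the overall minimum is
   deployed. Choosing the weights themselves is out of scope; they are
   plain configuration.
5. **Deployment and streaming.** The winner is exported as a directory
   bundle: `model.json` (architecture + weights as JSON arrays) and
   `config.json` (model id, algorithm, `w`, `s`, `f`, channels, input
   length, scaler mean/std) — everything needed to predict without the
   training environment. The streaming loop keeps a rolling buffer of the
   last `s·(w−1)+1` samples of the current continuous run, consumes every
   `s`-th value from the oldest end, and emits one forecast per incoming
   reading for the time `s+f` seconds after it; a gap > 3 s empties the
   buffer. Offline replay is prediction-for-prediction identical to the
   online loop.

## Models and numerical choices

Two families are registered: a fully connected network (reference
configuration 128/64/32 ReLU hidden layers, linear scalar output) and a
single-layer GRU (default 128 units, sized to match the fcnn's first layer)
reading the window as `w` timesteps × channels with a linear readout. Both
are implemented in a small numpy core written for this package — exact
analytic gradients (validated against central finite differences in the
test suite), Adam at its conventional settings, mini-batches of 32, and the
early stopping described above. Unstated training hyperparameters were
fixed once as: learning rate 1e-3, batch size 32, patience 10 epochs,
epoch cap 200, all exposed on `TrainingProtocol`. The output bias is
initialized at the training-target mean, so optimization starts from the
climatological constant predictor rather than from zero (saturations live
near 95, far from any sensible zero-centered initialization). All
randomness flows through `numpy.random.Generator` seeded from the protocol
seed via `SeedSequence`, making every split, initialization, and shuffle —
and therefore every reported metric — bit-reproducible.

Degenerate inputs are handled explicitly: constant input columns scale by
std 1; traces shorter than the buffer span emit no stream predictions;
empty traces yield empty segment lists and empty datasets; MAPE refuses
zero true values; duplicate timestamps are rejected rather than averaged.

## Synthetic vitals generator

Real traces from the original five-patient study are not deposited, so the
package ships a seedable simulator that emulates the features the pipeline
depends on: a 1 Hz grid around a patient baseline (default 95%),
activity-driven desaturation episodes as a Poisson process (default
6/hour) with linear onset (15 s) and exponential recovery (τ = 30 s) —
the lagged dynamics of blood-oxygen response — additive Gaussian sensor
noise (0.5%), integer quantization as consumer devices report, i.i.d.
per-sample dropout (default 5%) reproducing the signal-quality gaps, and a
heart rate that rises ~1.5 bpm per percent of desaturation. Cohorts are
hierarchically seeded (`SeedSequence.spawn`), so any member regenerates
identically in isolation; members differ in baseline, episode rate/depth
and recovery dynamics, which is what makes a model trained on one member
degrade on the others.

What the simulator does **not** capture: real circadian and
activity-schedule structure, burst (non-independent) dropout, sensor drift
and motion artifacts, oxygen-therapy dose changes, and disease
progression. Tests passing on synthetic data therefore establish that the
machinery is correct and that learnable structure is recovered — not that
any particular clinical error level would be achieved on real patients.

## Evaluation scales used by the tests

The published per-patient result tables are embedded (`oxipredict.refdata`)
and their fitness column is recomputed from the printed error metrics to
±0.05 (the printed inputs are rounded to two decimals). Experiments that
train networks run on deliberately small problems — simulated traces of
1–4 ks, hidden layers of 8–32 units, ≤ 60 epochs, 1–2 repeats — chosen so
the full suite completes in well under a minute while still exercising the
same code paths as a full-scale run; the defaults
(128/64/32, 10 repeats, 200-epoch cap) remain what `select_best` and the
CLI use unless overridden.

## Known limitations

- The GRU's hyperparameters are a single defensible default, not a search.
- The stream annotates each reading with the forecast it *triggered*; the
  forecast refers to `s+f` seconds later, so plotted comparisons must shift
  predictions right by `s+f` to align with realized values.
- `f` counts data points within a continuous run; across small internal
  gaps (≤ 3 s) the wall-clock horizon can exceed `f` seconds slightly.
- Whether the deployed model should be the best repeat or a refit on all
  rows is ambiguous; the best repeat is kept.
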