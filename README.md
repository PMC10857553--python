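# oxipredict

Personalized short-horizon forecasting of oxygen saturation (SpO₂) from
1 Hz pulse-oximetry streams, for patients on long-term oxygen therapy whose
saturation fluctuates with activity. The package implements the full
per-patient model-generation pipeline: gap-aware segmentation of raw
traces, sliding-window supervised dataset construction over a grid of
window shapes, repeat-training of small neural forecasters, composite
fitness ranking of every architecture/dataset combination, and export of
the winner as a self-contained bundle for streaming edge inference.

## The method in brief

Raw readings are split into continuous runs wherever consecutive
timestamps differ by more than 3 s (quality-rejected readings leave gaps).
Within a run, a supervised row takes `w` values at stride `s` as inputs and
the saturation `s·w + f` points after the window's start as target, so a
run of length `n` yields `max(0, n − s·w − f)` rows. Candidate datasets are
built for a grid of `(w, s, f)` shapes — by default
⟨w20,s10,f20⟩, ⟨w20,s10,f30⟩, ⟨w20,s10,f40⟩, ⟨w20,s5,f20⟩, ⟨w10,s10,f20⟩ —
and every registered model family (a 128/64/32 ReLU fully connected
network and a single-layer GRU) is trained on every dataset: random
70/15/15 train/validation/test splits, early stopping on validation MSE,
10 repeats with re-randomized partitions, mean metrics reported. Cells are
ranked by

    fit = MaxAE/α + β·MSE + γ·MAPE + δ·MAE        (lower is better)

with `(α, β, γ, δ) = (5, 2.5, 1.67, 1.25)`; per-family winners are
re-scored on their entire dataset and the overall best is exported as a
bundle (`model.json` + `config.json` with the window spec and input-scaling
mean/std). A streaming loop then emits one forecast per incoming reading
from a rolling buffer that never crosses a gap.

Because the original patient recordings are not publicly available, the
package includes a seedable simulator of ambulatory SpO₂/heart-rate traces
(desaturation episodes with lagged exponential recovery, sensor noise,
integer quantization, quality dropouts) on which the entire pipeline runs
end to end. See `docs/methods.md` for the model details and the
simulator's scope.

## Worked example

```bash
oxipredict simulate --out trace.csv --duration 1200 --seed 4
# wrote 1137 samples to trace.csv

oxipredict select --in trace.csv --out-dir bundle --report report.csv \
    --seed 2 --repeats 1 --max-epochs 5 --algorithms fcnn \
    --grid-file grid.json     # [{"w":5,"s":2,"f":5},{"w":8,"s":1,"f":4}]
# best: fcnn-128-64-32 on (w=8, s=1, f=4) full-dataset fitness 4.09 -> bundle

cat report.csv
# algorithm,arch,w,s,f,Data,MAE,MSE,MAPE,Max,Fit
# fcnn,fcnn-128-64-32,5,2,5,1122,0.57,0.68,0.61,3.51,4.14
# fcnn,fcnn-128-64-32,8,1,4,1125,0.54,0.64,0.57,2.93,3.82

oxipredict stream --bundle bundle --in trace.csv --out out.jsonl
# emitted 1130 predictions over 1137 samples -> out.jsonl
```

The report mirrors the per-patient evaluation tables: each row is one
grid cell with its dataset size (`Data`), mean test errors over the
training repeats (MAE and MaxAE in saturation points, MSE in squared
points, MAPE in percent) and the composite fitness (`Fit`). Here the
⟨w8,s1,f4⟩ dataset wins with a held-out MAE of 0.54 points — i.e. the
forecast 5 s ahead (one stride past the window plus `f`=4) is off by about
half a saturation point on average — and a full-dataset fitness of 4.09.
Each line of `out.jsonl` carries a reading's timestamp, SpO₂, heart rate,
and, once the buffer is full, the forecast emitted at that reading.

From Python, the same pipeline:

```python
from oxipredict import (SimConfig, simulate_trace, dataset_grid,
                        select_best, finalize, export_bundle)

trace = simulate_trace(SimConfig(duration=7200, seed=0))
datasets = dataset_grid(trace)              # the five default (w,s,f) shapes
result = select_best(datasets)              # fcnn + gru, 10 repeats per cell
best = finalize(result, datasets)           # re-score winners on full data
export_bundle(best.model, "bundle/")
```

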