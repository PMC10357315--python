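# gaitpipe

Contactless gait assessment from depth-camera skeleton streams, for
movement-analysis researchers and clinical-tool builders who need standard
spatiotemporal gait parameters (stride, cadence, swing/stance/double
support, …) without force plates or wearables.

A walk recorded at 30 Hz as nine lower-body joints (pelvis, hips, knees,
ankles, feet) in 3-D camera coordinates is processed in two stages:

1. **Frame classification.**  Every frame gets one of five gait states —
   standstill `S`, left swing `L`, double support `D`, right swing `R`,
   turnaround `T` — predicted from 32 spatiotemporal features by either an
   RBF-kernel SVM (single frames) or a bidirectional LSTM over 5-frame
   windows (implemented in numpy in this package).
2. **Segmentation, validation, parameters.**  State transitions yield 7
   gait semantics (`L_up`, `L_down`, `R_up`, `R_down`, `Turn_start`,
   `Turn_end`, `Gait_start`).  The *gait pair mechanism* (GPM) keeps only
   chains of 4 consecutive foot events in the legal cyclic order
   `L_up → L_down → R_up → R_down` outside turnarounds; 18 parameters are
   computed per validated gait cycle and averaged, e.g.

   - LeftStride = ‖ankle_L(L_down⁽ⁱ⁺¹⁾) − ankle_L(L_down⁽ⁱ⁾)‖,
   - LeftCadence = 120 / LeftCycle,
   - LeftSwing % = 100 · (T(L_down) − T(L_up)) / LeftCycle,
   - DoubleSupport % = 100 − LeftSwing % − RightSwing %.

A kinematic walking simulator with analytic ground truth, an ankle-speed
heuristic baseline, and the evaluation statistics (weighted
precision/recall/F1, tolerance-based event-localization accuracy,
parameter error summaries) round out the package.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
from gaitpipe import GaitSimConfig, simulate_gait, parameter_error
from gaitpipe.pipeline import run_pipeline_on_labels

seq, truth = simulate_gait(GaitSimConfig())        # 6 passes of 5 m, 30 Hz
params, cycles, events = run_pipeline_on_labels(seq, truth.labels)
print(f"LeftStride   {params.left_stride:.3f} m (true {truth.parameters.left_stride:.3f})")
print(f"LeftCadence  {params.left_cadence:.1f} steps/min")
print(f"DoubleSupport {params.double_support:.1f} %")
print(f"mean error   {parameter_error(params, truth.parameters).mean_error:.2f} %")
```

prints

```
LeftStride   1.020 m (true 1.020)
LeftCadence  124.9 steps/min
DoubleSupport 37.5 %
mean error   0.45 %
```

i.e. feeding the true labels through segmentation + GPM + parameter
calculation recovers the generator's analytic values to within frame
quantization (the residual 0.45 % is the 30 Hz event-timing grid).

The same chain is available from the shell:

```sh
gaitpipe simulate --out walk.csv --labels-out labels.txt --truth-out truth.json
gaitpipe params walk.csv --out params.json
gaitpipe benchmark --n-walks 30 --noise-sd 0.005 --seed 0
```

The benchmark simulates a noisy cohort, cross-validates both classifiers
(10 folds, whole walks per fold), runs the heuristic, and prints one row
per method; with 5 mm joint noise at seed 0:

```
method     mean err %  sd err %  seg acc  w-prec   w-rec    w-F1
heuristic        4.21      5.71    1.000      --      --      --
svm              3.05      4.69    0.998   0.966   0.965   0.965
bilstm           1.55      2.93    0.999   0.980   0.980   0.980
```

reproducing the expected ordering: the sequence model degrades least,
the single-frame SVM next, the single-feature heuristic most.

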