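# fmpools

Kinetic simulation and FM-dye destaining analysis of synaptic vesicle
reserve pools.

Presynaptic terminals hold vesicles in a readily releasable pool (RRP) and
one or more reserve pools, distinguished operationally by how quickly they
are mobilized during stimulation. Whether slowly mobilized reserves feed
the quickly mobilized ones in **series**, or the two feed independent
fast-releasing and reluctant RRP subdivisions in **parallel**, changes how
synapses filter spike-train information. FM-dye stain/destain experiments
discriminate the organizations: dye-loaded terminals are destained by field
stimulation while fluorescence F(t) is imaged at 0.25 Hz, and the
*fractional destaining* rate

    k = −(dF/dt) / F        [min⁻¹]

is constant in time for a single well-mixed pool (equivalently
F(t) = F(0)·e^(−kt)), but runs down when a quickly mobilized reserve
selectively empties. `fmpools` is for modelers and analysts who want that
entire workflow as a tested library: a mean-field simulator of parallel,
serial, and last-in/first-out (LIFO) pool organizations under arbitrary
stain/destain protocols, and the trace analysis used on the real data —
windowed k̂ estimation (OLS slope over a window divided by the fitted
start intensity), baseline QC (≤1.5 %/min) and correction, constrained
single-exponential fits (k ∈ [0, 0.3] min⁻¹) and weighted two-exponential
decompositions w·e^(−k_f t) + (1−w)·e^(−k_s t), runs-test residual
diagnostics with the 0.25 outlier rule, population summaries, and a
calibrated synthetic-data generator (traces and TIFF image stacks) so
every stage is testable without any data download.

## Worked example

```python
from fmpools import (calibrate, calibrated_normalized_trace,
                     fractional_destain, fold_decrease, fit_double_exp)

defaults = calibrate()          # solve rates from the interval targets
trace = calibrated_normalized_trace(defaults)   # noiseless F/F(0), 4 s frames
early = fractional_destain(trace, (0.0, 1.5))   # minutes 0-1.5 of 1 Hz
late = fractional_destain(trace, (21.0, 25.0))  # minutes 21-25
print(early.k_hat, late.k_hat, fold_decrease(early, late))
print(fit_double_exp(trace).w_fast)
```

prints

```
0.08699999999999924 0.03200000000000126 2.7187499999998694
0.3899999999999999
```

— fractional destaining falls from 0.087 min⁻¹ at the start of a 1 Hz
train to 0.032 min⁻¹ at its end (a 2.7-fold decrease, incompatible with a
single mixing pool), and the two-exponential decomposition attributes a
weight of 0.39 to the fast component. Simulating the two-color protocol on
the default parallel model (`run_experiment(default_parallel(),
"fig9_rg")`) gives a second-dye/first-dye destaining-rate ratio of 4.51:
the dye applied during 1 Hz stimulation labels the quickly mobilized
reserve and destains >4-fold faster than the dye left in the slowly
mobilized reserve, which is the parallel-organization signature.

The `examples/` scripts walk each capability (calibration and estimation,
simulation, topology discrimination, population analysis, image pipeline)
and print annotated numbers; `fmpools --help` exposes the same workflows as
a command line (`simulate`, `calibrate`, `analyze`, `discriminate`,
`make-fixtures`).

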