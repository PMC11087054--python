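"""Image-to-trace pipeline on a synthetic time-lapse of punctae.

Builds a small synthetic field of fluorescent punctae following calibrated
destaining traces, detects them on the mean image, extracts per-ROI traces,
and recovers the destaining statistics from the pixels alone.
"""

import numpy as np

from fmpools import (calibrate, calibrated_normalized_trace, detect_punctae,
                     extract_traces, fractional_destain, normalize_trace)
from fmpools.synthetic import (Fig2Timeline, ImageParams, gen_image_stack,
                               random_positions)

defaults = calibrate()
timeline = Fig2Timeline()
params = ImageParams(field_px=(96, 96), noise_sd=2.0)
rng = np.random.default_rng(8)

n = 12
trace = calibrated_normalized_trace(defaults, timeline=timeline,
                                    span_only=False)
positions = random_positions(params, n, rng)
stack = gen_image_stack(params, [trace] * n, positions, seed=8)
print(f"synthetic stack: {stack.shape[0]} frames of "
      f"{stack.shape[1]}x{stack.shape[2]} px, {n} punctae")

rois = detect_punctae(stack.mean(axis=0))
print(f"detected {len(rois)} punctae (blob detection on the mean image)")

raw = extract_traces(stack, rois, times=trace.times,
                     background=(0, 0, 12, 12))
ks = []
for r in raw:
    nt = normalize_trace(r, timeline.baseline_window_s(),
                         timeline.plateau_window_s())
    ks.append(fractional_destain(nt, (0.0, 1.5),
                                 timeline.onset_s / 60.0).k_hat)
print(f"early fractional destaining across extracted ROIs: "
      f"{np.mean(ks):.3f} +/- {np.std(ks):.3f} /min "
      "(pixel round trip of the 0.087 /min calibration)")
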