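"""Predict performance for conditions that were never tested.

Sweeps the memory delay (including its complete removal) and a target
separation of 135 degrees, and shows the model's predictions: accuracy
worsens monotonically as the delay grows, is best with no delay at all,
and RT at 135 degrees interpolates between the tested 90 and 180.
"""

import tempocat as tc

params = tc.AttractorParams()
pred = tc.predict_generalization(params, delays=(0.0, 1000.0, 3000.0),
                                 angles=(45, 90, 135, 180),
                                 n_per_interval=300, seed=0)

bi = pred["by_interval"]
inner = bi[(bi.interval_ms > 450.0) & (bi.interval_ms < 920.0)]
pooled = inner.groupby("delay_ms")["error_rate"].mean()
print("Pooled error over the hard (inner) intervals, by delay:")
print(pooled.round(3).to_string())

ba = pred["by_angle"]
print("\nCorrect-trial RT (ms) by delay and separation angle:")
print(ba.pivot(index="delay_ms", columns="angle_deg",
               values="rt_mean").round(1))
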