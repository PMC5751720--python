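"""Simulate a labeled sensor-array dataset and inspect its geometry.

Generates a small 4-class panel at 1 Hz, writes it to CSV, reads it back and
prints the shapes every downstream stage relies on.
"""

import numpy as np

import enoselearn as el

cfg = el.SynthConfig(n_classes=4, reps_per_class=10, n_sensors=5,
                     duration_s=120, rate_hz=1.0, t_inject=10, t_peak=40,
                     tau_rise=8, tau_decay=60, seed=0)
dataset = el.generate_dataset(cfg)
el.write_sample_set(dataset, "scratch_dataset.csv")
back = el.read_sample_set("scratch_dataset.csv")

x = el.flatten_sample(back.samples[0])
print(f"samples: {len(back)}  classes: {back.class_names}")
print(f"panel: {back.panel}")
print(f"flattened input vector: {x.size} values "
      f"({len(back.panel)} sensors x {len(back.samples[0].curves[0])} points)")
peak = back.samples[0].curves[0].values.max()
print(f"first curve peaks at {peak:.3f} (baseline {cfg.baseline_level}); the "
      "peak height is the class fingerprint the classifiers must learn")

# the full-rate path: 364 s at 100 Hz decimated to the 1 Hz analysis rate
full = el.simulate_curve(2.0, el.SynthConfig(seed=0), np.random.default_rng(0))
print(f"full-rate curve: {len(full)} points -> "
      f"{len(el.downsample(full, 1.0))} points after 100 Hz -> 1 Hz decimation")
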