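"""The full developmental schedule, then tracking in darkness.

Trains the deliberately miscalibrated network through the two-stage
warm-up schedule (drift removal first, then all calibrations with
per-block landmark association), audits bump drift before and after, and
finally evaluates tracking with no landmarks at all -- the darkness test:
a well-calibrated compass holds its heading estimate for minutes on
vestibular input alone.
"""

import json

from hdcompass import ExperimentConfig, run_darkness_eval, run_full_training

cfg = ExperimentConfig.desk(seed=1, vestibular_bias=0.08,
                            vestibular_noise=5.0, miss_probability=0.3,
                            alpha_stability=3e-5, stage_duration=600.0)

bundle = run_full_training(cfg)
print("pre-training drift  (deg/s):",
      bundle.logs["audit_pre"].drift_deg_s.round(1).tolist())
print("post-training drift (deg/s):",
      bundle.logs["audit_post"].drift_deg_s.round(1).tolist())
print("scalars:", json.dumps(bundle.scalars, indent=1))

dark = run_darkness_eval(cfg, bundle.trained_net, bundle.calibration)
print("darkness:", json.dumps(dark.scalars, indent=1))
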