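"""Generate a synthetic peri-saccadic LFP session and detect the saccades.

Builds a 12-direction session (7-deg outside-in saccades, 1 kHz LFP with a
direction-tuned dip/peak/dip template in 1/f noise), then re-detects each
trial's saccade from the eye traces with the 3-SD velocity criterion and
compares against the generator's ground truth.
"""

import numpy as np

from perisacc import SynthConfig, gen_trialset
from perisacc.pipeline import detect_events

cfg = SynthConfig(trials_per_direction=10, n_channels=4, snr=2.0, seed=42)
ts, truth = gen_trialset(cfg)
print(f"session: {ts.n_trials} trials, {ts.n_channels} channels, "
      f"{ts.n_time} samples at {ts.sample_rate:.0f} Hz")
print(f"directions: {ts.directions().astype(int).tolist()} deg")

det = detect_events(ts)
end_err = det["end_ms"].to_numpy() - truth.events["end_ms"].to_numpy()
onset_err = det["onset_ms"].to_numpy() - truth.events["onset_ms"].to_numpy()
print(f"saccade end (fixation onset) error: "
      f"RMS {np.sqrt(np.mean(end_err ** 2)):.2f} ms, "
      f"max |err| {np.max(np.abs(end_err)):.0f} ms")
print(f"saccade onset error: RMS {np.sqrt(np.mean(onset_err ** 2)):.2f} ms")
# sub-2-ms end errors mean every downstream window is aligned to the true
# fixation onset at the resolution of the 1 kHz sampling
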