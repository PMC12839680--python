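"""Round-trip a three-state activity pattern through a noisy continuous signal.

Generates planted ROI state sequences, emits a continuous signal
(state x amplitude + Gaussian noise), then z-scores and thresholds it back
into states.  The recovery accuracy shows how well event calling survives
measurement noise at a given threshold.
"""

import numpy as np

from templex import discretize, gen_bold_from_states, gen_state_series, zscore

states = gen_state_series(n_roi=8, n_time=2000, marginals=(0.3, 0.3), seed=7)
for noise_sd in (0.0, 0.1, 0.5, 1.0):
    signal = gen_bold_from_states(states, amplitude=1.0, noise_sd=noise_sd, seed=1)
    recovered = discretize(zscore(signal), threshold=0.5).states
    acc = (recovered == states).mean()
    print(f"noise SD {noise_sd:>4.1f}: state recovery accuracy {acc:.3f}")

print()
print("At zero noise the thresholding recovers the planted states exactly;")
print("accuracy decays toward the chance level of the marginal state")
print("frequencies as the noise drowns the +-1 amplitude separation.")
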