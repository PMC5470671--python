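"""Simulate a cued-movement EEG recording and reduce it to induced power.

Builds one synthetic subject (32-channel montage, five coupled motor
sources), runs the preprocessing chain — band-pass 4-48 Hz, artifact
rejection at 500 uV, projection through the lead-field pseudoinverse,
7-cycle Morlet transform, trial averaging with percent-change baseline
correction — and checks the measured band power against the generating
envelope.
"""

import numpy as np

from motornet import (
    SimulationConfig,
    average_and_baseline,
    bandpass_epochs,
    build_model_space,
    generate_cohort,
    morlet_power,
    project_to_sources,
    reject_artifacts,
    simulate_eeg_trials,
    simulate_induced_power,
)

FREQS = np.array([6.0, 11.0, 22.0, 39.0])  # one bin per band, demo scale

cfg = SimulationConfig(frequencies=FREQS, sample_rate=500.0, n_trials=12,
                       noise_sd=0.5, seed=7)
model = build_model_space(nonlinear_pairs=(("beta", "theta"), ("theta", "beta")))[0]
clinical, truth = generate_cohort(1, 1, cfg, model=model)

epochs = simulate_eeg_trials(truth, cfg, subject=0)
print(f"simulated epochs: {epochs.data.shape[0]} channels x "
      f"{epochs.data.shape[1]} samples x {epochs.n_trials} trials")

epochs = bandpass_epochs(epochs, 4.0, 48.0)
epochs, rejected = reject_artifacts(epochs, 500.0)
print(f"artifact rejection: {len(rejected)} trials dropped, {epochs.n_trials} kept")

series = project_to_sources(epochs, truth.lead_field)
power = morlet_power(series, cfg.sample_rate, FREQS, wavelet_number=7)
spec = average_and_baseline(power, epochs.times_ms, FREQS,
                            list(truth.coupling[0].source_labels))
print(f"induced power: {spec.power.shape[0]} sources x "
      f"{spec.power.shape[1]} frequencies x {spec.power.shape[2]} time points, "
      f"range {spec.power.min():.1f}% to {spec.power.max():.1f}% of baseline")

# compare the measured spectrogram with the generating coupling model
pred = simulate_induced_power(model, truth.coupling[0], times_ms=spec.times_ms)
r = np.corrcoef(spec.power.ravel(), pred.power.ravel())[0, 1]
print(f"correlation with the generating envelope: {r:.3f}")
print("(values near 1 mean the chain faithfully recovers the induced-power"
      " dynamics that generated the oscillations)")
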