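"""Compare candidate network architectures at the group level.

Simulates three subjects whose induced responses come from the full
nonlinear (cross-frequency) architecture, inverts both that model and
the all-linear control for each subject, and compares them with
fixed-effects (summed evidence) and random-effects (Dirichlet exceedance
probability) Bayesian model selection.
"""

import numpy as np

from motornet import (
    InversionOptions,
    SimulationConfig,
    best_model_counts,
    build_model_space,
    ffx_compare,
    generate_cohort,
    invert,
    rfx_compare,
    simulate_induced_power,
)
from motornet.preprocess import SourceSpectrogram

FREQS = np.array([6.0, 11.0, 22.0, 39.0])
NL4 = (("beta", "theta"), ("theta", "beta"), ("beta", "gamma"), ("gamma", "beta"))

space = build_model_space(nonlinear_pairs=NL4)
dcm1, linear = space[0], space[-1]
print(f"model space: {[m.name for m in space]}")

cfg = SimulationConfig(frequencies=FREQS, sample_rate=250.0, n_trials=1, seed=300)
_, truth = generate_cohort(2, 1, cfg, model=dcm1)   # data from the nonlinear model

times = np.arange(-500.0, 801.0, 25.0)
rng = np.random.default_rng(0)
opts = InversionOptions(max_iter=64)
F = np.zeros((3, 2))
for i in range(3):
    spec = simulate_induced_power(dcm1, truth.coupling[i], times_ms=times)
    noisy = SourceSpectrogram(
        power=spec.power + 1.0 * rng.standard_normal(spec.power.shape),
        frequencies=FREQS, times_ms=times, source_labels=spec.source_labels,
    )
    F[i, 0] = invert(dcm1, noisy, options=opts).free_energy
    F[i, 1] = invert(linear, noisy, options=opts).free_energy
    print(f"subject {i}: F(nonlinear) - F(linear) = {F[i, 0] - F[i, 1]:+.1f} nats")

ffx = ffx_compare(F)
rfx = rfx_compare(F, seed=1)
counts = best_model_counts(F)
print(f"FFX posterior [nonlinear, linear]: {np.round(ffx, 3)}")
print(f"RFX exceedance probabilities:      {np.round(rfx.exceedance_prob, 3)}")
print(f"per-subject best-model counts:     {list(counts)}")
print("(positive evidence differences and an exceedance probability near 1 for"
      " the nonlinear model mean the cross-frequency couplings in the data are"
      " detectable against the extra-parameter penalty)")
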