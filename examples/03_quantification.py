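"""Light/heavy dimethyl quantification with unanimous-vote screening.

Simulates an equal-mix experiment — 200 light/heavy peptide pairs whose
true abundance ratio is 1 (log ratio 0), 40 of which are distorted noise
pairs engineered to pass the conventional idotP >= 0.9, |mass error| <= 6
ppm filter — trains an ensemble, and compares the log-ratio statistics of
the pairs each selection strategy keeps.
"""

from peakvote import (
    RunConfig,
    load_packaged_training_table,
    run_evaluation,
    run_quantification,
    simulate_quant_experiment,
)

config = RunConfig(seed=3, test_counts={"peptide": 161, "noise": 158})
model = run_evaluation(load_packaged_training_table(), config).model

groups = simulate_quant_experiment(
    200, true_log_ratio=0.0, noise_sd=0.2, seed=4,
    n_distorted=40, distortion_sd=2.0,
)
result = run_quantification(groups, model, config)

print(result.summary.to_string(index=False))
print(
    "\nAll 200 pairs pass the conventional filter by construction, but the"
    "\ndistorted ones are voted down by the ensemble: the 'conventional_only'"
    "\nset carries a biased mean log2 ratio with a large spread, while pairs"
    "\nin 'both' (accepted unanimously as well) centre on the true value 0"
    "\nwith a small spread — cleaner peaks give cleaner ratios."
)
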