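"""Parameter recovery on synthetic study tables.

Generates replicate tables at the real study's size (27 animals, ~10%
missing cells) with three CI-tracking biomarkers and three pure-noise ones,
runs the full screen -> signal-average pipeline on each, and summarises how
well the known generative slopes are recovered and how often noise slips
through the gate.
"""

from cystindex import SyntheticConfig, recovery_experiment

config = SyntheticConfig(seed=7)
report = recovery_experiment(config, replicates=100)
print(report.to_text())

print(
    "\nSignal biomarkers should show gate_pass_rate near 1 and slope_bias "
    "within Monte-Carlo error of 0 (against the attenuation-corrected "
    "expected_slope); null biomarkers should essentially never pass the "
    "r >= 0.7 gate at n = 27."
)
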