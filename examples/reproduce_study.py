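"""Derive the composite cystic-index formula from the packaged PCK-rat table.

Screens all 13 variables against histological CI, keeps the serum/urine
biomarkers passing the correlation gate, and signal-averages their univariate
linear equations into the composite calculator.
"""

from cystindex import fit_quality, reproduce

bundle = reproduce()

print("Correlation screen (one row per variable):")
cols = ["variable", "fluid", "n", "r_linear", "r_best", "best_family", "passed"]
print(bundle.correlations[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nUnivariate CI equations retained (serum/urine biomarkers only):")
for text in bundle.equation_texts:
    print(" ", text)

print("\nComposite formula (equal-weight signal average):")
print(" ", bundle.formula_text)

quality = fit_quality(bundle.predictions)
print(
    f"\nPredicted vs observed CI on the {quality['n']:.0f} animals with a "
    f"complete panel: RMSE {quality['rmse']:.2f} %CI, Pearson r {quality['pearson_r']:.2f}."
)
print("Each retained biomarker tracks CI on its own; averaging the three "
      "equations trades their independent errors against each other.")
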