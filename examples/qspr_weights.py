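"""Derive criterion weights from property-index correlations.

Builds a synthetic panel of 24 random molecule-like graphs with a property
constructed to correlate 0.7 with the first Zagreb index, fits each index
against the property, and turns the correlations into ratio weights with a
beneficial/non-beneficial split.
"""

from toporank.qspr import classify_criteria, fit_indices, ratio_weights
from toporank.synthetic import SyntheticConfig, synthetic_panel

table, prop = synthetic_panel(SyntheticConfig(n_molecules=24, seed=2))
fits = fit_indices(prop, table)
print("correlation and regression SE per index:")
print(fits.round(4).to_string())

weights = ratio_weights({k: float(v) for k, v in fits["r"].items()})
orientation = classify_criteria(weights, threshold=0.11)
print("\nratio weights w_i = r_i / sum(r) and orientation (threshold 0.11):")
for name, w in weights.items():
    print(f"  {name:>4}: w = {w:.4f}  {orientation[name]}")
print(f"\nweights sum to {sum(weights.values()):.12f}")

# Weights are the correlations rescaled to sum to 1; criteria whose weight
# exceeds the threshold are treated as 'more is better' in the ranking
# stage, the rest as 'less is better'.
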