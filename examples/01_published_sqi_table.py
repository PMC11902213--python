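"""Score the packaged published membership/weight table.

Loads the fuzzy-membership values and factor-analysis weights of the
two-species sewage-sludge-biochar pot experiment and computes the soil
quality index SQI(t) = Σ_i Q_i(t)·S_i for every treatment, with its
five-class quality level. S1–S5 are biochar doses 0, 1, 3, 6, 9 % (w/w).
"""

from rhizoq import compute_sqi, table4_fixture

for species in ("ryegrass", "cosmos"):
    memberships, weights = table4_fixture(species)
    result = compute_sqi(memberships, weights)
    print(f"\n=== {species} ===")
    print(result.to_frame().to_string(float_format="%.4f"))
    best = result.scores.idxmax()
    print(f"best treatment: {best} (SQI {result.scores[best]:.4f})")

print(
    "\nLevels: I >= 0.85 extremely high, II >= 0.70 high, III >= 0.55 "
    "medium,\nIV >= 0.40 low, V < 0.40 very low. Higher SQI = better "
    "weighted desirability\nof the eight soil indicators."
)
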