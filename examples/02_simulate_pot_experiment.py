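"""Generate a synthetic pot experiment and evaluate its soil quality.

The generator reproduces the experimental design (2 plant species × biochar
doses 0/1/3/6/9 % w/w × 3 replicates): dose-responsive soil indicators with
replicate noise, and Dirichlet-multinomial taxon counts whose composition
shifts with dose. Soil quality is then scored per species from the
replicate-level table: min-max memberships of treatment means, weighted by
PCA communality shares.
"""

from rhizoq import (
    SyntheticConfig,
    evaluate_soil_quality,
    generate_experiment,
    kmo_bartlett,
)

indicators, counts, taxonomy, truth = generate_experiment(SyntheticConfig(seed=7))
print(f"samples: {len(indicators.sample_ids)}, "
      f"indicators: {len(indicators.indicators)}, "
      f"taxa: {len(counts.taxon_ids)}")
print(indicators.data.head(3).to_string(float_format="%.2f"))

for species in ("P1", "P2"):
    sub = indicators.subset(indicators.data["species"] == species)
    kmo, chi2, p = kmo_bartlett(sub)
    result = evaluate_soil_quality(sub)
    print(f"\n--- species {species} "
          f"(KMO {kmo:.3f}, Bartlett chi2 {chi2:.1f}, p {p:.2e}) ---")
    print(result.to_frame().to_string(float_format="%.4f"))

print(
    "\nDose-level treatments are scored like the published table: the "
    "unamended\ncontrol scores lowest and mid/high doses reach the "
    "medium-quality class,\nreflecting the hump-shaped nutrient and enzyme "
    "responses built into the generator."
)
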