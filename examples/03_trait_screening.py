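"""Quantify plant-growth-promotion traits (PGPT) from colorimetric readings.

Simulates Salkowski (IAA), Mo–Sb (phosphate), DPPH and CAS-siderophore
readings with their standard series, inverse-predicts concentrations through
fitted curves, counts abilities per strain, and compares counts between the
triterpenoid growth classes.
"""

import endosyncom as es

catalog = es.default_catalog()
truth = es.reference_profile_truth(catalog, seed=7)
samples, standards = es.simulate_trait_assays(catalog, truth, noise_sd=0.02, seed=7)

curve = es.fit_standard_curve(
    standards[standards["assay"] == "iaa"], assay="iaa", wavelength_nm=535
)
print(
    f"IAA standard curve: A535 = {curve.slope:.4f} x [IAA mg/L] + "
    f"{curve.intercept:.3f} (R^2 = {curve.r_squared:.4f})"
)

profiles = es.quantify_traits(samples, standards)
scored = es.score_pgpt(profiles)
print("\nFirst strains:")
print(scored.head(5).round(2).to_string())

dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.05, seed=7)
classification, _ = es.classify_panel(dose, catalog)
result = es.compare_pgpt_by_class(scored, classification)
print("\nAbility counts by class:")
print(result["summary"].round(2).to_string(index=False))
for kingdom in ("bacteria", "fungi"):
    cmp = result[kingdom]
    print(f"  {kingdom}: promoted vs inhibited, p = {cmp.p_value:.3g} ({cmp.stars})")

print(
    "\npgpt_count tallies how many of the four traits (IAA, siderophore,\n"
    "DPPH > 50%, phosphate solubilization) a strain shows above its\n"
    "detection cutoff; promoted strains typically carry more abilities."
)
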