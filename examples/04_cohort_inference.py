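"""Cohort-level inference on a simulated case-control study.

Simulates one cohort of 30 elite skiers and 38 controls under the default
study parameterization, then runs the inference layer: best-subset linear
models (adjusted R^2 criterion), the univariate group comparison, and the
regional-pattern delta tests.
"""

from tendonswe import (analyze_cohort, reference_cohort_params,
                       simulate_cohort)

cohort = simulate_cohort(reference_cohort_params(), seed=1)
gm = cohort.groupby("group")[["swv_overall", "swv_mid"]].mean()
print("group means (m/s):")
print(gm.round(2))

fits = analyze_cohort(cohort, criterion="adjusted_r2")
print("\nbest-subset model, overall region:")
sel = fits["population"]["overall"]
print(f"  selected predictors: {sel['selected']}")
for row in sel["coefficients"]:
    print(f"  {row['predictor']:>13}: {row['estimate']:+.3f} m/s "
          f"(SE {row['std_error']:.3f}, p {row['p_value']:.3g})")

tt = fits["group_t_tests"]["overall"]
print(f"\nWelch t test, overall: diff {tt['mean_difference']:.2f} m/s, "
      f"p = {tt['p_value']:.2g}")
for name, d in fits["regional_deltas"].items():
    print(f"delta {name}: skier {d['mean_skier']:+.2f} vs control "
          f"{d['mean_control']:+.2f} m/s, p = {d['p_value']:.3g}")
# One cohort of n=68 is noisy: the selected subset varies from seed to seed
# and the expected skier excess in the distal-minus-mid delta (~0.24 m/s
# against a ~2 m/s per-subject delta SD) is usually not significant in a
# single draw — only the Monte-Carlo recovery runs (see the acceptance
# script) pin the generating coefficients down.
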