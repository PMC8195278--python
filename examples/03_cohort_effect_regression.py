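"""The pre-harmonization cohort effect and its regression validation.

Renders GA/PMA-matched cohorts (30 per cohort), segments them with the
intensity-window reference segmenter, and fits
``CT ~ cohort + PMA + GA + sex``.  Under the default calibration the cohort
coefficient recovers the rendered 0.2 mm acquisition bias, while the same
model on ground-truth labels shows no cohort effect.  Takes a few minutes.
"""

from neoharm.pipeline import cohort_effect_run

res = cohort_effect_run(n_per_cohort=30, seed=5)

print("cohort-effect report (per measure and condition):")
print(res.report[["condition", "measure", "cohort_beta", "cohort_p",
                  "significant"]].round(4).to_string(index=False))
print()
ct = res.ct_fits["naive"]
print(f"naive CT model: cohort beta = {ct['coef']['cohort']:.3f} mm "
      f"(p = {ct['pvalue']['cohort']:.2e}), "
      f"PMA beta = {ct['coef']['pma_weeks']:.3f} mm/week")
t = res.t_test
print(f"group means: source {t['mean_a']:.2f} mm (SD {t['sd_a']:.2f}), "
      f"target {t['mean_b']:.2f} mm (SD {t['sd_b']:.2f}); "
      f"t({t['df']}) = {abs(t['t']):.2f}")
print()
print("The cohort coefficient on naive measurements recovers the rendered "
      "0.2 mm boundary bias; the truth condition shows no cohort effect.")
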