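"""Generate a small matched two-cohort phantom and inspect its ground truth.

The phantom draws two cohorts from the same anatomy law (so any systematic
measurement difference is acquisition-induced by construction), renders each
subject in its own cohort's acquisition domain, and records true tissue
volumes and cortical thickness per subject.
"""

from neoharm.phantom import PhantomParams, generate_matched_dataset

params = PhantomParams()  # 64^3 at 0.75 mm, the package's default calibration
ds = generate_matched_dataset(n_per_cohort=5, params=params, seed=7)

print(ds.truth[["id", "cohort", "ga_weeks", "pma_weeks",
                "true_thickness_mm"]].round(2).to_string(index=False))
print()
by_cohort = ds.truth.groupby("cohort")["true_thickness_mm"].agg(["mean", "std"])
print(by_cohort.round(3))
print()
print("The two cohorts share one thickness law (difference is sampling "
      "noise); the rendered images, however, differ by contrast, blur and "
      "the target domain's 0.2 mm apparent boundary shift.")
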