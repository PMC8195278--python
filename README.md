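# neoharm

Adversarial domain adaptation for harmonizing neonatal brain MRI tissue
segmentation — with a synthetic two-cohort phantom and a regression-based
validation of the harmonization.

## The problem

Pooling MRI cohorts acquired with different scanners and protocols is the
standard way to gain statistical power, but acquisition differences leak
into derived measures: the same anatomy segments differently, and derived
quantities such as cortical thickness (CT) pick up a *cohort effect* that
has nothing to do with biology. For neonatal studies this is acute — a
term-born reference cohort and a preterm clinical cohort are typically
scanned years apart on different hardware. Analyses that pool them without
harmonization can manufacture spurious brain–behaviour associations.

`neoharm` implements and validates three segmentation strategies for a
labeled *source* domain and an unlabeled *target* domain:

1. **baseline** — a supervised 3D U-Net trained on the source domain,
   minimizing the generalized Dice loss
   `L = 1 − 2 Σ_l w_l Σ_n p_ln t_ln / Σ_l w_l Σ_n (p_ln + t_ln)` with
   `w_l = 1/(Σ_n t_ln)²`;
2. **latent-space adaptation** — the segmenter's decoder features feed a
   PatchGAN domain classifier; the segmenter minimizes `L_seg − α·L_adv`
   (α ramping 0 → 0.05 over epochs 20–50), pushing its features toward
   domain-invariance;
3. **image-space adaptation** — a generator U-Net translates source
   volumes into target-like volumes (LSGAN objective, normalized
   cross-correlation constraint `λ(1 − NCC)`), and the segmenter trains on
   real source plus synthesized volumes: `L_seg + L_adv + λ(1 − NCC)`.

Because the real cohorts of interest are access-controlled, validation
runs on a **synthetic two-cohort phantom** with known ground truth: nested
tissue shells with an exactly realized cortical-thickness law
(`T = 1.73 + 0.04·ΔPMA + 0.06·ΔGA − 0.001·ΔPMA·ΔGA + ε` mm), two cohorts
with different gestational-age distributions, and a rendered acquisition
difference whose key confound is a 0.2 mm outward shift of the *apparent*
cGM/CSF boundary in the target domain. Downstream, the package measures
tissue volumes, Laplace-equation cortical thickness, and fits the
validation models `measure ~ cohort + PMA + GA + sex` on GA/PMA-matched
cohorts: harmonization succeeds when the cohort term stops being
significant. The networks run on a small numpy autograd backend included
in the package, so everything trains and tests on one CPU.

See `docs/methods.md` for the full model and calibration account.

## Worked example

```python
from neoharm.pipeline import cohort_effect_run

res = cohort_effect_run(n_per_cohort=30, seed=1)
fit = res.ct_fits["naive"]
print(f"source mean CT {res.source_mean_ct_mm:.3f} mm, "
      f"target mean CT {res.target_mean_ct_mm:.3f} mm")
print(f"cohort beta {fit['coef']['cohort']:.3f} mm "
      f"(p = {fit['pvalue']['cohort']:.1e})")
```

prints

```
source mean CT 1.783 mm, target mean CT 2.015 mm
cohort beta 0.222 mm (p = 9.5e-17)
```

Both cohorts share one anatomy law (true mean thickness 1.73 mm at the
matched reference ages), yet the intensity-based measurement of the
target-domain renderings comes out ~0.2 mm thicker — the acquisition-
induced cohort effect, recovered by the regression. On ground-truth labels
(`res.ct_fits["truth"]`) the same model shows no cohort effect. The
`examples/` directory walks through each capability: phantom generation,
thickness measurement, the cohort-effect regression, training the
domain-adaptation models, and the spurious-outcome demonstration.

A thin CLI wraps the same pipeline
(`neoharm simulate | train | predict | measure | report | e2e`); every
output directory receives its effective YAML config and seed.

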