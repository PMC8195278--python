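"""Train the image-space domain-adaptation model at desk scale.

Trains the supervised baseline and the image-space adversarial model
(generator + segmenter + PatchGAN discriminator, NCC-constrained) on small
rendered cohorts, then compares target-domain Dice and the cohort effect on
measured cortical thickness before and after harmonization.  This is the
full pipeline; expect ~15 minutes on one CPU.
"""

from neoharm.pipeline import train_e2e_models, validation_replicate

models = train_e2e_models(seed=0, epochs=30)
hist = models.history_image_da.to_dataframe()
print("image-space DA training tail:")
print(hist[["epoch", "seg_loss", "adv_loss", "ncc",
            "val_dice_target"]].tail(5).round(3).to_string(index=False))

rep = validation_replicate(models, seed=1)
print()
print(f"target-domain mean Dice: baseline {rep['dice_target_baseline']:.3f}"
      f" -> image-space DA {rep['dice_target_image_da']:.3f}")
print(f"cohort effect on measured CT: naive beta "
      f"{rep['naive_cohort_beta']:.3f} (p={rep['naive_cohort_p']:.2e}) "
      f"-> harmonized beta {rep['da_cohort_beta']:.3f} "
      f"(p={rep['da_cohort_p']:.3f})")
print()
print("Harmonization succeeds when the naive cohort effect is significant "
      "and the DA-segmented one is not.")
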