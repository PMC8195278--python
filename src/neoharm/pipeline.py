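"""End-to-end experiment drivers.

These functions chain the phantom generator, the measurement operators and
the regression validation into the named experiments the package exists
for:

* `cohort_effect_run` — the pre-harmonization validation: render matched
  cohorts in their own domains, segment with the intensity-window reference
  segmenter, measure volumes and cortical thickness, and fit the
  ``measure ~ cohort + PMA + GA + sex`` models against the ground-truth
  condition.
* `desk_params` / `desk_specs` — the reduced problem size used for network
  training experiments (48^3 voxels at 0.9 mm with width-shrunken nets).
* `e2e_replicate` — one seeded end-to-end domain-adaptation replicate:
  train the baseline and the image-space DA model, compare target-domain
  Dice, and test whether the cohort effect on measured cortical thickness
  survives harmonized segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measure import (
    NaiveSegmentConfig,
    cortical_thickness,
    naive_segment,
    tissue_volumes,
)
from .nets import DiscSpec, UNetSpec
from .phantom import (
    CLASS_NAMES,
    PhantomParams,
    PhantomDataset,
    TissueLabelMap,
    build_anatomy,
    generate_matched_dataset,
    render_image,
    _sample_matched_meta,
)
from .stats import fit_lm, harmonization_report, two_sample_t
from .train import (
    Subject,
    TrainPlan,
    dice_scores,
    guard_targets,
    predict,
    train_baseline,
    train_image_da,
)

__all__ = [
    "measurement_table",
    "cohort_effect_run",
    "CohortEffectResult",
    "desk_params",
    "desk_specs",
    "TrainedModels",
    "train_e2e_models",
    "validation_replicate",
]


def measurement_table(dataset: PhantomDataset,
                      label_maps: list[TissueLabelMap]) -> pd.DataFrame:
    """One analysis row per subject from a list of (predicted) label maps."""
    rows = []
    for meta, labels, truth_t in zip(dataset.meta, label_maps,
                                     dataset.truth["true_thickness_mm"]):
        vols = tissue_volumes(labels)
        row = {
            "id": meta.id, "cohort": meta.cohort,
            "ga_weeks": meta.ga_weeks, "pma_weeks": meta.pma_weeks,
            "sex": meta.sex, "true_thickness_mm": float(truth_t),
        }
        for name, v in zip(vols["tissue"], vols["volume_mm3"]):
            row[f"vol_{name}_mm3"] = float(v)
        try:
            row["thickness_mm"] = cortical_thickness(labels).global_mean_mm
        except ValueError:
            row["thickness_mm"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortEffectResult:
    """Outputs of the pre-harmonization validation run."""

    tables: dict[str, pd.DataFrame]
    report: pd.DataFrame
    ct_fits: dict[str, dict]
    t_test: dict
    source_mean_ct_mm: float
    target_mean_ct_mm: float


def cohort_effect_run(n_per_cohort: int = 30,
                      params: PhantomParams | None = None,
                      seed: int = 0) -> CohortEffectResult:
    """Matched cohorts, naive segmentation, cohort-effect regressions.

    Builds two measurement conditions — `truth` (ground-truth labels) and
    `naive` (intensity-window segmentation of the rendered images) — and
    fits ``CT ~ cohort + PMA + GA + sex`` in each, plus the pooled-variance
    t-test on naive cortical thickness.
    """
    params = params or PhantomParams()
    dataset = generate_matched_dataset(n_per_cohort, params, seed=seed)
    cfg = NaiveSegmentConfig.from_phantom(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-class warnings on odd draws
        naive_maps = [naive_segment(img, cfg) for img in dataset.images]
    tables = {
        "truth": measurement_table(dataset, dataset.labels),
        "naive": measurement_table(dataset, naive_maps),
    }
    report = harmonization_report(tables)
    ct_fits = {
        cond: fit_lm(tab, "thickness_mm",
                     ["cohort", "pma_weeks", "ga_weeks", "sex"]).__dict__
        for cond, tab in tables.items()
    }
    naive = tables["naive"]
    src = naive[naive.cohort == "source"]["thickness_mm"]
    tgt = naive[naive.cohort == "target"]["thickness_mm"]
    return CohortEffectResult(
        tables=tables,
        report=report,
        ct_fits=ct_fits,
        t_test=two_sample_t(src, tgt),
        source_mean_ct_mm=float(src.mean()),
        target_mean_ct_mm=float(tgt.mean()),
    )


# ---------------------------------------------------------------------------
# desk-scale end-to-end domain adaptation
# ---------------------------------------------------------------------------

def desk_params() -> PhantomParams:
    """Phantom calibration for network-training experiments (48^3, 0.9 mm)."""
    return PhantomParams(
        grid_shape=(48, 48, 48), spacing_mm=(0.9, 0.9, 0.9),
        radii_mm=(15.5, 14.0, 13.0), radius_growth_mm_per_week=0.25,
        radius_jitter_sd_mm=0.45, csf_rim_mm=2.2,
        dgm_radii_mm=(5.0, 4.5, 4.0), cerebellum_radius_mm=3.2,
        brainstem_radius_mm=2.2,
    )


def desk_specs() -> tuple[UNetSpec, DiscSpec]:
    """Width- and depth-shrunken network specs that train on one CPU.

    Three levels with 8/16/32 channels: the phantom's shell anatomy is
    locally decodable, so the shallow-wide variant converges in far fewer
    steps than the narrow five-level one at equal cost per step.
    """
    return (UNetSpec(levels=3, channels=(16, 32, 64), width_multiplier=0.5),
            DiscSpec(width_multiplier=0.125))


def _render_subjects(metas, domain, params, seed_base, rng):
    out = []
    for i, meta in enumerate(metas):
        anatomy = build_anatomy(meta, params, seed=seed_base + i)
        img = render_image(anatomy, domain, params, seed=seed_base + 5000 + i)
        out.append((meta, anatomy, img))
    return out


def _cohort_subjects(n, cohort, domain, params, seed_base, rng):
    metas = _sample_matched_meta(n, cohort, rng, params)
    return [Subject(image=img, labels=an.labels, id=m.id)
            for m, an, img in _render_subjects(metas, domain, params,
                                               seed_base, rng)]


@dataclass
class TrainedModels:
    """The trained baseline and image-space DA models of one experiment."""

    baseline: object
    generator: object
    da_segmenter: object
    history_baseline: object
    history_image_da: object
    params: PhantomParams
    seed: int


def train_e2e_models(seed: int = 0, epochs: int = 30, n_train: int = 6,
                     params: PhantomParams | None = None,
                     epochs_baseline: int | None = None) -> TrainedModels:
    """Train the baseline and the image-space DA model at desk scale.

    Both runs are independently seeded.  Target-domain training labels are
    wrapped in the access guard; only target images reach the DA model.
    """
    params = params or desk_params()
    unet, disc = desk_specs()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 71)))
    base = (seed % 100_000) * 100_000
    src_train = _cohort_subjects(n_train, "source", "source", params, base, rng)
    tgt_train = _cohort_subjects(n_train, "target", "target", params, base + 100, rng)
    src_val = _cohort_subjects(2, "source", "source", params, base + 200, rng)
    tgt_val = _cohort_subjects(2, "target", "target", params, base + 300, rng)

    plan_b = TrainPlan(regime="baseline", epochs=epochs_baseline or epochs,
                       unet=unet, disc=disc, seed=seed)
    baseline_model, hist_b = train_baseline(src_train, src_val, plan_b)
    plan_i = TrainPlan(regime="image_da", epochs=epochs, unet=unet, disc=disc,
                       seed=seed + 1)
    gen, da_model, _, hist_i = train_image_da(
        src_train, guard_targets(tgt_train), src_val, tgt_val, plan_i)
    return TrainedModels(baseline=baseline_model, generator=gen,
                         da_segmenter=da_model, history_baseline=hist_b,
                         history_image_da=hist_i, params=params, seed=seed)


def validation_replicate(models: TrainedModels, seed: int,
                         n_measure: int = 10) -> dict:
    """One seeded harmonization-validation replicate.

    Draws fresh matched cohorts, renders them in their own domains, and
    compares: (a) target-domain mean Dice of the baseline vs the DA
    segmenter, and (b) the cohort effect on measured cortical thickness
    under naive (pre-harmonization) vs DA (harmonized) segmentation, via
    ``CT ~ cohort + PMA + GA + sex``.
    """
    params = models.params
    rng = np.random.default_rng(np.random.SeedSequence((seed, 977)))
    base = 50_000_000 + (seed % 100_000) * 10_000
    cfg = NaiveSegmentConfig.from_phantom(params)
    rows = []
    dice_b, dice_d = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cohort, offset in (("source", 0), ("target", 5000)):
            metas = _sample_matched_meta(n_measure, cohort, rng, params)
            for m, an, img in _render_subjects(metas, cohort, params,
                                               base + offset, rng):
                naive_ct = cortical_thickness(
                    naive_segment(img, cfg)).global_mean_mm
                _, pl = predict(models.da_segmenter, img)
                try:
                    da_ct = cortical_thickness(pl).global_mean_mm
                except ValueError:
                    da_ct = float("nan")
                if cohort == "target":
                    truth = an.labels.labels
                    dice_d.append(np.nanmean(
                        dice_scores(pl.labels, truth, 7)[1:]))
                    _, pb = predict(models.baseline, img)
                    dice_b.append(np.nanmean(
                        dice_scores(pb.labels, truth, 7)[1:]))
                rows.append({
                    "cohort": cohort, "pma_weeks": m.pma_weeks,
                    "ga_weeks": m.ga_weeks, "sex": m.sex,
                    "true_ct": an.true_mean_thickness_mm,
                    "naive_ct": naive_ct, "da_ct": da_ct,
                })
    table = pd.DataFrame(rows)
    fit_naive = fit_lm(table, "naive_ct",
                       ["cohort", "pma_weeks", "ga_weeks", "sex"])
    result = {
        "seed": seed,
        "dice_target_baseline": float(np.mean(dice_b)),
        "dice_target_image_da": float(np.mean(dice_d)),
        "naive_cohort_beta": fit_naive.coef["cohort"],
        "naive_cohort_p": fit_naive.pvalue["cohort"],
        "table": table,
    }
    if table["da_ct"].notna().all():
        fit_da = fit_lm(table, "da_ct",
                        ["cohort", "pma_weeks", "ga_weeks", "sex"])
        result["da_cohort_beta"] = fit_da.coef["cohort"]
        result["da_cohort_p"] = fit_da.pvalue["cohort"]
    else:
        result["da_cohort_beta"] = float("nan")
        result["da_cohort_p"] = float("nan")
    return result
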