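"""Synthetic two-domain neonatal-brain phantom with known ground truth.

The generator emulates the statistical structure that the harmonization
analyses assume, at desk scale:

* two cohorts with different gestational-age (GA) distributions — a
  term-dominated *source* cohort and a preterm-only (GA <= 33 w) *target*
  cohort — both scanned near term-equivalent postmenstrual age (PMA);
* identical anatomy statistics for GA/PMA-matched subsets of the cohorts;
* anatomy built as nested shells around ellipsoids: an outer CSF rim, a
  cortical gray-matter (cGM) ribbon of controlled metric thickness, a white
  matter (WM) core containing deep gray matter, a cerebellum lobe and a
  brainstem — 7 tissue classes in total;
* a cortical-thickness law ``T = T0 + b_pma (PMA - PMA_ref) + b_ga (GA -
  GA_ref) + b_int (PMA - PMA_ref)(GA - GA_ref) + eps`` with subject noise
  ``eps ~ N(0, sigma_T^2)``;
* a domain-specific appearance model: per-class intensity means differ
  between domains, the target domain is blurred more strongly, and — the key
  confound — the *rendered* cGM/CSF boundary in the target domain is pushed
  outward by ``domain_boundary_offset_mm`` while the ground-truth labels stay
  untouched.  Intensity-based segmentation of target images therefore
  overestimates cortical thickness by about that offset.

The cGM ribbon is bounded by two inward offset surfaces of the outer brain
ellipsoid, computed from the exact point-to-ellipsoid distance, so the
realized ribbon width equals the drawn T everywhere (up to voxelization).
Sub-voxel placement is dithered by jittering the brain center and radii per
subject, which keeps cohort-mean measurements unbiased on coarse grids.

An analytic fast path (`sample_truth_table`) draws per-subject true
thicknesses and volumes from the same generative law without rasterizing
volumes; the statistical validation suites use it where only the measurement
table matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SubjectMeta",
    "ThicknessModel",
    "IntensityModel",
    "PhantomParams",
    "Volume3D",
    "TissueLabelMap",
    "ParcelMap",
    "Anatomy",
    "PhantomDataset",
    "CLASS_NAMES",
    "sample_cohort",
    "build_anatomy",
    "render_image",
    "generate_matched_dataset",
    "sample_truth_table",
]

CLASS_NAMES = ("background", "csf", "cgm", "wm", "dgm", "cerebellum", "brainstem")
BG, CSF, CGM, WM, DGM, CEREBELLUM, BRAINSTEM = range(7)

Cohort = Literal["source", "target"]


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata: cohort, ages (weeks), sex, optional covariates."""

    id: str
    cohort: str
    ga_weeks: float
    pma_weeks: float
    sex: str
    birth_weight_kg: float | None = None
    outcome_score: float | None = None

    def __post_init__(self):
        if self.cohort not in ("source", "target"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (23.0 <= self.ga_weeks <= 42.0):
            raise ValueError("ga_weeks must lie in [23, 42]")
        if self.pma_weeks < self.ga_weeks:
            raise ValueError("pma_weeks must be >= ga_weeks")
        if self.cohort == "target" and self.ga_weeks > 33.0:
            raise ValueError("target-cohort subjects are preterm (GA <= 33 w)")


@dataclass(frozen=True)
class ThicknessModel:
    """Linear cortical-thickness law, referenced at the matched-subset medians."""

    t0_mm: float = 1.73
    beta_pma_mm_per_week: float = 0.04
    beta_ga_mm_per_week: float = 0.06
    beta_interaction: float = -0.001
    # calibrated so the TOTAL matched-subset SD (age-driven + irreducible)
    # reproduces the reported 0.12 mm
    sigma_t_mm: float = 0.087
    pma_ref_weeks: float = 41.3
    ga_ref_weeks: float = 30.5

    def mean_thickness(self, ga: float, pma: float) -> float:
        dp = pma - self.pma_ref_weeks
        dg = ga - self.ga_ref_weeks
        return (self.t0_mm + self.beta_pma_mm_per_week * dp
                + self.beta_ga_mm_per_week * dg + self.beta_interaction * dp * dg)


@dataclass(frozen=True)
class IntensityModel:
    """Per-class rendered intensity means for one domain (arbitrary units in [0, 1])."""

    means: tuple[float, ...]
    smoothing_fwhm_mm: float
    bias_field_amplitude: float
    noise_sd: float = 0.02

    def __post_init__(self):
        if len(self.means) != 7:
            raise ValueError("need one mean per tissue class (7)")


@dataclass(frozen=True)
class PhantomParams:
    """Generator calibration.  Defaults are the package's acceptance surface."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 0.75)
    # outer-brain ellipsoid semi-axes at PMA_ref, growth per week of PMA,
    # and per-subject anatomical jitter (also dithers voxel quantization)
    radii_mm: tuple[float, float, float] = (19.0, 17.0, 15.5)
    radius_growth_mm_per_week: float = 0.3
    radius_jitter_sd_mm: float = 0.5
    csf_rim_mm: float = 2.5
    dgm_radii_mm: tuple[float, float, float] = (6.5, 5.5, 5.0)
    cerebellum_radius_mm: float = 4.0
    brainstem_radius_mm: float = 3.0
    thickness_model: ThicknessModel = field(default_factory=ThicknessModel)
    # Contrast is monotone along the spatial nesting (WM > cGM > CSF > bg,
    # a T1-like ordering): blurred shell transitions then cross only the
    # windows of the two classes that actually meet, the window-based
    # reference segmenter is well-posed, and detected interfaces sit at
    # blurred-profile midpoints (i.e. at the rendered geometry).
    source_intensity: IntensityModel = field(default_factory=lambda: IntensityModel(
        means=(0.03, 0.16, 0.45, 0.75, 0.55, 0.45, 0.64),
        smoothing_fwhm_mm=1.10, bias_field_amplitude=0.04, noise_sd=0.02))
    target_intensity: IntensityModel = field(default_factory=lambda: IntensityModel(
        means=(0.07, 0.12, 0.48, 0.72, 0.57, 0.47, 0.62),
        smoothing_fwhm_mm=1.60, bias_field_amplitude=0.06, noise_sd=0.03))
    domain_boundary_offset_mm: float = 0.20
    partial_volume_mm: float = 0.15  # logistic transition scale of interfaces
    n_parcels: int = 11
    # outcome-score model: cohort-level mean shift, NO dependence on thickness
    outcome_mean: tuple[float, float] = (96.4, 91.3)  # (source, target)
    outcome_sd: tuple[float, float] = (14.9, 17.4)

    def __post_init__(self):
        if self.domain_boundary_offset_mm < 0:
            raise ValueError("domain_boundary_offset_mm must be >= 0")
        if self.radius_jitter_sd_mm < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_parcels < 1:
            raise ValueError("n_parcels must be >= 1")
        ext = min(n * s for n, s in zip(self.grid_shape, self.spacing_mm))
        if 2 * (max(self.radii_mm) + self.radius_growth_mm_per_week * 5) > ext:
            raise ValueError("grid too small to contain the largest brain ellipsoid")

    def intensity(self, domain: str) -> IntensityModel:
        if domain == "source":
            return self.source_intensity
        if domain == "target":
            return self.target_intensity
        raise ValueError(f"unknown domain {domain!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """Scalar 3D image with voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class TissueLabelMap:
    """Integer label grid over the 7 tissue classes."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("TissueLabelMap requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min() < 0 or self.labels.max() > 6:
            raise ValueError("label values must lie in {0..6}")


@dataclass
class ParcelMap:
    """Cortical parcels: values {0..n_parcels}, nonzero exactly on cGM."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_parcels: int


@dataclass
class Anatomy:
    """Ground-truth anatomy of one subject.

    Iterable as (labels, parcels, true_mean_thickness_mm) for convenience.
    The signed distance to the outer brain surface (`signed_dist_mm`,
    negative inside) and the realized geometry are kept for sub-voxel
    rendering; they are *not* measurement inputs.
    """

    labels: TissueLabelMap
    parcels: ParcelMap
    true_mean_thickness_mm: float
    signed_dist_mm: np.ndarray
    csf_rim_mm: float
    seed: int

    def __iter__(self) -> Iterator:
        return iter((self.labels, self.parcels, self.true_mean_thickness_mm))


@dataclass
class PhantomDataset:
    """A rendered two-cohort dataset with its ground-truth table."""

    meta: list[SubjectMeta]
    images: list[Volume3D]
    labels: list[TissueLabelMap]
    parcels: list[ParcelMap]
    truth: pd.DataFrame
    params: PhantomParams
    seed: int


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _draw_ga(rng: np.random.Generator, cohort: str, n: int) -> np.ndarray:
    if cohort == "source":
        # term-dominated mixture with a preterm tail
        term = rng.normal(39.6, 1.4, size=n)
        preterm = rng.uniform(28.0, 37.0, size=n)
        pick = rng.random(n) < 0.8
        return np.clip(np.where(pick, term, preterm), 23.0, 42.0)
    return rng.uniform(24.0, 33.0, size=n)


def _draw_pma(rng: np.random.Generator, cohort: str, ga: np.ndarray) -> np.ndarray:
    if cohort == "source":
        pma = rng.normal(40.9, 1.7, size=ga.size)
    else:
        pma = rng.normal(42.9, 2.3, size=ga.size)
    pma = np.clip(pma, 37.0, 46.0)
    return np.maximum(pma, ga + 0.3)


def _finish_meta(rng: np.random.Generator, cohort: str, ga: np.ndarray,
                 pma: np.ndarray, params: PhantomParams,
                 prefix: str) -> list[SubjectMeta]:
    n = ga.size
    sexes = np.array(["F", "M"] * (n // 2 + 1))[:n]
    rng.shuffle(sexes)
    bw = np.clip(3.4 + 0.17 * (ga - 40.0) + rng.normal(0, 0.35, n), 0.4, 4.8)
    om, osd = params.outcome_mean, params.outcome_sd
    k = 0 if cohort == "source" else 1
    outcome = rng.normal(om[k], osd[k], size=n)
    return [
        SubjectMeta(id=f"{prefix}{i:03d}", cohort=cohort, ga_weeks=float(ga[i]),
                    pma_weeks=float(pma[i]), sex=str(sexes[i]),
                    birth_weight_kg=float(bw[i]), outcome_score=float(outcome[i]))
        for i in range(n)
    ]


def sample_cohort(n: int, cohort: str, seed: int,
                  params: PhantomParams | None = None) -> list[SubjectMeta]:
    """Draw n subjects from a cohort's GA/PMA distribution (full-cohort law)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if cohort not in ("source", "target"):
        raise ValueError(f"unknown cohort {cohort!r}")
    params = params or PhantomParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ga = _draw_ga(rng, cohort, n)
    pma = _draw_pma(rng, cohort, ga)
    return _finish_meta(rng, cohort, ga, pma, params, prefix=f"{cohort[0]}")


def _sample_matched_meta(n: int, cohort: str, rng: np.random.Generator,
                         params: PhantomParams) -> list[SubjectMeta]:
    """GA/PMA-matched law shared by both cohorts (preterm, term-equivalent scan)."""
    tm = params.thickness_model
    ga = np.clip(rng.normal(tm.ga_ref_weeks, 1.2, size=n), 24.0, 33.0)
    pma = np.clip(rng.normal(tm.pma_ref_weeks, 1.0, size=n), 38.0, 45.0)
    pma = np.maximum(pma, ga + 0.3)
    return _finish_meta(rng, cohort, ga, pma, params, prefix=f"m{cohort[0]}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid_signed_distance(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                               center: np.ndarray, axes: np.ndarray,
                               shell_mm: float = 12.0) -> np.ndarray:
    """Exact signed distance (mm) to an axis-aligned ellipsoid surface.

    Negative inside.  Points further than `shell_mm` from the surface (by a
    first-order estimate) keep the fast estimate; near-surface points are
    refined by Newton iteration on the foot-point multiplier, which is
    well-conditioned away from the medial axis.
    """
    x = coords[0] - center[0]
    y = coords[1] - center[1]
    z = coords[2] - center[2]
    a, b, c = axes
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    grad = np.sqrt((x / a**2) ** 2 + (y / b**2) ** 2 + (z / c**2) ** 2)
    grad = np.maximum(grad, 1e-12)
    approx = (rho**2 - 1.0) / (2.0 * grad)  # first-order signed distance
    out = approx.copy()
    near = np.abs(approx) < shell_mm
    if not np.any(near):
        return out
    shape = approx.shape
    xs = np.broadcast_to(x, shape)[near]
    ys = np.broadcast_to(y, shape)[near]
    zs = np.broadcast_to(z, shape)[near]
    ax2 = np.array([a * a, b * b, c * c])
    # solve F(lam) = sum (a_i^2 x_i^2 / (a_i^2 + lam)^2) - 1 = 0
    lam = np.zeros(xs.shape)
    lam_min = -ax2.min()
    for _ in range(40):
        d0 = ax2[0] + lam
        d1 = ax2[1] + lam
        d2 = ax2[2] + lam
        f = (ax2[0] * xs**2 / d0**2 + ax2[1] * ys**2 / d1**2
             + ax2[2] * zs**2 / d2**2) - 1.0
        fp = -2.0 * (ax2[0] * xs**2 / d0**3 + ax2[1] * ys**2 / d1**3
                     + ax2[2] * zs**2 / d2**3)
        step = f / np.where(np.abs(fp) > 1e-14, fp, -1e-14)
        lam = np.maximum(lam - step, lam_min * 0.98)
    fx = ax2[0] * xs / (ax2[0] + lam)
    fy = ax2[1] * ys / (ax2[1] + lam)
    fz = ax2[2] * zs / (ax2[2] + lam)
    dist = np.sqrt((xs - fx) ** 2 + (ys - fy) ** 2 + (zs - fz) ** 2)
    inside = rho[near] < 1.0
    out[near] = np.where(inside, -dist, dist)
    return out


def _grid_coords(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(params.grid_shape, params.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def build_anatomy(meta: SubjectMeta, params: PhantomParams | None = None,
                  seed: int = 0) -> Anatomy:
    """Rasterize one subject's ground-truth labels, parcels and thickness.

    The cGM ribbon lies between the inward offset surfaces at csf_rim and
    csf_rim + T of the outer brain ellipsoid, so its metric width equals the
    realized T drawn from the thickness law.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tm = params.thickness_model

    t_true = tm.mean_thickness(meta.ga_weeks, meta.pma_weeks)
    t_true += rng.normal(0.0, tm.sigma_t_mm) if tm.sigma_t_mm > 0 else 0.0
    t_true = float(np.clip(t_true, 0.4, None))

    growth = params.radius_growth_mm_per_week * (meta.pma_weeks - tm.pma_ref_weeks)
    axes = np.array(params.radii_mm) + growth
    axes = axes + rng.normal(0.0, params.radius_jitter_sd_mm, size=3)
    extent = np.array([n * s for n, s in zip(params.grid_shape, params.spacing_mm)])
    if np.any(2 * (axes + 1.0) > extent):
        raise ValueError("grid too small to contain this subject's anatomy")
    center = extent / 2.0 + rng.uniform(-0.6, 0.6, size=3) * np.array(params.spacing_mm)

    coords = _grid_coords(params)
    sd = _ellipsoid_signed_distance(coords, center, axes)

    rim = params.csf_rim_mm
    labels = np.full(params.grid_shape, BG, dtype=np.int16)
    labels[sd <= 0] = CSF
    labels[sd <= -rim] = CGM
    labels[sd <= -(rim + t_true)] = WM

    x = coords[0] - center[0]
    y = coords[1] - center[1]
    z = coords[2] - center[2]
    da, db, dc = params.dgm_radii_mm
    dgm = ((x / da) ** 2 + (y / db) ** 2 + (z / dc) ** 2) <= 1.0
    labels[dgm & (labels == WM)] = DGM
    # brainstem: inferior cylinder below the deep gray nucleus
    bs_r = params.brainstem_radius_mm
    zlo, zhi = -0.60 * axes[2], -0.10 * axes[2]
    bs = ((x**2 + y**2) <= bs_r**2) & (z >= zlo) & (z <= zhi)
    labels[bs & (labels == WM)] = BRAINSTEM
    # cerebellum: posterior-inferior sphere inside WM
    cb_center = center + np.array([0.26 * axes[0], 0.0, -0.26 * axes[2]])
    cb = ((coords[0] - cb_center[0]) ** 2 + (coords[1] - cb_center[1]) ** 2
          + (coords[2] - cb_center[2]) ** 2) <= params.cerebellum_radius_mm**2
    labels[cb & (labels == WM)] = CEREBELLUM

    # parcels: angular sectors about the vertical axis, restricted to cGM
    theta = np.arctan2(np.broadcast_to(y, labels.shape),
                       np.broadcast_to(x, labels.shape))
    sector = np.floor((theta + np.pi) / (2 * np.pi) * params.n_parcels).astype(np.int16)
    sector = np.clip(sector, 0, params.n_parcels - 1)
    parcels = np.where(labels == CGM, sector + 1, 0).astype(np.int16)

    return Anatomy(
        labels=TissueLabelMap(labels, params.spacing_mm),
        parcels=ParcelMap(parcels, params.spacing_mm, params.n_parcels),
        true_mean_thickness_mm=t_true,
        signed_dist_mm=sd,
        csf_rim_mm=rim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        return (x > 0).astype(float)
    return 1.0 / (1.0 + np.exp(np.clip(-x / width, -60, 60)))


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * B, B in [-1, 1]."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.standard_normal((4, 4, 4))
    field_ = ndimage.zoom(coarse, [s / 4 for s in shape], order=3)
    field_ = field_[: shape[0], : shape[1], : shape[2]]
    pad = [(0, shape[i] - field_.shape[i]) for i in range(3)]
    field_ = np.pad(field_, pad, mode="edge")
    field_ = field_ / (np.abs(field_).max() + 1e-12)
    return 1.0 + amplitude * field_


def render_image(anatomy: Anatomy, domain: str, params: PhantomParams | None = None,
                 seed: int = 0) -> Volume3D:
    """Render one T2w-like volume of an anatomy in a given acquisition domain.

    The target domain shifts per-class intensities, blurs more strongly, and
    moves the *apparent* cGM/CSF interface outward by the configured offset.
    Ground-truth labels are never modified.  Output intensities are mapped to
    [-1, 1] by a fixed affine map (no per-image rescaling).
    """
    params = params or PhantomParams()
    imodel = params.intensity(domain)
    m = imodel.means
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    sd = anatomy.signed_dist_mm
    labels = anatomy.labels.labels
    rim = anatomy.csf_rim_mm
    t_true = anatomy.true_mean_thickness_mm
    delta = params.domain_boundary_offset_mm if domain == "target" else 0.0
    w = params.partial_volume_mm

    # nested interfaces along the signed distance: bg|CSF at 0,
    # CSF|cGM at -(rim - delta)  [apparent ribbon thickened outward],
    # cGM|WM at -(rim + T)
    img = m[BG] + (m[CSF] - m[BG]) * _logistic(-sd, w)
    img = img + (m[CGM] - m[CSF]) * _logistic(-sd - (rim - delta), w)
    img = img + (m[WM] - m[CGM]) * _logistic(-sd - (rim + t_true), w)
    # deep structures: mask-based recoloring (their boundaries are not
    # thickness-relevant; the blur below feathers them)
    img[labels == DGM] = m[DGM]
    img[labels == CEREBELLUM] = m[CEREBELLUM]
    img[labels == BRAINSTEM] = m[BRAINSTEM]

    img = img * _bias_field(img.shape, imodel.bias_field_amplitude, rng)
    if imodel.smoothing_fwhm_mm > 0:
        sigma = [imodel.smoothing_fwhm_mm / 2.3548 / s for s in params.spacing_mm]
        img = ndimage.gaussian_filter(img, sigma)
    if imodel.noise_sd > 0:
        img = img + rng.normal(0.0, imodel.noise_sd, size=img.shape)
    # fixed map [0, 1] -> [-1, 1], clipped
    img = np.clip(2.0 * img - 1.0, -1.0, 1.0)
    return Volume3D(img.astype(np.float32), params.spacing_mm)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def _truth_row(meta: SubjectMeta, anatomy: Anatomy, domain: str,
               voxel_vol: float) -> dict:
    counts = np.bincount(anatomy.labels.labels.ravel(), minlength=7)
    row = {
        "id": meta.id, "cohort": meta.cohort, "domain": domain,
        "ga_weeks": meta.ga_weeks, "pma_weeks": meta.pma_weeks, "sex": meta.sex,
        "birth_weight_kg": meta.birth_weight_kg, "outcome_score": meta.outcome_score,
        "true_thickness_mm": anatomy.true_mean_thickness_mm,
    }
    for k, name in enumerate(CLASS_NAMES):
        row[f"true_vol_{name}_mm3"] = float(counts[k] * voxel_vol)
    return row


def generate_matched_dataset(n_per_cohort: int, params: PhantomParams | None = None,
                             seed: int = 0) -> PhantomDataset:
    """Two GA/PMA-matched cohorts rendered in their own domains.

    Anatomy statistics are identical across cohorts (same matched law); only
    the rendering domain differs, so any systematic measurement difference
    between cohorts is acquisition-induced by construction.
    """
    if n_per_cohort < 2:
        raise ValueError("n_per_cohort must be >= 2")
    params = params or PhantomParams()
    root = np.random.SeedSequence(seed)
    meta_rngs = [np.random.default_rng(s) for s in root.spawn(2)]
    metas = (_sample_matched_meta(n_per_cohort, "source", meta_rngs[0], params)
             + _sample_matched_meta(n_per_cohort, "target", meta_rngs[1], params))
    subject_seeds = root.spawn(len(metas))
    voxel_vol = float(np.prod(params.spacing_mm))

    images, labels, parcels, rows = [], [], [], []
    for meta, sseq in zip(metas, subject_seeds):
        s_anat, s_render = (int(c.generate_state(1)[0] % (2**31)) for c in sseq.spawn(2))
        anatomy = build_anatomy(meta, params, seed=s_anat)
        img = render_image(anatomy, domain=meta.cohort, params=params, seed=s_render)
        images.append(img)
        labels.append(anatomy.labels)
        parcels.append(anatomy.parcels)
        rows.append(_truth_row(meta, anatomy, meta.cohort, voxel_vol))
    return PhantomDataset(meta=metas, images=images, labels=labels, parcels=parcels,
                          truth=pd.DataFrame(rows), params=params, seed=seed)


def _analytic_volumes(params: PhantomParams, axes: np.ndarray, t: float) -> dict:
    """Shell volumes from ellipsoid formulas (offset shells approximated by
    shrinking each semi-axis by the offset)."""
    def vol(semi):
        semi = np.maximum(semi, 0.0)
        return 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2]

    rim = params.csf_rim_mm
    v_brain = vol(axes)
    v_in_csf = vol(axes - rim)
    v_in_cgm = vol(axes - rim - t)
    v_dgm = vol(np.array(params.dgm_radii_mm))
    v_cb = 4.0 / 3.0 * np.pi * params.cerebellum_radius_mm**3
    zlo, zhi = 0.60 * axes[2], 0.10 * axes[2]
    v_bs = np.pi * params.brainstem_radius_mm**2 * (zlo - zhi)
    return {
        "csf": v_brain - v_in_csf,
        "cgm": v_in_csf - v_in_cgm,
        "wm": v_in_cgm - v_dgm - v_cb - v_bs,
        "dgm": v_dgm,
        "cerebellum": v_cb,
        "brainstem": v_bs,
    }


def sample_truth_table(n_per_cohort: int, params: PhantomParams | None = None,
                       seed: int = 0, matched: bool = True,
                       measured: bool = False,
                       measurement_noise_sd_mm: float = 0.03) -> pd.DataFrame:
    """Analytic per-subject truth table without rasterizing any volume.

    With ``measured=True`` an additional `measured_thickness_mm` column
    emulates the intensity-based measurement chain: the target cohort gains
    the domain boundary offset, and both cohorts i.i.d. measurement noise.
    Used by the statistical validation suites, where only the table matters.
    """
    params = params or PhantomParams()
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(3)]
    tm = params.thickness_model
    rows = []
    for k, cohort in enumerate(("source", "target")):
        rng = rngs[k]
        if matched:
            metas = _sample_matched_meta(n_per_cohort, cohort, rng, params)
        else:
            ga = _draw_ga(rng, cohort, n_per_cohort)
            pma = _draw_pma(rng, cohort, ga)
            metas = _finish_meta(rng, cohort, ga, pma, params, prefix=f"{cohort[0]}")
        for meta in metas:
            t = tm.mean_thickness(meta.ga_weeks, meta.pma_weeks)
            t += rng.normal(0.0, tm.sigma_t_mm) if tm.sigma_t_mm > 0 else 0.0
            t = float(np.clip(t, 0.4, None))
            growth = params.radius_growth_mm_per_week * (meta.pma_weeks - tm.pma_ref_weeks)
            axes = (np.array(params.radii_mm) + growth
                    + rng.normal(0.0, params.radius_jitter_sd_mm, size=3))
            vols = _analytic_volumes(params, axes, t)
            row = {
                "id": meta.id, "cohort": cohort,
                "ga_weeks": meta.ga_weeks, "pma_weeks": meta.pma_weeks,
                "sex": meta.sex, "birth_weight_kg": meta.birth_weight_kg,
                "outcome_score": meta.outcome_score,
                "true_thickness_mm": t,
            }
            for name, v in vols.items():
                row[f"true_vol_{name}_mm3"] = float(v)
            rows.append(row)
    df = pd.DataFrame(rows)
    if measured:
        mrng = rngs[2]
        bias = np.where(df["cohort"] == "target",
                        params.domain_boundary_offset_mm, 0.0)
        noise = mrng.normal(0.0, measurement_noise_sd_mm, size=len(df))
        df["measured_thickness_mm"] = df["true_thickness_mm"] + bias + noise
    return df
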