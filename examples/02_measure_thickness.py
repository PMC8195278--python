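"""Measure cortical thickness with the Laplace-equation method.

Builds one subject, measures thickness on the ground-truth labels and on a
naive intensity-window segmentation of the rendered image, for both
acquisition domains of the same anatomy.  The target-domain measurement
comes out ~0.2 mm thicker although the anatomy is identical — that is the
acquisition-induced bias the harmonization pipeline exists to remove.
"""

import warnings

from neoharm.measure import NaiveSegmentConfig, cortical_thickness, naive_segment
from neoharm.phantom import PhantomParams, SubjectMeta, build_anatomy, render_image

params = PhantomParams()
meta = SubjectMeta(id="demo", cohort="target", ga_weeks=30.5, pma_weeks=41.3,
                   sex="F")
anatomy = build_anatomy(meta, params, seed=11)
print(f"true mean cortical thickness: {anatomy.true_mean_thickness_mm:.3f} mm")

truth_ct = cortical_thickness(anatomy.labels)
print(f"measured on ground-truth labels: {truth_ct.global_mean_mm:.3f} mm "
      f"({truth_ct.n_voxels} ribbon voxels)")

cfg = NaiveSegmentConfig.from_phantom(params)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for domain in ("source", "target"):
        img = render_image(anatomy, domain, params, seed=12)
        seg = naive_segment(img, cfg)
        ct = cortical_thickness(seg)
        print(f"naive segmentation of the {domain}-domain rendering: "
              f"{ct.global_mean_mm:.3f} mm")
print()
print("Same anatomy, two domains: the target rendering measures thicker "
      "because its apparent cGM/CSF boundary is pushed outward.")
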