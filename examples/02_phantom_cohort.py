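"""Generate a synthetic two-class phantom cohort.

Samples a reduced-scale cohort (33x64x64 stacks), prints the class
geometry that makes it separable, and exports it to disk in the formats
the CLI consumes (NIfTI + annotation JSON + manifest CSV).
"""

import numpy as np

from landmarknet import PhantomSpec, sample_cohort, export_cohort

spec = PhantomSpec.reduced(n_patients=5, n_controls=5, seed=0)
cohort = sample_cohort(spec)

print(f"subjects: {len(cohort)}  "
      f"({sum(l == 'HLHS' for _, _, l in cohort)} patients, "
      f"{sum(l == 'control' for _, _, l in cohort)} controls)")
shift = spec.templates("HLHS")[3] - spec.templates("control")[3]
print(f"aortic-valve landmark class shift      : {np.linalg.norm(shift):.0f} mm")
print(f"within-class landmark jitter SD        : {spec.jitter_sd_mm:.0f} mm")

stack, ann, label = cohort[0]
print(f"first subject {ann.subject_id!r} ({label}), stack {stack.values.shape}, "
      f"landmark voxels:\n{ann.landmarks.astype(int)}")

out = export_cohort(cohort, "scratch/example_cohort", spec)
print(f"exported to {out}")
# The 40 mm aortic-valve shift against 3 mm jitter makes ground-truth
# point clouds linearly separable, mirroring the anatomy difference the
# classifier exploits.
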