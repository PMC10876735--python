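"""Classify ground-truth landmark point clouds with the linear SVM.

Runs the annotation-only pathway: centred point clouds built from the
phantom annotations are cross-validated with stratified 5-fold CV, and
the per-landmark weight summary shows which landmark drives the
decision.
"""

from landmarknet import PhantomSpec, sample_cohort
from landmarknet.evaluation import run_crossval

spec = PhantomSpec.reduced(n_patients=23, n_controls=17, seed=1)
cohort = sample_cohort(spec)

result = run_crossval(cohort, k=5, seed=0, from_annotations=True)
print(f"cross-validated accuracy on annotated landmarks: "
      f"{100 * result['accuracy']:.1f}%")
print("\nper-landmark classifier weights (fold average):")
print(result["weights"].to_string(index=False,
                                  float_format=lambda v: f"{v: .4f}"))
# Accuracy is 100% because the class geometry is linearly separable; the
# aortic-valve landmark (id 4) carries the largest RMS weight — it is the
# landmark whose position differs between the classes.
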