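"""Linear SVM over centred landmark point clouds.

The classifier is a soft-margin support-vector machine with a linear
kernel and library-default regularisation (C = 1), fitted on the 21
centred coordinates in landmark-major order (L1z, L1y, L1x, ..., L7x).
Because the only features are relative landmark positions in mm, the
learned hyperplane is directly interpretable: per-landmark weight
summaries (max and RMS of the three spatial coefficients) say which
anatomical structure drives the decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import LANDMARK_NAMES, N_LANDMARKS
from .pointcloud import clouds_to_features

__all__ = [
    "ClassifierModel",
    "fit_classifier",
    "classify",
    "decision_values",
    "weight_summary",
]

N_FEATURES = 3 * N_LANDMARKS


@dataclass
class ClassifierModel:
    """Fitted linear hyperplane over the 21 centred coordinates."""

    svc: SVC
    classes: tuple[str, str]

    @property
    def coefficients(self) -> np.ndarray:
        """Length-21 weight vector in landmark-major order."""
        return np.asarray(self.svc.coef_).reshape(-1)

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    def save_coefficients(self, path) -> None:
        """Plain-text dump of the per-landmark weight summary table."""
        weight_summary(self).to_csv(path, index=False)


def _extract_features_labels(clouds, labels=None):
    x = clouds_to_features(clouds)
    if labels is None:
        labels = [c.label for c in clouds]
        if any(l is None for l in labels):
            raise ValueError("clouds must carry labels (or pass labels explicitly)")
    y = np.asarray(labels)
    if x.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {x.shape[1]}")
    return x, y


def fit_classifier(clouds, labels=None) -> ClassifierModel:
    """Fit the linear SVM on centred clouds.

    ``labels`` defaults to the labels carried by the clouds.  Requires
    both classes to be present; fitting is deterministic for a fixed
    input order.
    """
    x, y = _extract_features_labels(clouds, labels)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError(f"need both classes to fit, got only {uniq!r}")
    svc = SVC(kernel="linear")
    svc.fit(x, y)
    return ClassifierModel(svc=svc, classes=tuple(svc.classes_))


def decision_values(model: ClassifierModel, clouds) -> np.ndarray:
    """Signed distances to the hyperplane (positive -> classes[1])."""
    x = clouds_to_features(np.atleast_1d(clouds))
    return np.asarray(model.svc.decision_function(x))


def classify(model: ClassifierModel, cloud) -> str:
    """Predicted label for one centred cloud.

    A cloud exactly on the hyperplane (decision value 0) receives the
    class the underlying library assigns for a zero decision value —
    deterministic, recorded here as the tie policy.
    """
    if not hasattr(model.svc, "coef_"):
        raise ValueError("classifier is not fitted")
    x = clouds_to_features([cloud])
    return str(model.svc.predict(x)[0])


def classify_many(model: ClassifierModel, clouds) -> np.ndarray:
    x = clouds_to_features(clouds)
    return model.svc.predict(x)


def weight_summary(model: ClassifierModel) -> pd.DataFrame:
    """Per-landmark max and RMS of the three spatial coefficients.

    Returns one row per landmark with the anatomical name; the landmark
    with the largest RMS is flagged in the ``is_argmax`` column.
    """
    coef = model.coefficients.reshape(N_LANDMARKS, 3)
    max_w = coef[np.arange(N_LANDMARKS), np.abs(coef).argmax(axis=1)]
    rms = np.sqrt((coef ** 2).mean(axis=1))
    argmax_landmark = int(rms.argmax())
    return pd.DataFrame(
        {
            "landmark_id": np.arange(1, N_LANDMARKS + 1),
            "landmark_name": [LANDMARK_NAMES[j] for j in range(1, N_LANDMARKS + 1)],
            "max_weight": max_w,
            "rms_weight": rms,
            "is_argmax": [j == argmax_landmark for j in range(N_LANDMARKS)],
        }
    )
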