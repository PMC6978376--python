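"""Trust-score baseline: nearest-class distance ratio after outlier removal.

The trust score of a test point is the distance to the nearest retained
training point of the *alternate* class divided by the distance to the
nearest retained point of the *predicted* class.  Values above 1 mean the
point sits closer to the class the model predicted; low values flag
predictions that disagree with a nearest-neighbor view of the training
data.  Before scoring, each class is filtered by removing the fraction of
points with the largest distance to their k-th same-class neighbor.

Distances are Euclidean in normalized feature space, so the score is
invariant to any common positive rescaling of the features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .schema import FeatureSchema

logger = logging.getLogger(__name__)

#: returned when a test point coincides with a retained predicted-class point
DEFAULT_CAP = 1e6


@dataclass
class TrustReference:
    """Outlier-filtered training points per class, ready for kNN queries."""

    schema: FeatureSchema
    filtered_pos: np.ndarray
    filtered_neg: np.ndarray
    k: int
    alpha: float

    def __post_init__(self) -> None:
        if len(self.filtered_pos) == 0 or len(self.filtered_neg) == 0:
            raise ValueError("each retained class set must be nonempty")
        self._nn_pos = NearestNeighbors(n_neighbors=1).fit(self.filtered_pos)
        self._nn_neg = NearestNeighbors(n_neighbors=1).fit(self.filtered_neg)


def _filter_class(X: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Keep the ceil((1−alpha)·n) points densest by k-th-neighbor distance."""
    n = X.shape[0]
    keep = math.ceil((1.0 - alpha) * n)
    if keep < 1:
        raise ValueError("alpha removes the entire class")
    if alpha == 0.0:
        return X.copy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)  # +1: self is its own neighbor
    dists, _ = nn.kneighbors(X)
    kth = dists[:, k]
    order = np.argsort(kth, kind="stable")
    return X[np.sort(order[:keep])]


def fit_trust_reference(
    features: pd.DataFrame | np.ndarray,
    labels,
    schema: FeatureSchema,
    k: int = 10,
    alpha: float = 0.05,
) -> TrustReference:
    """Filter each class and build the nearest-neighbor reference.

    ``alpha`` is the fraction of each class dropped as outliers (those with
    the largest distance to their ``k``-th nearest same-class neighbor).
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    X = schema.normalize(features)
    y = np.asarray(labels).astype(int).reshape(-1)
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    Xp, Xn = X[y == 1], X[y == 0]
    if Xp.shape[0] == 0 or Xn.shape[0] == 0:
        raise ValueError("both classes must be present")
    if k >= min(Xp.shape[0], Xn.shape[0]):
        raise ValueError("k must be smaller than the minority class size")
    return TrustReference(
        schema=schema,
        filtered_pos=_filter_class(Xp, k, alpha),
        filtered_neg=_filter_class(Xn, k, alpha),
        k=k,
        alpha=alpha,
    )


def trust_score(
    ref: TrustReference,
    features: pd.DataFrame | np.ndarray,
    predicted_class,
    cap: float = DEFAULT_CAP,
) -> np.ndarray:
    """d(x, nearest alternate-class point) / d(x, nearest predicted-class point).

    ``predicted_class`` is a 0/1 array (or scalar) giving the class the risk
    model assigns to each row.  A zero denominator (the point coincides with
    a retained predicted-class example) returns ``cap`` and is logged.
    """
    X = ref.schema.normalize(features)
    pred = np.asarray(predicted_class, dtype=int).reshape(-1)
    if pred.size == 1:
        pred = np.full(X.shape[0], pred[0])
    if pred.size != X.shape[0]:
        raise ValueError("predicted_class must match the number of rows")
    if not np.all((pred == 0) | (pred == 1)):
        raise ValueError("predicted_class must be binary 0/1")
    d_pos = ref._nn_pos.kneighbors(X)[0][:, 0]
    d_neg = ref._nn_neg.kneighbors(X)[0][:, 0]
    d_pred = np.where(pred == 1, d_pos, d_neg)
    d_alt = np.where(pred == 1, d_neg, d_pos)
    out = np.empty(X.shape[0])
    zero = d_pred == 0.0
    if zero.any():
        logger.info(
            "%d test points coincide with predicted-class training points; "
            "trust score capped at %g",
            int(zero.sum()),
            cap,
        )
    out[zero] = cap
    out[~zero] = d_alt[~zero] / d_pred[~zero]
    return out


def predicted_classes(scores, threshold: float) -> np.ndarray:
    """Assign predicted classes by thresholding risk scores.

    Under heavy class imbalance a 0.5 threshold would predict the negative
    class almost always; thresholding at the cohort prevalence keeps both
    predicted classes populated.
    """
    s = np.asarray(scores, dtype=float).reshape(-1)
    return (s >= threshold).astype(int)
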