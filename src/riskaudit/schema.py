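"""Feature schemas for mixed continuous/binary patient feature vectors.

A :class:`FeatureSchema` fixes the coordinate convention used throughout the
package: coordinate ``j`` of every vector, mean, and covariance row refers to
``schema.names[j]``.  Continuous features carry a ``(min, max)`` range used to
map raw clinical units onto the unit interval; binary features are 0/1 and are
never rescaled.  All downstream objects (class summaries, risk models, score
distributions) operate in these normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered description of the feature space.

    Parameters
    ----------
    names
        Feature identifiers, in coordinate order.
    kinds
        Per-feature flag, ``"continuous"`` or ``"binary"``.
    ranges
        Mapping ``name -> (min, max)`` for every continuous feature, used for
        [0, 1] normalization.  Binary features must not appear here.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "ranges", dict(self.ranges))
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        for name, kind in zip(self.names, self.kinds):
            if kind == CONTINUOUS:
                if name not in self.ranges:
                    raise ValueError(f"continuous feature {name!r} needs a range")
                lo, hi = self.ranges[name]
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(f"range for {name!r} must satisfy min < max")
            elif kind == BINARY:
                if name in self.ranges:
                    raise ValueError(f"binary feature {name!r} must not have a range")
            else:
                raise ValueError(f"unknown feature kind {kind!r} for {name!r}")

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([k == BINARY for k in self.kinds], dtype=bool)

    @property
    def continuous_mask(self) -> np.ndarray:
        return ~self.binary_mask

    def normalize(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Return an ``(n, p)`` float array in normalized units.

        DataFrames are re-ordered to schema order; arrays are assumed to be
        in schema order already but in *raw* units.  Continuous coordinates
        are affinely mapped by their range; binary coordinates must be 0/1.
        Non-finite entries raise ``ValueError("invalid feature value")``.
        """
        if isinstance(features, pd.DataFrame):
            missing = [n for n in self.names if n not in features.columns]
            if missing:
                raise ValueError(f"feature table missing columns: {missing}")
            X = features.loc[:, list(self.names)].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != self.n_features:
                raise ValueError(
                    f"expected {self.n_features} features, got {X.shape[1]}"
                )
        if not np.all(np.isfinite(X)):
            raise ValueError("invalid feature value: non-finite entries present")
        X = X.copy()
        for j, (name, kind) in enumerate(zip(self.names, self.kinds)):
            if kind == CONTINUOUS:
                lo, hi = self.ranges[name]
                X[:, j] = (X[:, j] - lo) / (hi - lo)
            else:
                col = X[:, j]
                if not np.all((col == 0.0) | (col == 1.0)):
                    raise ValueError(
                        f"invalid feature value: binary feature {name!r} not 0/1"
                    )
        return X

    def to_frame(self, X: np.ndarray) -> pd.DataFrame:
        """Wrap a normalized-units array as a DataFrame with schema columns."""
        return pd.DataFrame(np.asarray(X, dtype=float), columns=list(self.names))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "kinds": list(self.kinds),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        return cls(
            names=tuple(d["names"]),
            kinds=tuple(d["kinds"]),
            ranges={k: (float(v[0]), float(v[1])) for k, v in d.get("ranges", {}).items()},
        )


def unit_schema(
    n_continuous: int,
    n_binary: int = 0,
    prefix: str = "x",
) -> FeatureSchema:
    """Convenience schema with continuous features already on [0, 1].

    Continuous features are named ``x1..`` with identity ranges ``(0, 1)``;
    binary features follow, named ``b1..``.
    """
    names: list[str] = [f"{prefix}{i + 1}" for i in range(n_continuous)]
    kinds: list[str] = [CONTINUOUS] * n_continuous
    names += [f"b{i + 1}" for i in range(n_binary)]
    kinds += [BINARY] * n_binary
    ranges = {n: (0.0, 1.0) for n, k in zip(names, kinds) if k == CONTINUOUS}
    return FeatureSchema(tuple(names), tuple(kinds), ranges)
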