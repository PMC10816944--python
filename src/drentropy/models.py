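"""Assembly of the 16 binary severity-vs-healthy feature models.

Each model M1..M16 pairs one retinopathy severity level (mild, proliferate,
severe, moderate) with one preprocessing level (original, or one of the three
gamma corrections) and classifies that level against healthy (NoDR) images
using the (Shannon entropy, fuzzy entropy) pair computed at that
preprocessing level.  The models group by preprocessing level into four
disjoint sets of four, one per contrast condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "DR_LEVELS",
    "CONTROL_LABEL",
    "enumerate_model_specs",
    "preprocessing_groups",
    "build_design_matrix",
]

#: Healthy reference class; always label 0 in the binary designs.
CONTROL_LABEL = "NoDR"

#: Severity levels in model-index order (M1-4 mild, M5-8 proliferate,
#: M9-12 severe, M13-16 moderate).
DR_LEVELS = ("mild", "proliferate", "severe", "moderate")

_LEVELS = ("O", "g1", "g2", "g3")


@dataclass(frozen=True)
class ModelSpec:
    """One binary model: a severity level at a preprocessing level."""

    index: str  # "M1" .. "M16"
    dr_level: str
    preprocessing: str

    def __post_init__(self) -> None:
        if self.dr_level not in DR_LEVELS:
            raise ValueError(f"unknown severity level {self.dr_level!r}")
        if self.preprocessing not in _LEVELS:
            raise ValueError(f"unknown preprocessing level {self.preprocessing!r}")

    @property
    def feature_columns(self) -> tuple[str, str]:
        return (f"SE_{self.preprocessing}", f"FE_{self.preprocessing}")


def enumerate_model_specs() -> list[ModelSpec]:
    """The 16 (severity, preprocessing) combinations in canonical order."""
    specs = []
    k = 1
    for level in DR_LEVELS:
        for prep in _LEVELS:
            specs.append(ModelSpec(index=f"M{k}", dr_level=level, preprocessing=prep))
            k += 1
    return specs


def preprocessing_groups() -> dict[str, list[str]]:
    """Partition of M1..M16 into the four contrast-condition groups."""
    groups: dict[str, list[str]] = {p: [] for p in _LEVELS}
    for spec in enumerate_model_specs():
        groups[spec.preprocessing].append(spec.index)
    return groups


@dataclass(frozen=True)
class DesignMatrix:
    """Binary two-feature design: rows from NoDR plus one severity level.

    X has columns (SE, FE) at the model's preprocessing level; y is 0 for
    NoDR and 1 for the severity level.
    """

    X: np.ndarray
    y: np.ndarray
    image_ids: tuple[str, ...]
    spec: ModelSpec

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("X must be n x 2")
        if len(self.y) != len(self.X) or len(self.image_ids) != len(self.X):
            raise ValueError("X, y and image_ids must align")
        if not np.isfinite(self.X).all():
            raise ValueError("design contains non-finite feature values")
        if not (0 in self.y and 1 in self.y):
            raise ValueError("both classes must be present")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": self.image_ids,
                "SE": self.X[:, 0],
                "FE": self.X[:, 1],
                "label": self.y,
            }
        )


def build_design_matrix(features: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Project the feature table onto one model's rows and columns.

    Rows are all NoDR images followed by all images of the model's severity
    level; columns are the (SE, FE) pair at the model's preprocessing level.
    """
    for cls in (CONTROL_LABEL, spec.dr_level):
        if not (features["label"] == cls).any():
            raise ValueError(f"feature table contains no {cls!r} images")
    se_col, fe_col = spec.feature_columns
    for col in (se_col, fe_col):
        if col not in features.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    sub = pd.concat(
        [
            features[features["label"] == CONTROL_LABEL],
            features[features["label"] == spec.dr_level],
        ],
        ignore_index=True,
    )
    X = sub[[se_col, fe_col]].to_numpy(dtype=np.float64)
    y = (sub["label"] == spec.dr_level).to_numpy(dtype=np.int64)
    return DesignMatrix(X=X, y=y, image_ids=tuple(sub["image_id"]), spec=spec)
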