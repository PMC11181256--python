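"""Named feature vectors and the CSV feature-table format shared by the
texture modules and the classifier."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["COMBINATIONS", "FeatureVector", "write_feature_table", "read_feature_table"]

#: Feature-combination identifiers and their expected lengths.
COMBINATIONS = {"GLCM48": 48, "GLCM48_PLUS_GLOBAL3": 51, "GGCM15": 15}


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named real-valued features for one lesion."""

    combination_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.combination_id not in COMBINATIONS:
            raise ValueError(f"unknown combination {self.combination_id!r}")
        expected = COMBINATIONS[self.combination_id]
        if len(self.names) != expected or len(self.values) != expected:
            raise ValueError(
                f"{self.combination_id} expects {expected} features, got "
                f"{len(self.names)} names / {len(self.values)} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def write_feature_table(
    path: str | Path,
    lesion_ids: list[str],
    vectors: list[FeatureVector],
    labels: list[int],
) -> pd.DataFrame:
    """Write one row per lesion: lesion_id, combination_id, features..., label.

    Column order is deterministic (the feature order of the combination).
    """
    if not vectors:
        raise ValueError("no feature vectors to write")
    combo = vectors[0].combination_id
    names = vectors[0].names
    for v in vectors:
        if v.combination_id != combo or v.names != names:
            raise ValueError("mixed feature combinations in one table")
    df = pd.DataFrame(
        [v.values for v in vectors], columns=list(names), index=None
    )
    df.insert(0, "lesion_id", lesion_ids)
    df.insert(1, "combination_id", combo)
    df["label"] = labels
    df.to_csv(path, index=False)
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"lesion_id": str})
    required = {"lesion_id", "combination_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
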