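"""The five-feature complexity score for supratentorial glioblastoma.

Each pre-operative MRI feature contributes one point when present:

====================================  =========================
periventricular / deep location       ventricle distance < 10 mm (strict)
corpus callosum or bilateral          either involvement flag
eloquent location                     overlap with eloquent regions
large tumour                          maximal diameter >= 40 mm (inclusive)
associated oedema                     extension >= 10 mm (inclusive)
====================================  =========================

The total (0-5) stratifies lesions into low (0-1), moderate (2-3) and
high (4-5) complexity. Boundary semantics are deliberate and pinned by
tests: a tumour exactly 10 mm from the ventricle scores 0 for location,
while a 40 mm diameter or 10 mm oedema extension scores 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FEATURE_COLUMNS, TumorFeatures

__all__ = [
    "GradeThresholds",
    "FeatureFlags",
    "GradeResult",
    "COMPLEXITY_LEVELS",
    "FLAG_NAMES",
    "binarize",
    "total_score",
    "classify",
    "classify_scores",
    "grade",
    "grade_table",
]

logger = logging.getLogger(__name__)

COMPLEXITY_LEVELS = ("low", "moderate", "high")
FLAG_NAMES = ("periventricular", "callosal_or_bilateral", "eloquent", "large", "oedema")


@dataclass(frozen=True)
class GradeThresholds:
    """Cut-offs (mm) for the three continuous features."""

    periventricular_mm: float = 10.0
    diameter_mm: float = 40.0
    oedema_mm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("periventricular_mm", "diameter_mm", "oedema_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FeatureFlags:
    """The five binarized features, each 0 or 1."""

    periventricular: int
    callosal_or_bilateral: int
    eloquent: int
    large: int
    oedema: int

    def __post_init__(self) -> None:
        for name in FLAG_NAMES:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"flag {name} must be 0 or 1")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in FLAG_NAMES)


@dataclass(frozen=True)
class GradeResult:
    flags: FeatureFlags
    score: int
    complexity: str


def binarize(features: TumorFeatures, thresholds: GradeThresholds | None = None) -> FeatureFlags:
    """Apply the threshold rules to raw measurements.

    Periventricular uses a strict ``<``; size and oedema are inclusive
    ``>=``. Missing (NaN) measurements make the record ungradable.
    """
    t = thresholds or GradeThresholds()
    lengths = (
        features.ventricle_distance_mm,
        features.max_diameter_mm,
        features.oedema_extension_mm,
    )
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in lengths):
        raise ValueError("missing measurement: record is ungradable")
    if any(v < 0 for v in lengths):
        raise ValueError("lengths must be non-negative")
    return FeatureFlags(
        periventricular=int(features.ventricle_distance_mm < t.periventricular_mm),
        callosal_or_bilateral=int(
            bool(features.corpus_callosum_involved) or bool(features.bilateral)
        ),
        eloquent=int(bool(features.eloquent_involved)),
        large=int(features.max_diameter_mm >= t.diameter_mm),
        oedema=int(features.oedema_extension_mm >= t.oedema_mm),
    )


def total_score(flags: FeatureFlags) -> int:
    """Sum of the five equally weighted flags (0-5)."""
    return sum(flags.as_tuple())


def classify(score: int) -> str:
    """Map a 0-5 score to its complexity class."""
    if not 0 <= score <= 5 or int(score) != score:
        raise ValueError(f"score must be an integer in 0..5, got {score}")
    if score <= 1:
        return "low"
    if score <= 3:
        return "moderate"
    return "high"


def classify_scores(scores) -> np.ndarray:
    """Vectorised :func:`classify` for integer score arrays."""
    s = np.asarray(scores)
    if s.size and (s.min() < 0 or s.max() > 5):
        raise ValueError("scores must lie in 0..5")
    return np.where(s <= 1, "low", np.where(s <= 3, "moderate", "high"))


def grade(features: TumorFeatures, thresholds: GradeThresholds | None = None) -> GradeResult:
    """Binarize, sum and classify one feature record."""
    flags = binarize(features, thresholds)
    score = total_score(flags)
    return GradeResult(flags=flags, score=score, complexity=classify(score))


def grade_table(df: pd.DataFrame, thresholds: GradeThresholds | None = None) -> pd.DataFrame:
    """Grade a per-subject feature table (the CSV schema emitted by extraction).

    Appends the five flag columns plus ``score`` and ``complexity``.
    Records with any missing feature are ungradable: their derived columns
    are left missing and a warning lists the offending subject_ids. No
    imputation is performed.
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns: {missing_cols}")
    out = df.copy()
    t = thresholds or GradeThresholds()
    ungradable = out[list(FEATURE_COLUMNS)].isna().any(axis=1)
    if ungradable.any():
        ids = out.loc[ungradable, "subject_id"].tolist() if "subject_id" in out else list(
            out.index[ungradable]
        )
        logger.warning("ungradable records (missing features): %s", ids)
    ok = ~ungradable
    flags = pd.DataFrame(index=out.index, columns=FLAG_NAMES, dtype="Int64")
    flags.loc[ok, "periventricular"] = (
        out.loc[ok, "ventricle_distance_mm"] < t.periventricular_mm
    ).astype(int)
    flags.loc[ok, "callosal_or_bilateral"] = (
        out.loc[ok, "corpus_callosum_involved"].astype(bool)
        | out.loc[ok, "bilateral"].astype(bool)
    ).astype(int)
    flags.loc[ok, "eloquent"] = out.loc[ok, "eloquent_involved"].astype(bool).astype(int)
    flags.loc[ok, "large"] = (out.loc[ok, "max_diameter_mm"] >= t.diameter_mm).astype(int)
    flags.loc[ok, "oedema"] = (out.loc[ok, "oedema_extension_mm"] >= t.oedema_mm).astype(int)
    out[list(FLAG_NAMES)] = flags
    out["score"] = flags.sum(axis=1, skipna=False).astype("Int64")
    out["complexity"] = pd.Series(pd.NA, index=out.index, dtype="string")
    out.loc[ok, "complexity"] = classify_scores(out.loc[ok, "score"].astype(int).to_numpy())
    if t != GradeThresholds():
        out.attrs["thresholds"] = {
            "periventricular_mm": t.periventricular_mm,
            "diameter_mm": t.diameter_mm,
            "oedema_mm": t.oedema_mm,
        }
    return out
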