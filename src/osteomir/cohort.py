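"""Cohort data model, delimited-text I/O, T-score classification, min-max scaling.

A cohort is one row per postmenopausal participant: circulating miR-194-5p
relative expression (2^-ddCT units), up to 42 routine medical-examination
items (EIs), lumbar-spine (L1-L4) BMD in g/cm2 and the corresponding T-score.
Bone status is derived from the T-score with the WHO cut-offs: normal above
-1.0, osteopenia in (-2.5, -1.0], osteoporosis at or below -2.5.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER = "mir194"
_META_COLS = ("id", MARKER, "bmd", "t_score")


class BoneStatus(str, enum.Enum):
    NORMAL = "normal"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"

    @property
    def at_risk(self) -> bool:
        """Binary risk label: the ROC positive class is osteoporosis only."""
        return self is BoneStatus.OSTEOPOROSIS


def classify_bone_status(t_score: float) -> BoneStatus:
    """Map a spine T-score (SD units) to a bone-status group.

    T-score > -1.0 is normal bone mass; -2.5 < T-score <= -1.0 is osteopenia;
    T-score <= -2.5 is osteoporosis.  The three intervals partition the real
    line, so every finite T-score receives exactly one status.
    """
    t = float(t_score)
    if not math.isfinite(t):
        raise ValueError(f"t_score must be finite, got {t_score!r}")
    if t > -1.0:
        return BoneStatus.NORMAL
    if t > -2.5:
        return BoneStatus.OSTEOPENIA
    return BoneStatus.OSTEOPOROSIS


# ---------------------------------------------------------------------------
# Item registry: the 42 routine examination items, grouped in 5 categories.
# Category sizes 3/18/5/9/7.  Names follow common clinical abbreviations.
# ---------------------------------------------------------------------------

EI_CATEGORIES: dict[str, tuple[str, ...]] = {
    "basic_information": ("age", "height", "weight"),
    "biochemical_test": (
        "ALT", "AST", "GGT", "ALP", "LDH", "UA", "CKMB_CK", "CK", "TBIL",
        "ALB", "TP", "BUN", "CREA", "GLU", "TG", "TC", "HDL", "LDL",
    ),
    "blood_test": ("WBC", "RBC", "HGB", "PLT", "HCT"),
    "echocardiography": (
        "LVDS", "LVEDD", "LA", "AO", "IVS", "LVPW", "EF", "FS", "E_A",
    ),
    "urine_test": ("U_EC", "U_ECH", "U_WBC", "U_RBC", "U_SG", "U_PH", "U_CAST"),
}

DEFAULT_EI_NAMES: tuple[str, ...] = tuple(
    name for names in EI_CATEGORIES.values() for name in names
)

#: The six model inputs of the published configuration (marker + five EIs).
MODEL_FEATURES: tuple[str, ...] = (MARKER, "weight", "age", "LVDS", "ALT", "U_EC")


@dataclass(frozen=True)
class ItemRegistry:
    """Named EI columns and their category grouping."""

    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(EI_CATEGORIES)
    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for names in self.categories.values() for n in names)

    def category_of(self, item: str) -> str:
        for cat, names in self.categories.items():
            if item in names:
                return cat
        raise KeyError(item)

    @classmethod
    def subset(cls, names: list[str] | tuple[str, ...]) -> "ItemRegistry":
        """Registry restricted to ``names`` (keeps full-registry grouping)."""
        keep = set(names)
        cats = {
            cat: tuple(n for n in items if n in keep)
            for cat, items in EI_CATEGORIES.items()
        }
        return cls(categories={c: ns for c, ns in cats.items() if ns})


DEFAULT_REGISTRY = ItemRegistry()

#: EI registry of the external-validation cohort (five model EIs only).
EXTERNAL_REGISTRY = ItemRegistry.subset(["age", "weight", "LVDS", "ALT", "U_EC"])


class SchemaError(ValueError):
    pass


class CohortValidationError(ValueError):
    pass


@dataclass
class CohortTable:
    """Participants x (marker, EIs, BMD, T-score) with a provenance tag.

    ``df`` holds columns ``id, mir194, <EIs>, bmd, t_score``.  Missing values
    (NaN) are permitted only in EI columns.
    """

    df: pd.DataFrame
    registry: ItemRegistry = field(default_factory=ItemRegistry)
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for col in _META_COLS:
            if col not in self.df.columns:
                raise SchemaError(f"mandatory column {col!r} missing")
        if len(self.df) == 0:
            raise CohortValidationError("cohort has no participants")
        ids = self.df["id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        extra = [
            c for c in self.df.columns
            if c not in _META_COLS and c not in self.registry.names
        ]
        if extra:
            raise SchemaError(f"EI columns not in registry: {extra}")
        for col in (MARKER, "bmd", "t_score"):
            if self.df[col].isna().any():
                raise CohortValidationError(f"missing values in column {col!r}")
        if (self.df["bmd"] <= 0).any():
            raise CohortValidationError("bmd must be positive")
        if (self.df[MARKER] < 0).any():
            raise CohortValidationError("marker expression must be non-negative")

    # -- convenience accessors ---------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy(dtype=object)

    @property
    def ei_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.registry.names if n in self.df.columns)

    @property
    def item_names(self) -> tuple[str, ...]:
        """Marker followed by the EI columns, in registry order."""
        return (MARKER,) + self.ei_names

    @property
    def bmd(self) -> np.ndarray:
        return self.df["bmd"].to_numpy(dtype=float)

    @property
    def t_score(self) -> np.ndarray:
        return self.df["t_score"].to_numpy(dtype=float)

    def status(self) -> list[BoneStatus]:
        return [classify_bone_status(t) for t in self.t_score]

    def status_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in BoneStatus}
        for s in self.status():
            counts[s.value] += 1
        return counts

    def risk_labels(self) -> np.ndarray:
        """Binary osteoporosis labels (1 = osteoporosis)."""
        return np.array([int(s.at_risk) for s in self.status()], dtype=int)

    def feature_matrix(self, features: list[str] | tuple[str, ...]) -> np.ndarray:
        missing = [f for f in features if f not in self.df.columns]
        if missing:
            raise KeyError(f"features absent from cohort: {missing}")
        return self.df[list(features)].to_numpy(dtype=float)

    def complete_cases(self, features: list[str] | tuple[str, ...]) -> np.ndarray:
        """Boolean mask of rows with no missing value in any model feature."""
        return ~self.df[list(features)].isna().any(axis=1).to_numpy()


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_cohort(
    path,
    registry: ItemRegistry | None = None,
    provenance: str = "file",
) -> CohortTable:
    """Read a comma-separated cohort file.

    The header must name ``id, mir194, <EI columns>, bmd, t_score``.  Cells
    that do not parse as numbers become missing values with a logged warning;
    empty fields are missing values.
    """
    registry = registry or DEFAULT_REGISTRY
    raw = pd.read_csv(path, dtype=str)
    for col in _META_COLS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    unknown = [
        c for c in raw.columns if c not in _META_COLS and c not in registry.names
    ]
    if unknown:
        raise SchemaError(f"EI columns not in registry: {unknown}")
    if len(raw) == 0:
        raise CohortValidationError(f"{path}: no participants")
    out = pd.DataFrame({"id": raw["id"].astype(str)})
    for col in raw.columns:
        if col == "id":
            continue
        numeric = pd.to_numeric(raw[col], errors="coerce").astype(float)
        bad = numeric.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            logger.warning(
                "%s: %d non-numeric cell(s) in column %r set to missing",
                path, int(bad.sum()), col,
            )
        out[col] = numeric
    return CohortTable(out, registry=registry, provenance=provenance)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV (missing values as empty fields)."""
    cols = ["id", MARKER, *cohort.ei_names, "bmd", "t_score"]
    cohort.df[cols].to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

class DegenerateFeatureError(ValueError):
    pass


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned on a reference cohort.

    Applying the params maps reference values into [0, 1]; values from an
    external cohort outside the reference range are clipped so they remain
    valid model inputs.
    """

    bounds: dict[str, tuple[float, float]]

    def apply(self, value, feature: str):
        if feature not in self.bounds:
            raise KeyError(f"no normalization fitted for feature {feature!r}")
        lo, hi = self.bounds[feature]
        return np.clip((np.asarray(value, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def invert(self, unit_value, feature: str):
        """Map a [0,1] value back to the feature's original scale."""
        lo, hi = self.bounds[feature]
        return lo + np.asarray(unit_value, dtype=float) * (hi - lo)

    def transform(self, cohort: CohortTable, features) -> np.ndarray:
        X = cohort.feature_matrix(features)
        cols = [self.apply(X[:, j], f) for j, f in enumerate(features)]
        return np.column_stack(cols)


def fit_minmax(cohort: CohortTable, features) -> NormalizationParams:
    """Learn per-feature (min, max) on a reference cohort.

    Each feature needs at least two distinct non-missing values; a constant
    feature is refused rather than silently dividing by zero.
    """
    bounds: dict[str, tuple[float, float]] = {}
    for f in features:
        vals = cohort.df[f].dropna().to_numpy(dtype=float)
        if vals.size < 2 or np.nanmin(vals) == np.nanmax(vals):
            raise DegenerateFeatureError(
                f"feature {f!r} has fewer than 2 distinct values"
            )
        bounds[f] = (float(vals.min()), float(vals.max()))
    return NormalizationParams(bounds)
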