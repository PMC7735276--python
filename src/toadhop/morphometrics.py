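"""Size-corrected shape scores.

Each linear trait is regressed on snout-vent length (SVL) by ordinary least
squares within a fitting group, and the residuals serve as size-corrected
shape measures. Body mass is excluded from the shape-trait set by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, ParameterError

#: Linear measures (mm) used as shape traits.
LINEAR_TRAITS = (
    "femur", "tibiofibula", "hindfoot", "forefoot",
    "head_width", "humerus", "radioulna",
)

GROUPINGS = ("pooled", "by-generation", "by-class")

#: Field-classification cutoff: animals below this SVL (mm) cannot be sexed
#: reliably and are scored as juveniles.
JUVENILE_SVL_MM = 90.0


@dataclass
class MorphologyRecord:
    """One toad's linear measures and cohort labels (lengths mm, mass g)."""

    animal_id: str
    population: str
    invasion_category: str  # "range-core" | "invasion-front"
    sex_class: str          # "female" | "male" | "juvenile"
    generation: str         # "F0" | "F1"
    svl: float
    mass: float
    femur: float
    tibiofibula: float
    hindfoot: float
    forefoot: float
    head_width: float
    humerus: float
    radioulna: float

    def __post_init__(self) -> None:
        if self.invasion_category not in ("range-core", "invasion-front"):
            raise ParameterError(f"unknown invasion_category {self.invasion_category!r}")
        if self.sex_class not in ("female", "male", "juvenile"):
            raise ParameterError(f"unknown sex_class {self.sex_class!r}")
        if self.generation not in ("F0", "F1"):
            raise ParameterError(f"unknown generation {self.generation!r}")
        if self.svl <= 0 or self.mass <= 0:
            raise ParameterError("svl and mass must be positive")
        for trait in LINEAR_TRAITS:
            if getattr(self, trait) <= 0:
                raise ParameterError(f"{trait} must be positive")
        if self.sex_class == "juvenile" and self.svl >= JUVENILE_SVL_MM:
            raise ParameterError(
                f"juvenile with SVL {self.svl:.1f} mm >= {JUVENILE_SVL_MM} mm"
            )


def records_to_frame(records: list[MorphologyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in (
            "animal_id", "population", "invasion_category", "generation",
            "svl", "mass", *LINEAR_TRAITS)}
        d["class"] = r.sex_class
        rows.append(d)
    return pd.DataFrame(rows)


@dataclass
class ShapeResiduals:
    """Residual shape scores for one trait.

    ``residuals`` is indexed by animal_id (trait units, mm); ``fits`` maps
    each fitting-group label to its ``(slope, intercept)`` of the
    trait-on-SVL regression.
    """

    trait: str
    grouping: str
    residuals: pd.Series
    fits: dict


def _group_labels(df: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "pooled":
        return pd.Series("all", index=df.index)
    if grouping == "by-generation":
        return df["generation"].astype(str)
    if grouping == "by-class":
        return df["class"].astype(str)
    raise ParameterError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")


def shape_residuals(
    morphology: pd.DataFrame | list[MorphologyRecord],
    trait: str,
    grouping: str = "by-generation",
) -> ShapeResiduals:
    """OLS residuals of ``trait`` on SVL within each fitting group.

    Requires at least 3 records and positive SVL variance per group.
    """
    df = records_to_frame(morphology) if isinstance(morphology, list) else morphology
    if trait not in df.columns:
        raise ParameterError(f"unknown trait {trait!r}")
    labels = _group_labels(df, grouping)
    resid = pd.Series(np.nan, index=df["animal_id"], name=f"resid_{trait}", dtype=float)
    fits = {}
    for label, idx in df.groupby(labels).groups.items():
        sub = df.loc[idx]
        if len(sub) < 3:
            raise DegenerateFitError(
                f"group {label!r} has {len(sub)} records; need >=3 for the "
                f"trait-on-SVL regression"
            )
        svl = sub["svl"].to_numpy(dtype=float)
        y = sub[trait].to_numpy(dtype=float)
        if np.var(svl) == 0:
            raise DegenerateFitError(f"group {label!r} has zero SVL variance")
        slope, intercept = np.polyfit(svl, y, 1)
        fits[label] = (float(slope), float(intercept))
        resid.loc[sub["animal_id"].to_numpy()] = y - (slope * svl + intercept)
    return ShapeResiduals(trait=trait, grouping=grouping, residuals=resid, fits=fits)


def residual_table(
    morphology: pd.DataFrame | list[MorphologyRecord],
    traits: tuple[str, ...] = LINEAR_TRAITS,
    grouping: str = "by-generation",
) -> pd.DataFrame:
    """Residual scores for several traits, one column per trait."""
    df = records_to_frame(morphology) if isinstance(morphology, list) else morphology
    out = pd.DataFrame({"animal_id": df["animal_id"]}).set_index("animal_id")
    for trait in traits:
        out[f"resid_{trait}"] = shape_residuals(df, trait, grouping).residuals
    return out.reset_index()
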