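"""DAS28-CRP scoring, activity staging and item-level feature expansion.

The DAS28-CRP is a weighted sum of four components measured over 28
predefined joints::

    DAS28-CRP = 0.56 * sqrt(TJC28) + 0.28 * sqrt(SJC28)
                + 0.36 * ln(CRP + 1) + 0.014 * GH + 0.96

with the tender joint count TJC28 and swollen joint count SJC28 in 0..28,
C-reactive protein CRP in mg/L and the patient global health rating GH on a
0-100 mm visual analogue scale.  Disease activity is staged from the score:
remission (< 2.6), low (2.6 to < 3.2), moderate (3.2 to 5.1) and high
(> 5.1); the 5.1 boundary itself counts as moderate.

The weights and cut-offs are exposed as overridable constant sets
(:class:`ScoreWeights`, :class:`StageThresholds`) so that variant
conventions can be plugged in without touching the scoring code.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .joints import (
    COMPONENT_NAMES,
    CRP_COLUMN,
    FEATURE_NAMES_58,
    GH_COLUMN,
    JOINT_NAMES,
    SWOLLEN_COLUMNS,
    TENDER_COLUMNS,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientRecord

__all__ = [
    "ActivityStage",
    "DAS28Components",
    "ScoreWeights",
    "StageThresholds",
    "components_of",
    "das28_crp",
    "expand_items",
    "score_frame",
    "stage",
]


class DomainError(ValueError):
    """An input value lies outside the domain of the scoring functions."""


class SchemaError(KeyError):
    """A record or table is missing a required key/column."""


@dataclass(frozen=True)
class ScoreWeights:
    """Coefficient set of the DAS28-CRP formula (standard published values)."""

    tender: float = 0.56
    swollen: float = 0.28
    crp: float = 0.36
    gh: float = 0.014
    intercept: float = 0.96


DEFAULT_WEIGHTS = ScoreWeights()


class ActivityStage(enum.IntEnum):
    """Ordered disease-activity stages (remission < low < moderate < high)."""

    REMISSION = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class StageThresholds:
    """DAS28-CRP cut-offs between activity stages.

    ``remission_below`` and ``low_below`` are exclusive upper bounds;
    ``moderate_upto`` is inclusive (a score exactly at it is moderate).
    """

    remission_below: float = 2.6
    low_below: float = 3.2
    moderate_upto: float = 5.1


DEFAULT_THRESHOLDS = StageThresholds()


@dataclass(frozen=True)
class DAS28Components:
    """The four components entering the DAS28-CRP."""

    tjc28: int
    sjc28: int
    crp: float
    gh: float

    def validate(self) -> None:
        if not 0 <= self.tjc28 <= 28:
            raise DomainError(f"tjc28 must be in 0..28, got {self.tjc28}")
        if not 0 <= self.sjc28 <= 28:
            raise DomainError(f"sjc28 must be in 0..28, got {self.sjc28}")
        if not self.crp >= 0:
            raise DomainError(f"crp must be >= 0 mg/L, got {self.crp}")
        if not 0 <= self.gh <= 100:
            raise DomainError(f"gh must be in [0, 100] mm, got {self.gh}")


def das28_crp(components: DAS28Components, weights: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Compute the DAS28-CRP score from its four components.

    Strictly increasing in every component; ``(0, 0, 0, 0)`` evaluates to
    the intercept.
    """
    components.validate()
    return (
        weights.tender * math.sqrt(components.tjc28)
        + weights.swollen * math.sqrt(components.sjc28)
        + weights.crp * math.log(components.crp + 1.0)
        + weights.gh * components.gh
        + weights.intercept
    )


def stage(score: float, thresholds: StageThresholds = DEFAULT_THRESHOLDS) -> ActivityStage:
    """Map a DAS28-CRP score to its activity stage."""
    if score < 0:
        raise DomainError(f"DAS28-CRP score must be nonnegative, got {score}")
    if score < thresholds.remission_below:
        return ActivityStage.REMISSION
    if score < thresholds.low_below:
        return ActivityStage.LOW
    if score <= thresholds.moderate_upto:
        return ActivityStage.MODERATE
    return ActivityStage.HIGH


def components_of(record: "PatientRecord") -> DAS28Components:
    """Derive the four score components from a patient record.

    The joint counts are the numbers of true flags; CRP and GH pass through.
    """
    for joint in JOINT_NAMES:
        if joint not in record.tender:
            raise SchemaError(f"missing tender flag for joint '{joint}'")
        if joint not in record.swollen:
            raise SchemaError(f"missing swollen flag for joint '{joint}'")
    comps = DAS28Components(
        tjc28=sum(bool(record.tender[j]) for j in JOINT_NAMES),
        sjc28=sum(bool(record.swollen[j]) for j in JOINT_NAMES),
        crp=float(record.crp),
        gh=float(record.gh),
    )
    comps.validate()
    return comps


def expand_items(record: "PatientRecord") -> pd.Series:
    """Expand a record into the d = 58 item-level feature vector.

    Order: 28 tender flags, 28 swollen flags, CRP, GH — indexed by
    :data:`das28ml.joints.FEATURE_NAMES_58`.
    """
    values = np.empty(58)
    for i, joint in enumerate(JOINT_NAMES):
        if joint not in record.tender:
            raise SchemaError(f"missing tender flag for joint '{joint}'")
        if joint not in record.swollen:
            raise SchemaError(f"missing swollen flag for joint '{joint}'")
        values[i] = float(bool(record.tender[joint]))
        values[28 + i] = float(bool(record.swollen[joint]))
    values[56] = float(record.crp)
    values[57] = float(record.gh)
    return pd.Series(values, index=list(FEATURE_NAMES_58))


def score_frame(
    cohort: pd.DataFrame,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    thresholds: StageThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score a cohort table: add component, ``das28_crp`` and ``stage`` columns.

    ``cohort`` follows the cohort CSV schema (tender_*/swollen_* flags plus
    ``crp_mg_l`` and ``gh_mm``).  Returns a new frame; the input is untouched.
    """
    for col in (*TENDER_COLUMNS, *SWOLLEN_COLUMNS, CRP_COLUMN, GH_COLUMN):
        if col not in cohort.columns:
            raise SchemaError(f"missing column '{col}'")
    out = cohort.copy()
    tjc = cohort[list(TENDER_COLUMNS)].to_numpy().astype(bool).sum(axis=1)
    sjc = cohort[list(SWOLLEN_COLUMNS)].to_numpy().astype(bool).sum(axis=1)
    crp = cohort[CRP_COLUMN].to_numpy(dtype=float)
    gh = cohort[GH_COLUMN].to_numpy(dtype=float)
    if (crp < 0).any():
        raise DomainError("crp_mg_l must be >= 0")
    if ((gh < 0) | (gh > 100)).any():
        raise DomainError("gh_mm must be in [0, 100]")
    out["tjc28"] = tjc
    out["sjc28"] = sjc
    out["crp"] = crp
    out["gh"] = gh
    out["das28_crp"] = (
        weights.tender * np.sqrt(tjc)
        + weights.swollen * np.sqrt(sjc)
        + weights.crp * np.log(crp + 1.0)
        + weights.gh * gh
        + weights.intercept
    )
    out["stage"] = [stage(s, thresholds).label for s in out["das28_crp"]]
    return out


def components_matrix(scored: pd.DataFrame) -> pd.DataFrame:
    """Return the n x 4 component matrix (tjc28, sjc28, crp, gh) of a scored frame."""
    missing = [c for c in COMPONENT_NAMES if c not in scored.columns]
    if missing:
        raise SchemaError(f"missing component columns {missing}; run score_frame first")
    return scored[list(COMPONENT_NAMES)].astype(float)
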