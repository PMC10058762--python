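"""Dietary guidelines as data, and the Dietary Non-Adherence Score (DNAS).

The DNAS of an intake vector x = (x_1, ..., x_n) against a guideline
reference y = (y_1, ..., y_n) is the Euclidean distance

    DNAS(x, y) = sqrt( sum_i (x_i - y_i)^2 )

computed on a normalized scale (by default each food group is divided by
its guideline reference, so the reference point maps to the all-ones
vector and the score is dimensionless).  A score of 0 means the diet sits
exactly at the recommended pattern; larger scores mean larger deviation
from it, jointly over all food groups rather than group by group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GuidelineSpec",
    "SampleStats",
    "load_guideline",
    "default_guideline",
    "normalize_intake",
    "compute_dnas",
    "score_panel",
]

Metric = Literal["euclidean", "manhattan"]
Mode = Literal["ratio", "grams", "zscore"]

#: Columns every intake panel must carry besides the food groups.
PANEL_ID_COLS = ["subject_id", "round", "age_years", "energy_kcal"]


class GuidelineError(ValueError):
    """Raised when a guideline table or intake panel fails validation."""


@dataclass(frozen=True)
class GuidelineSpec:
    """Per-food-group recommended intake ranges and reference values.

    Parameters
    ----------
    groups
        Ordered food-group names; must be unique.
    low_g, high_g
        Recommended minimum / maximum intake, g/day, per group.
    reference_g
        Reference intake per group (the guideline target the score is
        measured against).  Defaults to the midpoint of [low, high].
    """

    groups: tuple[str, ...]
    low_g: np.ndarray
    high_g: np.ndarray
    reference_g: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        low = np.asarray(self.low_g, dtype=float)
        high = np.asarray(self.high_g, dtype=float)
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "low_g", low)
        object.__setattr__(self, "high_g", high)
        if self.reference_g is None:
            object.__setattr__(self, "reference_g", (low + high) / 2.0)
        else:
            object.__setattr__(
                self, "reference_g", np.asarray(self.reference_g, dtype=float)
            )
        ref = self.reference_g
        n = len(self.groups)
        if n < 1:
            raise GuidelineError("guideline needs at least one food group")
        if len(set(self.groups)) != n:
            dupes = sorted({g for g in self.groups if list(self.groups).count(g) > 1})
            raise GuidelineError(f"duplicated food-group names: {dupes}")
        for arr, name in ((low, "low"), (high, "high"), (ref, "reference")):
            if arr.shape != (n,):
                raise GuidelineError(f"{name} must have one value per group")
            if not np.all(np.isfinite(arr)):
                raise GuidelineError(f"non-finite value in column '{name}'")
        bad = np.flatnonzero(low < 0)
        if bad.size:
            raise GuidelineError(
                f"negative recommended minimum for group '{self.groups[bad[0]]}'"
            )
        bad = np.flatnonzero(low > high)
        if bad.size:
            raise GuidelineError(
                f"low > high for group '{self.groups[bad[0]]}'"
            )
        bad = np.flatnonzero((ref < low) | (ref > high))
        if bad.size:
            raise GuidelineError(
                f"reference outside [low, high] for group '{self.groups[bad[0]]}'"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.groups),
                "low": self.low_g,
                "high": self.high_g,
                "reference": self.reference_g,
            }
        )


@dataclass(frozen=True)
class SampleStats:
    """Per-group sample mean/SD, the fitting context for z-score scaling."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, spec: GuidelineSpec) -> "SampleStats":
        grams = panel[list(spec.groups)].to_numpy(dtype=float)
        sd = grams.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise GuidelineError("zero-variance food group; z-score scaling undefined")
        return cls(mean=grams.mean(axis=0), sd=sd)


def load_guideline(path: str | Path) -> GuidelineSpec:
    """Read a guideline CSV with columns ``group,low,high[,reference]``.

    ``reference`` defaults to the range midpoint when absent.  Validation
    errors name the offending row.
    """
    df = pd.read_csv(path)
    required = {"group", "low", "high"}
    missing = required - set(df.columns)
    if missing:
        raise GuidelineError(f"guideline file {path}: missing columns {sorted(missing)}")
    ref = df["reference"].to_numpy(dtype=float) if "reference" in df.columns else None
    return GuidelineSpec(
        groups=tuple(df["group"].astype(str)),
        low_g=df["low"].to_numpy(dtype=float),
        high_g=df["high"].to_numpy(dtype=float),
        reference_g=ref,
    )


def default_guideline() -> GuidelineSpec:
    """The bundled 10-group guideline table (editable; ranges in g/day).

    The numeric ranges shipped here are plausible placeholder values for
    the ten food groups; analyses against a specific guideline edition
    should load a verified table with :func:`load_guideline`.
    """
    with resources.as_file(
        resources.files("dnas.data").joinpath("cdg_guideline.csv")
    ) as p:
        return load_guideline(p)


def _reference_normalized(spec: GuidelineSpec, mode: Mode, stats: SampleStats | None):
    if mode == "ratio":
        return np.ones(spec.n_groups)
    if mode == "grams":
        return spec.reference_g.copy()
    if mode == "zscore":
        if stats is None:
            raise GuidelineError("zscore mode requires fitted SampleStats")
        return (spec.reference_g - stats.mean) / stats.sd
    raise GuidelineError(f"unknown normalization mode: {mode!r}")


def normalize_intake(
    grams: Sequence[float] | np.ndarray,
    spec: GuidelineSpec,
    mode: Mode = "ratio",
    stats: SampleStats | None = None,
) -> np.ndarray:
    """Map a grams/day vector (aligned to ``spec.groups``) onto the scoring scale.

    ``ratio``  — grams / reference per group (reference maps to 1).
    ``grams``  — raw grams, unchanged.
    ``zscore`` — (grams - sample mean) / sample SD, needing ``stats``.
    """
    x = np.asarray(grams, dtype=float)
    if x.shape[-1] != spec.n_groups:
        raise GuidelineError(
            f"intake vector has {x.shape[-1]} entries, guideline has {spec.n_groups}"
        )
    if np.any(x < 0):
        raise GuidelineError("negative intake")
    if mode == "ratio":
        zero = np.flatnonzero(spec.reference_g == 0)
        if zero.size:
            raise GuidelineError(
                f"reference is 0 for group '{spec.groups[zero[0]]}'; ratio scaling "
                "needs a positive reference — supply one or use a group-specific scale"
            )
        return x / spec.reference_g
    if mode == "grams":
        return x.copy()
    if mode == "zscore":
        if stats is None:
            raise GuidelineError("zscore mode requires fitted SampleStats")
        return (x - stats.mean) / stats.sd
    raise GuidelineError(f"unknown normalization mode: {mode!r}")


def compute_dnas(
    grams: Sequence[float] | np.ndarray,
    spec: GuidelineSpec,
    metric: Metric = "euclidean",
    mode: Mode = "ratio",
    stats: SampleStats | None = None,
) -> float:
    """Distance between a normalized intake vector and the guideline reference.

    ``euclidean`` gives sqrt(sum_i (x_i - y_i)^2) over the food groups on
    the normalized scale; ``manhattan`` gives sum_i |x_i - y_i|.
    """
    x = normalize_intake(grams, spec, mode=mode, stats=stats)
    y = _reference_normalized(spec, mode, stats)
    d = x - y
    if not np.all(np.isfinite(d)):
        raise GuidelineError("non-finite normalized intake entry")
    if metric == "euclidean":
        return float(np.sqrt(np.sum(d * d)))
    if metric == "manhattan":
        return float(np.sum(np.abs(d)))
    raise GuidelineError(f"unknown metric: {metric!r}")


def score_panel(
    panel: pd.DataFrame,
    spec: GuidelineSpec,
    metric: Metric = "euclidean",
    mode: Mode = "ratio",
    stats: SampleStats | None = None,
) -> pd.DataFrame:
    """Score every (subject, round) row of a long-format intake panel.

    Returns ``subject_id, round, age_years, score`` ordered by subject
    then round; the row count is preserved.  Duplicate (subject, round)
    pairs are an error.
    """
    for col in ("subject_id", "round", "age_years"):
        if col not in panel.columns:
            raise GuidelineError(f"intake panel missing column '{col}'")
    missing = [g for g in spec.groups if g not in panel.columns]
    if missing:
        raise GuidelineError(f"intake panel missing food-group columns: {missing}")
    dup = panel.duplicated(subset=["subject_id", "round"])
    if dup.any():
        first = panel.loc[dup, ["subject_id", "round"]].iloc[0]
        raise GuidelineError(
            f"duplicated (subject, round): ({first['subject_id']}, {first['round']})"
        )
    if len(panel) == 0:
        return pd.DataFrame(columns=["subject_id", "round", "age_years", "score"])
    if mode == "zscore" and stats is None:
        stats = SampleStats.from_panel(panel, spec)

    grams = panel[list(spec.groups)].to_numpy(dtype=float)
    if np.any(~np.isfinite(grams)):
        raise GuidelineError("missing or non-finite food-group amount in panel")
    if np.any(grams < 0):
        raise GuidelineError("negative intake in panel")
    # vectorized version of compute_dnas over rows
    if mode == "ratio":
        xn = grams / spec.reference_g  # zero-reference guard below
        if np.any(spec.reference_g == 0):
            zero = np.flatnonzero(spec.reference_g == 0)
            raise GuidelineError(
                f"reference is 0 for group '{spec.groups[zero[0]]}' in ratio mode"
            )
    elif mode == "grams":
        xn = grams
    else:
        xn = (grams - stats.mean) / stats.sd  # type: ignore[union-attr]
    y = _reference_normalized(spec, mode, stats)
    d = xn - y
    if metric == "euclidean":
        scores = np.sqrt(np.sum(d * d, axis=1))
    elif metric == "manhattan":
        scores = np.sum(np.abs(d), axis=1)
    else:
        raise GuidelineError(f"unknown metric: {metric!r}")
    out = panel[["subject_id", "round", "age_years"]].copy()
    out["score"] = scores
    out = out.sort_values(["subject_id", "round"]).reset_index(drop=True)
    return out
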