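"""Tumor-growth quantification: per-mouse AUC and tumor rejection scores.

Growth is summarized per mouse by the trapezoidal area under the tumor-area
curve between the first and last observation (no extrapolation).  Each mouse
is categorized from its final observed area: complete rejection (final area at
or below ``complete_threshold``, default 0), partial control (at or below
``partial_threshold``) or progression.  The tumor rejection score (TRS) of a
group of n mice is

    TRS = 5 * (n_complete + w * n_partial) / n

rounded to one decimal, so 5.0 means every mouse rejected the tumor and 0
means none did; the partial-control weight ``w`` (default 0.5) sets how much
credit near-complete rejection earns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("complete_rejection", "partial_control", "progression")


@dataclass(frozen=True)
class GrowthCurve:
    """One mouse's tumor areas over strictly increasing days."""

    mouse: str
    days: tuple[float, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.areas):
            raise ValueError("days and areas must have equal length")
        d = np.asarray(self.days, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(np.asarray(self.areas, dtype=float) < 0):
            raise ValueError("areas must be non-negative")


def curves_from_table(df: pd.DataFrame) -> dict[tuple[str, str], GrowthCurve]:
    """Split a (group, mouse, day, area) table into per-mouse curves."""
    out = {}
    for (group, mouse), sub in df.groupby(["group", "mouse"], sort=False):
        sub = sub.sort_values("day")
        out[(group, mouse)] = GrowthCurve(
            mouse=mouse, days=tuple(sub["day"]), areas=tuple(sub["area"])
        )
    return out


def growth_auc(curve: GrowthCurve) -> float:
    """Trapezoidal integral of tumor area over the observed day range."""
    if len(curve.days) < 2:
        raise ValueError("AUC requires at least two timepoints")
    return float(np.trapezoid(curve.areas, curve.days))


def classify_outcome(
    curve: GrowthCurve,
    complete_threshold: float = 0.0,
    partial_threshold: float = 10.0,
) -> str:
    """Outcome category from the final observed area."""
    if not 0.0 <= complete_threshold < partial_threshold:
        raise ValueError("require 0 <= complete_threshold < partial_threshold")
    final = curve.areas[-1]
    if final <= complete_threshold:
        return "complete_rejection"
    if final <= partial_threshold:
        return "partial_control"
    return "progression"


def tumor_rejection_score(outcomes: Sequence[str], partial_weight: float = 0.5) -> float:
    """TRS on the 0-5 scale, one-decimal precision."""
    if not 0.0 <= partial_weight <= 1.0:
        raise ValueError("partial_weight must lie in [0, 1]")
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one mouse")
    unknown = set(outcomes) - set(OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcomes: {sorted(unknown)}")
    n_complete = outcomes.count("complete_rejection")
    n_partial = outcomes.count("partial_control")
    return round(5.0 * (n_complete + partial_weight * n_partial) / len(outcomes), 1)


def summarize_groups(
    df: pd.DataFrame,
    complete_threshold: float = 0.0,
    partial_threshold: float = 10.0,
    partial_weight: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse AUC/outcome table and per-group TRS summary."""
    curves = curves_from_table(df)
    mouse_rows = []
    for (group, mouse), curve in curves.items():
        mouse_rows.append(
            {
                "group": group,
                "mouse": mouse,
                "auc": growth_auc(curve),
                "final_area": curve.areas[-1],
                "outcome": classify_outcome(curve, complete_threshold, partial_threshold),
            }
        )
    per_mouse = pd.DataFrame(mouse_rows)
    group_rows = []
    for group, sub in per_mouse.groupby("group", sort=False):
        outcomes = list(sub["outcome"])
        group_rows.append(
            {
                "group": group,
                "n_mice": len(sub),
                "n_complete": outcomes.count("complete_rejection"),
                "n_partial": outcomes.count("partial_control"),
                "n_progression": outcomes.count("progression"),
                "mean_auc": float(sub["auc"].mean()),
                "trs": tumor_rejection_score(outcomes, partial_weight),
            }
        )
    return per_mouse, pd.DataFrame(group_rows)
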