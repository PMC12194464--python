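"""Lipid/water peak assignment, the structural biomarker and its trajectory.

The biomarker is the ratio of the fitted lipid peak height (center in the
12–15.5 nm^-1 window) to the fitted water peak height (16.5–20.5 nm^-1),
computed per measurement inside the 10–20.5 nm^-1 analysis window. With
this direction the ratio *decreases* as disease progresses. Trajectories
aggregate grid positions to subject means, then subjects to group mean and
standard deviation (n = animals), ordered Control, Day2, Day4, Day7, Day16,
with temporally matched control statistics alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .model import FitResult, GaussianPeak

__all__ = [
    "RATIO_DIRECTION",
    "BiomarkerRecord",
    "TrajectoryPoint",
    "Trajectory",
    "assign_peaks",
    "compute_biomarker",
    "match_controls",
    "build_trajectory",
]

#: printed in every report header so the ratio direction is never silently inverted.
RATIO_DIRECTION = "lipid/water"

GROUP_ORDER = ("Control", "Day2", "Day4", "Day7", "Day16")


def _day_of(group: str) -> Optional[int]:
    digits = "".join(ch for ch in group if ch.isdigit())
    return int(digits) if digits else None


def assign_peaks(
    result: FitResult,
    lipid_window: tuple[float, float] = defaults.LIPID_WINDOW,
    water_window: tuple[float, float] = defaults.WATER_WINDOW,
) -> tuple[Optional[GaussianPeak], Optional[GaussianPeak]]:
    """Assign fitted peaks to (lipid, water) by center window.

    The designated broad auxiliary peak is never assigned. When several
    candidates fall in one window the larger amplitude wins. A missing
    candidate returns None in that slot.
    """
    candidates = [p for p in result.params.peaks if p.label != "broad"]

    def pick(window: tuple[float, float]) -> Optional[GaussianPeak]:
        inside = [p for p in candidates if window[0] <= p.center <= window[1]]
        if not inside:
            return None
        return max(inside, key=lambda p: p.amplitude)

    return pick(lipid_window), pick(water_window)


@dataclass
class BiomarkerRecord:
    """Per-measurement lipid/water structural biomarker."""

    subject_id: Optional[str]
    group: Optional[str]
    lobe: Optional[str]
    pos_row: Optional[int]
    pos_col: Optional[int]
    sacrifice_day: Optional[int]
    lipid_height: Optional[float]
    water_height: Optional[float]
    lipid_height_err: Optional[float]
    water_height_err: Optional[float]
    lipid_area: Optional[float]
    water_area: Optional[float]
    ratio: Optional[float]
    ratio_err: Optional[float]
    ok: bool
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_biomarker(result: FitResult) -> BiomarkerRecord:
    """Lipid/water peak-height ratio with first-order error propagation.

    (delta r / r)^2 = (delta A_l / A_l)^2 + (delta A_w / A_w)^2. Records
    with unassignable peaks, a failed fit, or non-positive water height are
    flagged not-ok with a reason instead of raising.
    """
    meta = result.profile_meta
    base = dict(
        subject_id=meta.get("subject_id"),
        group=meta.get("group"),
        lobe=meta.get("lobe"),
        pos_row=meta.get("pos_row"),
        pos_col=meta.get("pos_col"),
        sacrifice_day=meta.get("sacrifice_day"),
    )

    def bad(reason: str, **kw) -> BiomarkerRecord:
        fields = dict(
            lipid_height=None, water_height=None,
            lipid_height_err=None, water_height_err=None,
            lipid_area=None, water_area=None,
            ratio=None, ratio_err=None,
        )
        fields.update(kw)
        return BiomarkerRecord(**base, **fields, ok=False, reason=reason)

    if not result.converged:
        return bad("fit did not converge")
    lipid, water = assign_peaks(result)
    if lipid is None or water is None:
        missing = "lipid" if lipid is None else "water"
        return bad(f"no assignable {missing} peak")
    if not water.amplitude > 0:
        return bad(
            "non-positive water height",
            lipid_height=lipid.amplitude, water_height=water.amplitude,
        )

    d_l = d_w = None
    if result.uncertainties is not None:
        by_label = {u.label: u for u in result.uncertainties.peaks}
        ul, uw = by_label.get(lipid.label), by_label.get(water.label)
        d_l = None if ul is None else ul.amplitude
        d_w = None if uw is None else uw.amplitude
    ratio = lipid.amplitude / water.amplitude
    ratio_err = None
    if d_l is not None and d_w is not None and lipid.amplitude > 0:
        ratio_err = ratio * np.hypot(d_l / lipid.amplitude, d_w / water.amplitude)
    return BiomarkerRecord(
        **base,
        lipid_height=lipid.amplitude,
        water_height=water.amplitude,
        lipid_height_err=d_l,
        water_height_err=d_w,
        lipid_area=lipid.area,
        water_area=water.area,
        ratio=ratio,
        ratio_err=ratio_err,
        ok=True,
    )


def _records_frame(records: Sequence[BiomarkerRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in records])
    return df[df["ok"]] if len(df) else df


def match_controls(records: Sequence[BiomarkerRecord]) -> dict[int, dict]:
    """Control-group biomarker statistics matched to each experimental day.

    Controls are matched by their sacrifice day; a day with no matching
    controls falls back to all controls and is flagged. Statistics are over
    control subject means (positions averaged first).
    """
    df = _records_frame(records)
    ctrl = df[df["group"] == "Control"] if len(df) else df
    if len(ctrl) == 0:
        raise ValueError("no control records to match")
    subj = ctrl.groupby(["subject_id", "sacrifice_day"], dropna=False)["ratio"].mean()
    subj = subj.reset_index()
    days = sorted(
        {d for d in (_day_of(g) for g in df["group"].unique()) if d is not None}
    )
    out: dict[int, dict] = {}
    for day in days:
        sel = subj[subj["sacrifice_day"] == day]
        fallback = len(sel) == 0
        if fallback:
            sel = subj
        vals = sel["ratio"].to_numpy(dtype=float)
        out[day] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
            "fallback": fallback,
        }
    return out


@dataclass
class TrajectoryPoint:
    """Group-level biomarker summary for one (group, lobe)."""

    group: str
    lobe: str
    mean_ratio: float
    sd_ratio: float
    n_subjects: int
    mean_lipid_height: float
    mean_water_height: float
    sd_lipid_height: float
    sd_water_height: float
    control_mean: Optional[float] = None
    control_sd: Optional[float] = None
    control_fallback: Optional[bool] = None


@dataclass
class Trajectory:
    """Ordered biomarker time course per lobe; ratio direction lipid/water."""

    points: list[TrajectoryPoint]
    direction: str = RATIO_DIRECTION

    def per_lobe(self, lobe: str) -> list[TrajectoryPoint]:
        return [p for p in self.points if p.lobe == lobe]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.points])


def build_trajectory(records: Sequence[BiomarkerRecord]) -> Trajectory:
    """Aggregate biomarker records into ordered group trajectories per lobe.

    Grid positions are averaged within subject first; the group mean and
    standard deviation are then taken over subjects (n = animals, sd = 0
    when n = 1). Non-ok records are excluded. Matched-control statistics
    are attached to each experimental day's point.
    """
    df = _records_frame(records)
    if len(df) == 0:
        raise ValueError("no usable biomarker records")
    try:
        controls = match_controls(records)
    except ValueError:
        controls = {}
    subj = (
        df.groupby(["group", "lobe", "subject_id"], dropna=False)[
            ["ratio", "lipid_height", "water_height"]
        ]
        .mean()
        .reset_index()
    )
    points: list[TrajectoryPoint] = []
    groups_present = [g for g in GROUP_ORDER if g in set(subj["group"])]
    groups_present += sorted(set(subj["group"]) - set(GROUP_ORDER))
    for lobe in sorted(set(subj["lobe"])):
        for group in groups_present:
            sel = subj[(subj["group"] == group) & (subj["lobe"] == lobe)]
            if len(sel) == 0:
                continue
            n = len(sel)

            def _sd(col: str) -> float:
                return float(sel[col].std(ddof=1)) if n > 1 else 0.0

            day = _day_of(group)
            ctrl = controls.get(day) if day is not None else None
            points.append(
                TrajectoryPoint(
                    group=group,
                    lobe=lobe,
                    mean_ratio=float(sel["ratio"].mean()),
                    sd_ratio=_sd("ratio"),
                    n_subjects=n,
                    mean_lipid_height=float(sel["lipid_height"].mean()),
                    mean_water_height=float(sel["water_height"].mean()),
                    sd_lipid_height=_sd("lipid_height"),
                    sd_water_height=_sd("water_height"),
                    control_mean=None if ctrl is None else ctrl["mean"],
                    control_sd=None if ctrl is None else ctrl["sd"],
                    control_fallback=None if ctrl is None else ctrl["fallback"],
                )
            )
    return Trajectory(points)
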