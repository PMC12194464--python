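"""Cleaning, background subtraction, windowing, L1 normalization, averaging.

The declared pipeline order for 1D profiles is: remove_nan ->
subtract_background (optional) -> restrict_q -> l1_normalize ->
clean_profiles -> group_average_profiles. L1 normalization divides
intensity and sigma by the total absolute intensity over the profile's
current q window, so profiles become comparable across exposures while
keeping their relative shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import Profile1D

__all__ = [
    "CleaningCriteria",
    "CleaningReport",
    "subtract_background",
    "remove_nan",
    "restrict_q",
    "l1_normalize",
    "clean_profiles",
    "group_average_profiles",
]


def subtract_background(profile: Profile1D, background: Profile1D) -> Profile1D:
    """Pointwise background subtraction with quadrature error combination."""
    if not profile.same_grid(background):
        raise ValueError("profile and background must share an identical q grid")
    return profile.replace(
        intensity=profile.intensity - background.intensity,
        sigma=np.hypot(profile.sigma, background.sigma),
    )


def remove_nan(profile: Profile1D) -> Profile1D:
    """Drop rows with non-finite intensity or sigma; q ordering preserved."""
    keep = np.isfinite(profile.intensity) & np.isfinite(profile.sigma)
    if not keep.any():
        raise ValueError("profile has no finite rows")
    if keep.all():
        return profile
    return profile.select(keep)


def restrict_q(profile: Profile1D, q_min: float, q_max: float) -> Profile1D:
    """Keep rows with q_min <= q <= q_max (closed interval)."""
    if not q_min < q_max:
        raise ValueError("q_min must be smaller than q_max")
    keep = (profile.q >= q_min) & (profile.q <= q_max)
    if not keep.any():
        raise ValueError(
            f"restriction to [{q_min}, {q_max}] nm^-1 leaves no data "
            f"(profile covers [{profile.q[0]:.3g}, {profile.q[-1]:.3g}])"
        )
    return profile.select(keep)


def l1_normalize(profile: Profile1D) -> Profile1D:
    """Scale so the sum of absolute intensities over the current window is 1.

    Sigma is divided by the same factor (the normalizer is treated as a
    constant). Invariant under positive rescaling of the input.
    """
    mass = float(np.nansum(np.abs(profile.intensity)))
    if not mass > 0:
        raise ValueError("cannot L1-normalize a profile with zero total mass")
    return profile.replace(
        intensity=profile.intensity / mass, sigma=profile.sigma / mass
    )


@dataclass(frozen=True)
class CleaningCriteria:
    """Automated surrogate for the study-style manual profile cleaning."""

    min_finite_fraction: float = 0.95
    mad_k: float = 5.0  # robust-z threshold on L1 distance to the stratum median


@dataclass
class CleaningEntry:
    index: int
    subject_id: Optional[str]
    group: Optional[str]
    lobe: Optional[str]
    pos_row: Optional[int]
    pos_col: Optional[int]
    retained: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CleaningReport:
    """One entry per input profile; every input accounted for exactly once."""

    entries: list[CleaningEntry]
    criteria: CleaningCriteria

    @property
    def n_retained(self) -> int:
        return sum(e.retained for e in self.entries)

    @property
    def n_rejected(self) -> int:
        return len(self.entries) - self.n_retained

    def to_dict(self) -> dict:
        return {
            "criteria": {
                "min_finite_fraction": self.criteria.min_finite_fraction,
                "mad_k": self.criteria.mad_k,
            },
            "n_input": len(self.entries),
            "n_retained": self.n_retained,
            "n_rejected": self.n_rejected,
            "entries": [
                {
                    "index": e.index,
                    "subject_id": e.subject_id,
                    "group": e.group,
                    "lobe": e.lobe,
                    "pos_row": e.pos_row,
                    "pos_col": e.pos_col,
                    "retained": e.retained,
                    "reasons": e.reasons,
                }
                for e in self.entries
            ],
        }


def clean_profiles(
    profiles: Sequence[Profile1D],
    criteria: CleaningCriteria = CleaningCriteria(),
) -> tuple[list[Profile1D], CleaningReport]:
    """Reject artifact profiles; report every decision.

    A profile is dropped when its finite fraction is below the threshold,
    its total absolute mass is non-positive, or its L1 distance to the
    median profile of its (group, lobe) stratum is a robust outlier
    (distance - median(d) > mad_k * 1.4826 * MAD(d)). Distances are
    computed on internally L1-normalized copies so the rule is scale-free.
    """
    entries = [
        CleaningEntry(
            index=i,
            subject_id=p.subject_id,
            group=p.group,
            lobe=p.lobe,
            pos_row=p.pos_row,
            pos_col=p.pos_col,
            retained=True,
        )
        for i, p in enumerate(profiles)
    ]
    for i, p in enumerate(profiles):
        finite = np.isfinite(p.intensity) & np.isfinite(p.sigma)
        if finite.mean() < criteria.min_finite_fraction:
            entries[i].retained = False
            entries[i].reasons.append("low finite fraction")
        mass = float(np.nansum(np.abs(p.intensity)))
        if not mass > 0:
            entries[i].retained = False
            entries[i].reasons.append("non-positive mass")

    # robust outlier rule within each (group, lobe) stratum
    strata: dict[tuple, list[int]] = {}
    for i, p in enumerate(profiles):
        if entries[i].retained:
            strata.setdefault((p.group, p.lobe), []).append(i)
    for idxs in strata.values():
        if len(idxs) < 3:
            continue
        grids = [profiles[i].q for i in idxs]
        if not all(len(g) == len(grids[0]) and np.allclose(g, grids[0]) for g in grids):
            continue  # heterogeneous grids: skip the shape rule for this stratum
        shapes = []
        for i in idxs:
            inten = np.nan_to_num(profiles[i].intensity)
            shapes.append(inten / max(np.abs(inten).sum(), 1e-300))
        arr = np.asarray(shapes)
        median_profile = np.median(arr, axis=0)
        dist = np.abs(arr - median_profile).mean(axis=1)
        med = np.median(dist)
        mad = 1.4826 * np.median(np.abs(dist - med))
        if mad <= 0:
            continue
        for k, i in enumerate(idxs):
            if dist[k] - med > criteria.mad_k * mad:
                entries[i].retained = False
                entries[i].reasons.append("stratum shape outlier (MAD rule)")

    retained = [p for i, p in enumerate(profiles) if entries[i].retained]
    return retained, CleaningReport(entries, criteria)


def group_average_profiles(
    profiles: Sequence[Profile1D],
    statistic: str = "mean",
) -> dict[tuple[Optional[str], Optional[str]], Profile1D]:
    """Average profiles within each (group, lobe) stratum.

    Returns one profile per stratum: pointwise mean (or median) intensity
    with sigma equal to the standard error of the mean across profiles
    (zero when n = 1), and the contributing count in ``n_pixels``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    strata: dict[tuple, list[Profile1D]] = {}
    for p in profiles:
        strata.setdefault((p.group, p.lobe), []).append(p)
    out: dict[tuple, Profile1D] = {}
    for key, members in strata.items():
        ref = members[0]
        if not all(m.same_grid(ref) for m in members):
            raise ValueError(f"profiles in stratum {key} do not share a q grid")
        arr = np.asarray([m.intensity for m in members])
        n = len(members)
        center = np.mean(arr, axis=0) if statistic == "mean" else np.median(arr, axis=0)
        if n > 1:
            sem = np.std(arr, axis=0, ddof=1) / np.sqrt(n)
        else:
            sem = np.zeros(arr.shape[1])
        out[key] = Profile1D(
            q=ref.q.copy(),
            intensity=center,
            sigma=sem,
            n_pixels=np.full(len(ref.q), n),
            group=key[0],
            lobe=key[1],
        )
    return out
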