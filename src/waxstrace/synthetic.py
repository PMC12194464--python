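"""Seeded synthetic WAXS data with known ground truth.

Generates 1D profiles, 2D detector frames and full longitudinal mouse
cohorts from the composite peak model, so every downstream stage (masking,
integration, preprocessing, fitting, biomarker trajectories) can be tested
for parameter recovery without any external data.

The cohort emulates the study design this package targets: five groups
(Control and Days 2/4/7/16 after tumor inoculation), five mice per group,
left (inoculated) and right (internal-control) prostate lobes, a 5x5 grid
of measurement positions per lobe, and Poisson counting noise. Disease
progression is a multiplicative effect on the left-lobe lipid and water
peak heights only: the lipid peak falls and the water peak rises with day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import defaults
from ._rng import child_seed, substream
from .geometry import DetectorGeometry, Frame, PixelMask, build_mask
from .model import CompositeParams, composite_model
from .profiles import Profile1D

__all__ = [
    "GROUPS",
    "CohortSpec",
    "GroundTruth",
    "default_effect_model",
    "simulate_profile",
    "simulate_frame",
    "simulate_cohort",
]

GROUPS = ("Control", "Day2", "Day4", "Day7", "Day16")
LOBES = ("left", "right")

#: sacrifice days assigned to control mice, cycled over subjects, so that
#: control measurements can be temporally matched to experimental days.
CONTROL_SACRIFICE_DAYS = (2, 4, 7, 16)


def default_effect_model() -> dict[str, tuple[float, float]]:
    """Left-lobe (lipid, water) amplitude multipliers per group.

    Day 2/4 near baseline; at Day 7 the lipid and water Gaussian heights are
    equal under the default control amplitudes (1.0 and 0.6); by Day 16 the
    water peak height strictly exceeds the lipid height. Lipid multipliers
    decrease and water multipliers increase monotonically. The right lobe is
    always (1.0, 1.0).
    """
    return {
        "Control": (1.0, 1.0),
        "Day2": (0.97, 1.03),
        "Day4": (0.92, 1.10),
        "Day7": (0.75, 1.25),
        "Day16": (0.45, 1.60),
    }


@dataclass
class CohortSpec:
    """Design of a synthetic longitudinal cohort."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 5
    lobes: tuple[str, ...] = LOBES
    positions_per_lobe: int = 25
    effect_model: Mapping[str, tuple[float, float]] = field(
        default_factory=default_effect_model
    )
    noise_scale: float = defaults.DEFAULT_NOISE_SCALE
    inter_subject_cv: float = defaults.DEFAULT_INTER_SUBJECT_CV
    #: CV of independent per-peak composition jitter (ratio variability).
    peak_jitter_cv: float = defaults.DEFAULT_INTER_SUBJECT_CV / 3.0
    control_params: CompositeParams = field(default_factory=defaults.default_control_params)
    control_sacrifice_days: tuple[int, ...] = CONTROL_SACRIFICE_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.noise_scale > 0:
            raise ValueError("noise_scale must be positive")
        if self.positions_per_lobe < 1:
            raise ValueError("positions_per_lobe must be >= 1")
        for g in self.groups:
            if g not in self.effect_model:
                raise ValueError(f"effect model missing group {g!r}")
            lm, wm = self.effect_model[g]
            if not (lm > 0 and wm > 0):
                raise ValueError("effect multipliers must be positive")
        if tuple(self.effect_model.get("Control", (1.0, 1.0))) != (1.0, 1.0):
            raise ValueError("Control multipliers must be 1.0")

    @property
    def n_subjects(self) -> int:
        return self.n_per_group * len(self.groups)

    @property
    def n_profiles(self) -> int:
        return self.n_subjects * len(self.lobes) * self.positions_per_lobe


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters of one simulated profile."""

    params: CompositeParams
    subject_id: Optional[str]
    lobe: Optional[str]
    group: Optional[str]
    seed: int


def simulate_profile(
    true_params: CompositeParams,
    q_grid: Optional[Sequence[float]] = None,
    noise_scale: float = defaults.DEFAULT_NOISE_SCALE,
    seed: int = 0,
    *,
    noise: bool = True,
    subject_id: Optional[str] = None,
    group: Optional[str] = None,
    lobe: Optional[str] = None,
    pos_row: Optional[int] = None,
    pos_col: Optional[int] = None,
    sacrifice_day: Optional[int] = None,
) -> tuple[Profile1D, GroundTruth]:
    """Simulate one 1D profile with Poisson counting noise.

    The composite model is scaled so the expected total over the grid equals
    ``noise_scale`` counts; each point is Poisson-sampled and sigma is
    sqrt(max(counts, 1)). With ``noise=False`` the model values are returned
    exactly (sigma = 0). Identical seeds give bit-identical output.
    """
    q = np.asarray(q_grid, dtype=float) if q_grid is not None else defaults.default_q_grid()
    if np.any(q <= 0):
        raise ValueError("q grid must be strictly positive")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    y = composite_model(q, true_params)
    meta = dict(
        subject_id=subject_id, group=group, lobe=lobe,
        pos_row=pos_row, pos_col=pos_col, sacrifice_day=sacrifice_day,
    )
    if not noise:
        profile = Profile1D(q=q, intensity=y, sigma=np.zeros_like(y), **meta)
        return profile, GroundTruth(true_params, subject_id, lobe, group, seed)
    lam = noise_scale * y / float(np.sum(y))
    rng = substream(seed, "profile-noise")
    counts = rng.poisson(lam).astype(float)
    sigma = np.sqrt(np.maximum(counts, 1.0))
    profile = Profile1D(q=q, intensity=counts, sigma=sigma, **meta)
    return profile, GroundTruth(true_params, subject_id, lobe, group, seed)


def simulate_frame(
    true_params: CompositeParams,
    geometry: Optional[DetectorGeometry] = None,
    total_counts: float = 1.0e7,
    beamstop_radius_mm: float = 1.0,
    dead_pixel_fraction: float = 0.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = defaults.DEFAULT_FRAME_SHAPE,
    noise: bool = True,
) -> tuple[Frame, PixelMask, GroundTruth]:
    """Simulate a circularly symmetric 2D detector frame.

    Each pixel's expectation is the composite model at that pixel's q,
    scaled so the unmasked total equals ``total_counts``; counts are
    Poisson-sampled. Pixels within the beamstop shadow or randomly chosen
    dead are masked (their counts are zeroed).
    """
    if not 0 <= dead_pixel_fraction < 1:
        raise ValueError("dead_pixel_fraction must be in [0, 1)")
    geom = geometry or defaults.default_geometry()
    qmap = geom.q_map(shape)
    qmap = np.maximum(qmap, 1e-12)  # beam center pixel; masked anyway in practice

    rng_dead = substream(seed, "dead-pixels")
    n_dead = int(round(dead_pixel_fraction * shape[0] * shape[1]))
    flat = rng_dead.choice(shape[0] * shape[1], size=n_dead, replace=False)
    dead = [(int(k // shape[1]), int(k % shape[1])) for k in flat]
    mask = build_mask(shape, geom.beam_center, beamstop_radius_mm, dead, geom)
    if mask.excluded.all():
        raise ValueError("mask excludes the entire detector")

    expected = composite_model(qmap, true_params)
    expected_masked = np.where(mask.excluded, 0.0, expected)
    scale = total_counts / float(expected_masked.sum())
    lam = expected_masked * scale
    if noise:
        counts = substream(seed, "frame-noise").poisson(lam).astype(float)
    else:
        counts = lam
    frame = Frame(counts=counts, exposure_time=0.1, monitor=1.0, frame_id=f"sim-{seed}")
    return frame, mask, GroundTruth(true_params, None, None, None, seed)


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier(s) with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[Profile1D], list[GroundTruth]]:
    """Simulate a full cohort: one profile per (subject, lobe, grid position).

    Per (subject, lobe) sample, amplitudes vary by a shared unit-mean
    lognormal brightness multiplier (CV ``inter_subject_cv``, applied to the
    whole profile — thickness/positioning variation that L1 normalization
    removes) times independent per-peak composition jitter (CV
    ``peak_jitter_cv``). The group effect multiplies the left-lobe lipid and
    water amplitudes only. Fully reproducible from ``spec.seed``.
    """
    grid_side = math.ceil(math.sqrt(spec.positions_per_lobe))
    profiles: list[Profile1D] = []
    truths: list[GroundTruth] = []
    q = defaults.default_q_grid()
    for g_idx, group in enumerate(spec.groups):
        lipid_mult, water_mult = spec.effect_model[group]
        for s_idx in range(spec.n_per_group):
            subject = f"{group}-m{s_idx + 1}"
            if group == "Control":
                day = spec.control_sacrifice_days[s_idx % len(spec.control_sacrifice_days)]
            else:
                day = int("".join(ch for ch in group if ch.isdigit()) or 0) or None
            for lobe in spec.lobes:
                rng_subj = substream(spec.seed, "cohort", subject, lobe)
                brightness = float(_lognormal_multiplier(rng_subj, spec.inter_subject_cv))
                jitter = _lognormal_multiplier(
                    rng_subj, spec.peak_jitter_cv, size=len(spec.control_params.peaks)
                )
                if lobe == "left":
                    lm, wm = lipid_mult, water_mult
                else:
                    lm, wm = 1.0, 1.0
                base = spec.control_params.scale_amplitudes(
                    lipid=lm * float(jitter[0]), water=wm * float(jitter[1])
                )
                true = base.scale_all(brightness)
                for p_idx in range(spec.positions_per_lobe):
                    row, col = divmod(p_idx, grid_side)
                    pseed = child_seed(spec.seed, "cohort", subject, lobe, f"pos{row},{col}")
                    prof, truth = simulate_profile(
                        true,
                        q_grid=q,
                        noise_scale=spec.noise_scale,
                        seed=pseed,
                        subject_id=subject,
                        group=group,
                        lobe=lobe,
                        pos_row=row,
                        pos_col=col,
                        sacrifice_day=day,
                    )
                    profiles.append(prof)
                    truths.append(truth)
    return profiles, truths
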