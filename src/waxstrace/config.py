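"""Structured pipeline configuration with paper-scale defaults.

One JSON-serializable config object drives the whole pipeline; command-line
flags override individual fields. All defaults mirror the study conditions:
414-point 3.25–21 nm^-1 grid, 10–20.5 nm^-1 biomarker/fit window, five
groups of five mice, 5x5 positions per lobe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import defaults
from .synthetic import CohortSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # geometry section
    sample_detector_distance_mm: float = 170.21
    pixel_pitch_mm: float = 0.172
    beam_center: tuple[float, float] = (350.0, 350.0)
    photon_energy_kev: float = 12.4
    # q grid section
    q_min: float = defaults.Q_MIN
    q_max: float = defaults.Q_MAX
    n_points: int = defaults.N_POINTS
    # analysis windows
    biomarker_window: tuple[float, float] = defaults.BIOMARKER_WINDOW
    fit_window: tuple[float, float] = defaults.BIOMARKER_WINDOW
    fit_variant: str = "3peak"
    # cleaning thresholds
    min_finite_fraction: float = 0.95
    mad_k: float = 5.0
    # cohort simulation
    n_per_group: int = 5
    positions_per_lobe: int = 25
    noise_scale: float = defaults.DEFAULT_NOISE_SCALE
    inter_subject_cv: float = defaults.DEFAULT_INTER_SUBJECT_CV
    seed: int = 0
    # output
    out_dir: str = "waxstrace-run"

    def __post_init__(self) -> None:
        self.beam_center = tuple(self.beam_center)  # type: ignore[assignment]
        self.biomarker_window = tuple(self.biomarker_window)  # type: ignore[assignment]
        self.fit_window = tuple(self.fit_window)  # type: ignore[assignment]
        if not self.q_min < self.q_max:
            raise ValueError("q_min must be < q_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.fit_variant not in ("2peak", "3peak"):
            raise ValueError("fit_variant must be '2peak' or '3peak'")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_group=self.n_per_group,
            positions_per_lobe=self.positions_per_lobe,
            noise_scale=self.noise_scale,
            inter_subject_cv=self.inter_subject_cv,
            seed=self.seed,
        )

    def geometry(self):
        from .geometry import DetectorGeometry

        return DetectorGeometry(
            sample_detector_distance_mm=self.sample_detector_distance_mm,
            pixel_pitch_mm=self.pixel_pitch_mm,
            beam_center=self.beam_center,
            photon_energy_kev=self.photon_energy_kev,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("beam_center", "biomarker_window", "fit_window"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
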