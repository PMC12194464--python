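"""The 1D scattering profile container used throughout the pipeline.

A :class:`Profile1D` is a calibrated intensity-versus-q curve (q in nm^-1)
with per-point Poisson uncertainties and the cohort metadata (subject, group,
prostate lobe, grid position) needed to aggregate biomarkers downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional

import numpy as np

__all__ = ["Profile1D"]


@dataclass
class Profile1D:
    """Calibrated (q, intensity, sigma) sequence with sample metadata.

    Parameters
    ----------
    q :
        Strictly increasing momentum-transfer grid, nm^-1.
    intensity :
        Scattered intensity per point; NaN marks empty/invalid bins.
    sigma :
        One-standard-deviation uncertainty per point (>= 0 where finite).
    n_pixels :
        Detector pixels contributing per bin when the profile came from
        azimuthal integration of a 2D frame; otherwise None.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    n_pixels: Optional[np.ndarray] = None
    subject_id: Optional[str] = None
    group: Optional[str] = None
    lobe: Optional[str] = None
    pos_row: Optional[int] = None
    pos_col: Optional[int] = None
    sacrifice_day: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("q must be one-dimensional")
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity and sigma must have equal length")
        if len(self.q) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.n_pixels is not None:
            self.n_pixels = np.asarray(self.n_pixels)
            if len(self.n_pixels) != len(self.q):
                raise ValueError("n_pixels length mismatch")
        finite = np.isfinite(self.intensity) & np.isfinite(self.sigma)
        if np.any(self.sigma[finite] < 0):
            raise ValueError("sigma must be non-negative where finite")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def metadata(self) -> dict[str, Any]:
        md: dict[str, Any] = {
            "subject_id": self.subject_id,
            "group": self.group,
            "lobe": self.lobe,
            "pos_row": self.pos_row,
            "pos_col": self.pos_col,
        }
        if self.sacrifice_day is not None:
            md["sacrifice_day"] = self.sacrifice_day
        return md

    def replace(self, **kwargs: Any) -> "Profile1D":
        """Copy with some fields replaced (arrays are not shared unless passed in)."""
        return replace(self, **kwargs)

    def select(self, keep: np.ndarray) -> "Profile1D":
        """Row subset by boolean mask or index array, metadata preserved."""
        np_sel = None if self.n_pixels is None else self.n_pixels[keep]
        return self.replace(
            q=self.q[keep],
            intensity=self.intensity[keep],
            sigma=self.sigma[keep],
            n_pixels=np_sel,
        )

    def same_grid(self, other: "Profile1D", rtol: float = 1e-9) -> bool:
        return len(self) == len(other) and np.allclose(
            self.q, other.q, rtol=rtol, atol=0.0
        )
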