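"""Detector geometry, pixel masks and azimuthal integration.

Maps flat-detector pixel positions to momentum transfer q via the exact
wide-angle relation q = 4*pi*sin(theta)/lambda with tan(2*theta) = r/L,
builds and dilates beamstop/dead-pixel masks, normalizes and averages raw
frames, and azimuthally integrates 2D frames into 1D profiles with Poisson
error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .profiles import Profile1D

__all__ = [
    "KEV_NM",
    "DetectorGeometry",
    "Frame",
    "PixelMask",
    "energy_to_wavelength",
    "pixel_to_q",
    "q_to_radius",
    "build_mask",
    "dilate_mask",
    "normalize_frame",
    "average_frames",
    "azimuthal_integrate",
]

#: hc in keV*nm — converts photon energy to wavelength.
KEV_NM = 1.2398420

# provenance bit flags for PixelMask
BEAMSTOP = 1
DEAD = 2
DILATED = 4
USER = 8


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return KEV_NM / energy_kev


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry driving the pixel -> q mapping.

    Attributes
    ----------
    sample_detector_distance_mm :
        Calibrated sample-to-detector distance L, mm.
    pixel_pitch_mm :
        Square pixel pitch, mm per pixel.
    beam_center :
        (row, col) of the direct beam in fractional pixel coordinates; may
        lie outside the detector bounds.
    photon_energy_kev :
        Monochromatic beam energy, keV; the wavelength is derived from it.
    """

    sample_detector_distance_mm: float = 170.21
    pixel_pitch_mm: float = 0.172
    beam_center: tuple[float, float] = (350.0, 350.0)
    photon_energy_kev: float = 12.4

    def __post_init__(self) -> None:
        if not self.sample_detector_distance_mm > 0:
            raise ValueError("sample-detector distance must be positive")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel pitch must be positive")
        if not self.photon_energy_kev > 0:
            raise ValueError("photon energy must be positive")

    @property
    def wavelength_nm(self) -> float:
        return energy_to_wavelength(self.photon_energy_kev)

    def radius_mm(self, shape: tuple[int, int]) -> np.ndarray:
        """Radial distance (mm) of every pixel center from the beam center."""
        rows = np.arange(shape[0], dtype=float)[:, None]
        cols = np.arange(shape[1], dtype=float)[None, :]
        cr, cc = self.beam_center
        return self.pixel_pitch_mm * np.hypot(rows - cr, cols - cc)

    def q_map(self, shape: tuple[int, int]) -> np.ndarray:
        """q (nm^-1) of every pixel center."""
        return pixel_to_q(self.radius_mm(shape), self)


def pixel_to_q(radial_distance_mm, geometry: DetectorGeometry):
    """Momentum transfer q (nm^-1) at radial distance r (mm) on the detector.

    Uses the exact relations 2*theta = arctan(r / L) and
    q = 4*pi*sin(theta)/lambda; strictly increasing in r.
    """
    r = np.asarray(radial_distance_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be non-negative")
    two_theta = np.arctan2(r, geometry.sample_detector_distance_mm)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / geometry.wavelength_nm
    return q if q.ndim else float(q)


def q_to_radius(q_nm_inv, geometry: DetectorGeometry):
    """Inverse of :func:`pixel_to_q`: radial distance (mm) for a given q."""
    q = np.asarray(q_nm_inv, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s = q * geometry.wavelength_nm / (4.0 * np.pi)
    if np.any(s >= 1.0):
        raise ValueError("q beyond the backscattering limit for this wavelength")
    r = geometry.sample_detector_distance_mm * np.tan(2.0 * np.arcsin(s))
    return r if r.ndim else float(r)


@dataclass
class Frame:
    """A single 2D detector exposure in photon counts."""

    counts: np.ndarray
    exposure_time: float = 0.1
    monitor: float = 1.0
    frame_id: Optional[str] = None
    applied_scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("frame counts must be a 2D array")
        if not self.exposure_time > 0:
            raise ValueError("exposure time must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass
class PixelMask:
    """Boolean exclusion grid with per-pixel provenance bit flags."""

    excluded: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.provenance is None:
            self.provenance = np.where(self.excluded, USER, 0).astype(np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        if self.provenance.shape != self.excluded.shape:
            raise ValueError("provenance shape must match excluded shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.excluded.shape  # type: ignore[return-value]

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(np.zeros(shape, dtype=bool), np.zeros(shape, dtype=np.uint8))


def build_mask(
    shape: tuple[int, int],
    beam_center: tuple[float, float],
    beamstop_radius_mm: float,
    dead_pixels: Iterable[tuple[int, int]] = (),
    geometry: Optional[DetectorGeometry] = None,
) -> PixelMask:
    """Mask pixels within the beamstop shadow or listed as dead.

    A pixel is beamstop-excluded iff its center lies within
    ``beamstop_radius_mm`` (in mm, using the geometry's pixel pitch) of the
    beam center; radius 0 means no beamstop. Duplicate dead-pixel entries
    are harmless.
    """
    if beamstop_radius_mm < 0:
        raise ValueError("beamstop radius must be non-negative")
    geom = geometry or DetectorGeometry(beam_center=beam_center)
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    cr, cc = beam_center
    r_mm = geom.pixel_pitch_mm * np.hypot(rows - cr, cols - cc)
    provenance = np.zeros(shape, dtype=np.uint8)
    if beamstop_radius_mm > 0:
        provenance[r_mm <= beamstop_radius_mm] |= BEAMSTOP
    for ij in dead_pixels:
        i, j = int(ij[0]), int(ij[1])
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise ValueError(f"dead pixel {ij} outside detector shape {shape}")
        provenance[i, j] |= DEAD
    return PixelMask(provenance != 0, provenance)


def _disk_footprint(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def dilate_mask(mask: PixelMask, radius_px: int) -> PixelMask:
    """Morphological dilation by a disk; only ever adds exclusions."""
    if radius_px < 0:
        raise ValueError("dilation radius must be non-negative")
    if radius_px == 0:
        return PixelMask(mask.excluded.copy(), mask.provenance.copy())
    grown = ndimage.binary_dilation(mask.excluded, structure=_disk_footprint(radius_px))
    provenance = mask.provenance.copy()
    provenance[grown & ~mask.excluded] |= DILATED
    return PixelMask(grown, provenance)


def normalize_frame(frame: Frame, reference_monitor: float) -> Frame:
    """Scale counts by (reference_monitor / monitor) / exposure_time.

    Corrects for beam-flux fluctuation and exposure duration; the applied
    scale is recorded on the returned frame.
    """
    if not reference_monitor > 0 or not frame.monitor > 0:
        raise ValueError("monitor readings must be positive")
    scale = (reference_monitor / frame.monitor) / frame.exposure_time
    return Frame(
        counts=frame.counts * scale,
        exposure_time=frame.exposure_time,
        monitor=reference_monitor,
        frame_id=frame.frame_id,
        applied_scale=scale,
    )


def average_frames(frames: Sequence[Frame]) -> Frame:
    """Pixelwise mean of repeated exposures at one measurement position."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share a shape")
    mean = np.mean([f.counts for f in frames], axis=0)
    return Frame(
        counts=mean,
        exposure_time=sum(f.exposure_time for f in frames),
        monitor=float(np.mean([f.monitor for f in frames])),
        frame_id=frames[0].frame_id,
    )


def azimuthal_integrate(
    frame: Frame,
    geometry: DetectorGeometry,
    mask: Optional[PixelMask] = None,
    q_edges: Optional[np.ndarray] = None,
    pixel_weights: Optional[np.ndarray] = None,
) -> Profile1D:
    """Azimuthally integrate a 2D frame into a 1D intensity profile.

    Each unmasked pixel is assigned to the q bin containing its center
    (bins half-open [lo, hi); the final bin is closed). Per bin the
    intensity is the *mean* pixel count — comparable across bins with
    different pixel populations — and sigma is sqrt(sum of counts)/n,
    i.e. Poisson propagation through the mean. Empty bins carry NaN.

    ``pixel_weights`` is the hook for optional geometric / absorption
    correction maps (multiplicative, default off).
    """
    if q_edges is None:
        raise ValueError("q_edges are required")
    edges = np.asarray(q_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("q_edges must be a strictly increasing 1D array of >= 2 edges")
    counts = frame.counts
    if mask is not None:
        if mask.shape != counts.shape:
            raise ValueError("mask shape must match frame shape")
        keep = ~mask.excluded
    else:
        keep = np.ones_like(counts, dtype=bool)
    if not keep.any():
        raise ValueError("all pixels are masked")
    if pixel_weights is not None:
        counts = counts * np.asarray(pixel_weights, dtype=float)

    qpix = geometry.q_map(counts.shape)[keep].ravel()
    cpix = counts[keep].ravel()
    nbins = len(edges) - 1
    idx = np.searchsorted(edges, qpix, side="right") - 1
    idx[qpix == edges[-1]] = nbins - 1  # final bin closed
    inside = (idx >= 0) & (idx < nbins)
    idx, cpix = idx[inside], cpix[inside]

    per_bin_n = np.bincount(idx, minlength=nbins)
    per_bin_sum = np.bincount(idx, weights=cpix, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(per_bin_n > 0, per_bin_sum / per_bin_n, np.nan)
        sigma = np.where(
            per_bin_n > 0,
            np.sqrt(np.clip(per_bin_sum, 0.0, None)) / np.maximum(per_bin_n, 1),
            np.nan,
        )
    mid = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(
        q=mid,
        intensity=intensity,
        sigma=sigma,
        n_pixels=per_bin_n,
        subject_id=frame.frame_id,
    )
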