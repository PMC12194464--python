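"""Versioned default study conditions: grid, generating parameters, geometry.

These constants define the conditions the package emulates — the 414-point
3.25–21 nm^-1 analysis grid, the control-group composite parameters, the
10–20.5 nm^-1 biomarker window and the detector geometry — and are the
single source the simulator, fitter and pipeline all read.
"""

from __future__ import annotations

import numpy as np

from .geometry import DetectorGeometry
from .model import CompositeParams, GaussianPeak

DEFAULTS_VERSION = "1.0"

#: analysis q grid: 414 points spanning 3.25–21 nm^-1 inclusive.
Q_MIN = 3.25
Q_MAX = 21.0
N_POINTS = 414

#: biomarker analysis window, nm^-1.
BIOMARKER_WINDOW = (10.0, 20.5)
#: peak-assignment windows, nm^-1.
LIPID_WINDOW = (12.0, 15.5)
WATER_WINDOW = (16.5, 20.5)

#: expected total photon counts per simulated 1D profile.
DEFAULT_NOISE_SCALE = 1.0e5

#: coefficient of variation of per-(subject, lobe) brightness multipliers.
DEFAULT_INTER_SUBJECT_CV = 0.15


def default_q_grid() -> np.ndarray:
    """The default 414-point grid with exact endpoints 3.25 and 21 nm^-1."""
    return np.linspace(Q_MIN, Q_MAX, N_POINTS)


def default_control_params() -> CompositeParams:
    """Generating parameters of a healthy control profile.

    Lipid peak (13.5 nm^-1) taller than the water peak (18 nm^-1), widths
    resolving but overlapping the peaks; B and C chosen so the amorphous
    background carries roughly 30% of the total signal on the default grid.
    """
    return CompositeParams(
        peaks=(
            GaussianPeak(amplitude=1.0, center=13.5, width=1.2, label="lipid-seed"),
            GaussianPeak(amplitude=0.6, center=18.0, width=1.5, label="water-seed"),
        ),
        porod_coefficient=120.0,
        offset=0.06,
    )


def default_geometry() -> DetectorGeometry:
    """Beamline-style geometry: 170.21 mm camera length, 12.4 keV, 172 um pixels."""
    return DetectorGeometry(
        sample_detector_distance_mm=170.21,
        pixel_pitch_mm=0.172,
        beam_center=(350.0, 350.0),
        photon_energy_kev=12.4,
    )


#: default simulated detector shape (covers the full grid at the default geometry).
DEFAULT_FRAME_SHAPE = (700, 700)
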