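"""Readers and writers for the package's on-disk formats.

Profiles travel as long-format CSV (one row per q point, metadata columns
identifying the measurement), frames as single-page 32-bit integer TIFF
with a JSON geometry/mask sidecar, fit results as JSON lines, biomarker
records and trajectories as CSV. Every writer's output is re-readable by
the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomarker import RATIO_DIRECTION, BiomarkerRecord, Trajectory
from .geometry import DetectorGeometry, Frame, PixelMask
from .model import CompositeParams, FitResult, GaussianPeak, _UncParams, _UncPeak
from .profiles import Profile1D

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_fit_results",
    "write_fit_results",
    "write_biomarkers",
    "read_biomarkers",
    "write_trajectory",
    "write_frame",
    "read_frame",
    "write_geometry",
    "read_geometry",
    "write_ground_truth",
]

PROFILE_COLUMNS = [
    "subject_id", "group", "lobe", "pos_row", "pos_col",
    "q_nm_inv", "intensity", "sigma",
]
_META_KEYS = ("subject_id", "group", "lobe", "pos_row", "pos_col", "sacrifice_day")


def _none_if_nan(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return v


def write_profiles(path, profiles: Sequence[Profile1D]) -> None:
    """Write profiles as long-format CSV (schema: PROFILE_COLUMNS [+ extras])."""
    rows = []
    for k, p in enumerate(profiles):
        n = len(p)
        frame = {
            "subject_id": p.subject_id if p.subject_id is not None else f"profile-{k}",
            "group": p.group,
            "lobe": p.lobe,
            "pos_row": p.pos_row,
            "pos_col": p.pos_col,
            "sacrifice_day": p.sacrifice_day,
            "q_nm_inv": p.q,
            "intensity": p.intensity,
            "sigma": p.sigma,
        }
        if p.n_pixels is not None:
            frame["n_pixels"] = p.n_pixels
        df = pd.DataFrame(frame, index=range(n))
        rows.append(df)
    # %.17g round-trips IEEE doubles exactly
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> list[Profile1D]:
    """Read a profiles CSV back into validated :class:`Profile1D` objects.

    Rejects files with missing columns, no records, or non-monotone q
    within a measurement, with diagnostics naming the offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    missing = [c for c in ("q_nm_inv", "intensity", "sigma") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in _META_KEYS:
        if col not in df.columns:
            df[col] = None
    profiles = []
    keys = ["subject_id", "group", "lobe", "pos_row", "pos_col"]
    for key, sub in df.groupby(keys, dropna=False, sort=False):
        q = sub["q_nm_inv"].to_numpy(dtype=float)
        if np.any(np.diff(q) <= 0):
            raise ValueError(f"{path}: non-monotone q for measurement {key}")
        day = _none_if_nan(sub["sacrifice_day"].iloc[0])
        pos_row = _none_if_nan(sub["pos_row"].iloc[0])
        pos_col = _none_if_nan(sub["pos_col"].iloc[0])
        profiles.append(
            Profile1D(
                q=q,
                intensity=sub["intensity"].to_numpy(dtype=float),
                sigma=sub["sigma"].to_numpy(dtype=float),
                n_pixels=sub["n_pixels"].to_numpy() if "n_pixels" in sub else None,
                subject_id=_none_if_nan(sub["subject_id"].iloc[0]),
                group=_none_if_nan(sub["group"].iloc[0]),
                lobe=_none_if_nan(sub["lobe"].iloc[0]),
                pos_row=None if pos_row is None else int(pos_row),
                pos_col=None if pos_col is None else int(pos_col),
                sacrifice_day=None if day is None else int(day),
            )
        )
    return profiles


def _params_to_dict(params: CompositeParams) -> dict:
    return {
        "peaks": [
            {"amplitude": p.amplitude, "center": p.center, "width": p.width,
             "label": p.label}
            for p in params.peaks
        ],
        "porod_coefficient": params.porod_coefficient,
        "offset": params.offset,
    }


def _params_from_dict(d: dict) -> CompositeParams:
    return CompositeParams(
        peaks=tuple(
            GaussianPeak(p["amplitude"], p["center"], p["width"], p.get("label"))
            for p in d["peaks"]
        ),
        porod_coefficient=d["porod_coefficient"],
        offset=d["offset"],
    )


def write_fit_results(path, results: Sequence[FitResult]) -> None:
    """One JSON object per line: params, uncertainties, diagnostics, metadata."""
    with open(path, "w") as fh:
        for r in results:
            unc = None
            if r.uncertainties is not None:
                unc = {
                    "peaks": [
                        {"amplitude": u.amplitude, "center": u.center,
                         "width": u.width, "label": u.label}
                        for u in r.uncertainties.peaks
                    ],
                    "porod_coefficient": r.uncertainties.porod_coefficient,
                    "offset": r.uncertainties.offset,
                }
            obj = {
                "params": _params_to_dict(r.params),
                "uncertainties": unc,
                "rss": r.rss,
                "reduced_chi2": r.reduced_chi2,
                "converged": r.converged,
                "n_evaluations": r.n_evaluations,
                "window": list(r.window),
                "model_variant": r.model_variant,
                "profile_meta": r.profile_meta,
            }
            fh.write(json.dumps(obj) + "\n")


def read_fit_results(path) -> list[FitResult]:
    results = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            unc = None
            if d["uncertainties"] is not None:
                u = d["uncertainties"]
                unc = _UncParams(
                    tuple(
                        _UncPeak(p["amplitude"], p["center"], p["width"], p.get("label"))
                        for p in u["peaks"]
                    ),
                    u["porod_coefficient"],
                    u["offset"],
                )
            results.append(
                FitResult(
                    params=_params_from_dict(d["params"]),
                    uncertainties=unc,
                    rss=d["rss"],
                    reduced_chi2=d["reduced_chi2"],
                    converged=d["converged"],
                    n_evaluations=d["n_evaluations"],
                    window=tuple(d["window"]),
                    model_variant=d["model_variant"],
                    profile_meta=d["profile_meta"],
                )
            )
    return results


def write_biomarkers(path, records: Sequence[BiomarkerRecord]) -> None:
    df = pd.DataFrame([r.to_dict() for r in records])
    with open(path, "w") as fh:
        fh.write(f"# ratio direction: {RATIO_DIRECTION}\n")
        df.to_csv(fh, index=False)


def read_biomarkers(path) -> list[BiomarkerRecord]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        d = {k: _none_if_nan(v) for k, v in row.items()}
        d["ok"] = bool(d["ok"])
        for key in ("pos_row", "pos_col", "sacrifice_day"):
            if d.get(key) is not None:
                d[key] = int(d[key])
        out.append(BiomarkerRecord(**d))
    return out


def write_trajectory(path, trajectory: Trajectory) -> None:
    df = trajectory.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# ratio direction: {trajectory.direction}\n")
        df.to_csv(fh, index=False)


def trajectory_summary_text(trajectory: Trajectory) -> str:
    """Plain-text per-group peak-magnitude table (mean +/- sd per lobe)."""
    lines = [f"ratio direction: {trajectory.direction}", ""]
    for lobe in ("left", "right"):
        pts = trajectory.per_lobe(lobe)
        if not pts:
            continue
        lines.append(f"lobe: {lobe}")
        lines.append(
            f"{'group':<9} {'lipid height':>22} {'water height':>22} "
            f"{'ratio':>18} {'n':>3}"
        )
        for p in pts:
            lines.append(
                f"{p.group:<9} "
                f"{p.mean_lipid_height:>12.4e} ± {p.sd_lipid_height:<8.1e}"
                f"{p.mean_water_height:>12.4e} ± {p.sd_water_height:<8.1e}"
                f"{p.mean_ratio:>10.3f} ± {p.sd_ratio:<6.3f}"
                f"{p.n_subjects:>3d}"
            )
        lines.append("")
    return "\n".join(lines)


def write_frame(path, frame: Frame, geometry: DetectorGeometry,
                mask: Optional[PixelMask] = None) -> None:
    """Single-page grayscale TIFF (int32 counts) + JSON sidecar (geometry, mask)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.rint(frame.counts).astype(np.int32))
    sidecar = {
        "geometry": dataclasses.asdict(geometry),
        "exposure_time": frame.exposure_time,
        "monitor": frame.monitor,
        "frame_id": frame.frame_id,
        "mask_excluded": None if mask is None else np.flatnonzero(
            mask.excluded.ravel()
        ).tolist(),
        "shape": list(frame.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_frame(path) -> tuple[Frame, DetectorGeometry, Optional[PixelMask]]:
    import tifffile

    path = Path(path)
    counts = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    g = sidecar["geometry"]
    geometry = DetectorGeometry(
        sample_detector_distance_mm=g["sample_detector_distance_mm"],
        pixel_pitch_mm=g["pixel_pitch_mm"],
        beam_center=tuple(g["beam_center"]),
        photon_energy_kev=g["photon_energy_kev"],
    )
    mask = None
    if sidecar.get("mask_excluded") is not None:
        excluded = np.zeros(counts.size, dtype=bool)
        excluded[np.asarray(sidecar["mask_excluded"], dtype=int)] = True
        mask = PixelMask(excluded.reshape(counts.shape))
    frame = Frame(
        counts=counts,
        exposure_time=sidecar.get("exposure_time", 0.1),
        monitor=sidecar.get("monitor", 1.0),
        frame_id=sidecar.get("frame_id"),
    )
    return frame, geometry, mask


def write_geometry(path, geometry: DetectorGeometry) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(geometry), indent=2))


def read_geometry(path) -> DetectorGeometry:
    d = json.loads(Path(path).read_text())
    d["beam_center"] = tuple(d["beam_center"])
    return DetectorGeometry(**d)


def write_ground_truth(path, truths) -> None:
    """Ground truth as JSON lines (one record per generated profile)."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps({
                "params": _params_to_dict(t.params),
                "subject_id": t.subject_id,
                "lobe": t.lobe,
                "group": t.group,
                "seed": t.seed,
            }) + "\n")
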