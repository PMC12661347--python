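"""File interchange: multi-page TIFF, JSON sidecars, CSV, HDF5."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthetic import BehaviorLog, ImagingSession, StructuralStack, Trial


def write_movie_tiff(session: ImagingSession, path: "str | Path") -> Path:
    """Plane-interleaved multi-page TIFF plus a JSON metadata sidecar.

    Page order is frame-major, plane-minor (frame0/plane0,
    frame0/plane1, ...), matching per-frame plane cycling; the sidecar
    documents the order and acquisition geometry.
    """
    path = Path(path)
    n_frames, n_planes, rows, cols = session.movie.shape
    pages = session.movie.reshape(n_frames * n_planes, rows, cols)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "page_order": "frame-major, plane-minor (plane cycles within frame)",
        "n_frames": int(n_frames),
        "n_planes": int(n_planes),
        "frame_rate_hz": session.frame_rate_hz,
        "plane_spacing_um": session.plane_spacing_um,
        "pixel_size_um": list(session.pixel_size_um),
        "channel": session.channel,
        "metadata": {k: v for k, v in session.metadata.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_movie_tiff(path: "str | Path") -> ImagingSession:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    n_frames, n_planes = meta["n_frames"], meta["n_planes"]
    movie = np.asarray(pages).reshape(n_frames, n_planes,
                                      *pages.shape[-2:])
    return ImagingSession(
        movie=movie, frame_rate_hz=meta["frame_rate_hz"],
        plane_spacing_um=meta["plane_spacing_um"],
        pixel_size_um=tuple(meta["pixel_size_um"]),
        channel=meta.get("channel", "functional"),
        metadata=meta.get("metadata", {}),
    )


def write_stack_tiff(stack: StructuralStack, path: "str | Path") -> Path:
    """Z-major, plane-minor pages with a JSON sidecar for the grid."""
    path = Path(path)
    n_z, n_planes, rows, cols = stack.images.shape
    tifffile.imwrite(path, stack.images.reshape(-1, rows, cols).astype(
        np.float32))
    sidecar = {
        "page_order": "z-major, plane-minor",
        "z_offsets_um": [float(z) for z in stack.z_offsets_um],
        "n_planes": int(n_planes),
        "pixel_size_um": list(stack.pixel_size_um),
        "plane_spacing_um": stack.plane_spacing_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack_tiff(path: "str | Path") -> StructuralStack:
    path = Path(path)
    pages = np.asarray(tifffile.imread(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    z = np.asarray(meta["z_offsets_um"])
    n_planes = meta["n_planes"]
    return StructuralStack(
        images=pages.reshape(len(z), n_planes, *pages.shape[-2:]),
        z_offsets_um=z, pixel_size_um=tuple(meta["pixel_size_um"]),
        plane_spacing_um=meta["plane_spacing_um"],
    )


def behavior_to_frame(log: BehaviorLog) -> pd.DataFrame:
    """One row per trial."""
    return pd.DataFrame([{
        "trial_type": t.trial_type, "cue_side": t.cue_side,
        "cue_pos_cm": t.cue_pos_cm, "t_start": t.t_start,
        "t_choice": t.t_choice, "t_outcome": t.t_outcome,
        "outcome": t.outcome, "chosen_side": t.chosen_side,
    } for t in log.trials])


def write_behavior_csv(log: BehaviorLog, path: "str | Path",
                       velocity_path: "str | Path | None" = None) -> Path:
    """Trial table CSV plus a per-frame velocity table.

    The velocity table (one row per imaging frame, so much larger than
    the trial table) goes alongside the trial CSV unless
    ``velocity_path`` redirects it.
    """
    path = Path(path)
    behavior_to_frame(log).to_csv(path, index=False)
    vel = pd.DataFrame({
        "frame": np.arange(log.velocity_cm_s.size),
        "velocity_cm_s": log.velocity_cm_s,
    })
    if velocity_path is None:
        velocity_path = path.with_name(path.stem + "_velocity.csv")
    vel.to_csv(Path(velocity_path), index=False)
    return path


def read_behavior_csv(path: "str | Path",
                      frame_rate_hz: float = 10.4) -> BehaviorLog:
    path = Path(path)
    df = pd.read_csv(path)
    trials = [Trial(
        trial_type=r.trial_type, cue_side=r.cue_side,
        cue_pos_cm=r.cue_pos_cm, t_start=r.t_start,
        t_choice=None if pd.isna(r.t_choice) else float(r.t_choice),
        t_outcome=r.t_outcome, outcome=r.outcome,
        chosen_side=None if pd.isna(r.chosen_side) else r.chosen_side,
    ) for r in df.itertuples()]
    vel_path = path.with_name(path.stem + "_velocity.csv")
    velocity = (pd.read_csv(vel_path)["velocity_cm_s"].to_numpy()
                if vel_path.exists() else np.zeros(0))
    return BehaviorLog(trials=trials, velocity_cm_s=velocity,
                       frame_rate_hz=frame_rate_hz)


def write_components_h5(components, background, path: "str | Path") -> Path:
    """Components + background to HDF5: sparse footprints, traces, metrics."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        bg = f.create_group("background")
        bg.create_dataset("spatial_map", data=background.spatial_map)
        bg.create_dataset("temporal_trace", data=background.temporal_trace)
        for k, comp in enumerate(components):
            g = f.create_group(f"components/{k:04d}")
            g.create_dataset("pixels", data=comp.mask.pixels)
            g.attrs["plane_index"] = comp.mask.plane_index
            g.create_dataset("raw_trace", data=comp.raw_trace)
            if comp.denoised_trace is not None:
                g.create_dataset("denoised_trace", data=comp.denoised_trace)
                g.create_dataset("spikes", data=comp.spikes)
            for attr in ("gamma", "snr", "rvalue"):
                val = getattr(comp, attr)
                if val is not None:
                    g.attrs[attr] = val
            g.attrs["decision"] = comp.decision
    return path


def metrics_table(components) -> pd.DataFrame:
    """Per-component screening metrics as a tidy table."""
    return pd.DataFrame([{
        "component": k, "plane": c.mask.plane_index,
        "area_px2": c.mask.area_px2, "gamma": c.gamma,
        "snr": c.snr, "rvalue": c.rvalue, "decision": c.decision,
    } for k, c in enumerate(components)])
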