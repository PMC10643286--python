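"""Plain-text readers/writers for the pipeline's tabular artefacts.

Tracks and LED traces use the same long/wide CSV layouts a video-digitisation
workflow produces; cameras, world frames and ground truth get JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Trajectory3D, WorldFrame
from .segmentation import FlightSegment
from .stereo import CameraModel, camera_from_dict, camera_to_dict
from .synthetic import GroundTruthFlight, ViewRecording


def write_tracks_csv(path: str | Path, view: ViewRecording) -> None:
    """Long-format point tracks: frame, point_name, x_px, y_px."""
    frames = np.asarray(view.frames)
    rows = []
    for name, track in (("front", view.front_px), ("rear", view.rear_px)):
        rows.append(
            pd.DataFrame(
                {"frame": frames, "point_name": name, "x_px": track[:, 0], "y_px": track[:, 1]}
            )
        )
    static = [(f"landmark_{i}", p) for i, p in enumerate(view.landmarks_px)]
    static += [("shadow_base", view.shadow_base_px), ("shadow_tip", view.shadow_tip_px)]
    for name, p in static:
        rows.append(
            pd.DataFrame({"frame": [0], "point_name": name, "x_px": [p[0]], "y_px": [p[1]]})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_led_csv(path: str | Path, led: np.ndarray) -> None:
    led = np.asarray(led)
    df = pd.DataFrame(led, columns=[f"led{i}" for i in range(led.shape[1])])
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_led_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("led")]
    return df[cols].to_numpy(dtype=float)


def write_camera_json(path: str | Path, cam: CameraModel) -> None:
    Path(path).write_text(json.dumps(camera_to_dict(cam), indent=2, sort_keys=True))


def read_camera_json(path: str | Path) -> CameraModel:
    return camera_from_dict(json.loads(Path(path).read_text()))


def write_trajectory_csv(path: str | Path, traj: Trajectory3D) -> None:
    df = pd.DataFrame(
        {
            "t_s": traj.t,
            "front_x_mm": traj.front[:, 0],
            "front_y_mm": traj.front[:, 1],
            "front_z_mm": traj.front[:, 2],
            "rear_x_mm": traj.rear[:, 0],
            "rear_y_mm": traj.rear[:, 1],
            "rear_z_mm": traj.rear[:, 2],
        }
    )
    com = traj.com
    df["com_x_mm"], df["com_y_mm"], df["com_z_mm"] = com[:, 0], com[:, 1], com[:, 2]
    df.to_csv(path, index=False)


def world_frame_to_dict(frame: WorldFrame) -> dict:
    return {
        "rotation": frame.rotation.tolist(),
        "translation": frame.translation.tolist(),
        "t0_index": frame.t0_index,
        "sun_azimuth_world_deg": frame.sun_azimuth_world,
        "plane_fit_rmse_mm": frame.plane_fit_rmse,
        "shadow_elevation_deg": frame.shadow_elevation_deg,
    }


def write_world_frame_json(path: str | Path, frame: WorldFrame) -> None:
    Path(path).write_text(json.dumps(world_frame_to_dict(frame), indent=2, sort_keys=True))


def write_segments_csv(path: str | Path, segments: list[FlightSegment]) -> None:
    pd.DataFrame(
        [
            {
                "phase": s.phase,
                "start": s.start,
                "stop": s.stop,
                "t_start_s": s.t_start,
                "t_stop_s": s.t_stop,
                "mean_direction_deg": s.mean_direction,
                "r": s.r,
                "n_samples": s.n_samples,
            }
            for s in segments
        ]
    ).to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(dirpath: str | Path, flight: GroundTruthFlight, stem: str = "flight") -> None:
    """Ground-truth flight as CSV plus a JSON sidecar with the truth scalars."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t_s": flight.t,
            "front_x_mm": flight.front[:, 0],
            "front_y_mm": flight.front[:, 1],
            "front_z_mm": flight.front[:, 2],
            "rear_x_mm": flight.rear[:, 0],
            "rear_y_mm": flight.rear[:, 1],
            "rear_z_mm": flight.rear[:, 2],
            "phase": flight.phase_labels,
        }
    )
    df.to_csv(dirpath / f"{stem}.csv", index=False)
    sidecar = {
        "fs": flight.fs,
        "sun_azimuth_deg": flight.sun_azimuth,
        "true_descent_onset_s": flight.true_descent_onset,
        "true_contact_interval_s": list(flight.true_contact_interval),
        "true_contact_index": list(flight.true_contact_index),
        "true_segment_boundaries": [list(b) for b in flight.true_segment_boundaries],
        "params": flight.params,
    }
    (dirpath / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
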