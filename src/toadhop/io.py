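"""CSV table schemas and round-trip readers/writers.

Every table is UTF-8 CSV with decimal points, one logical table per file,
and a leading comment line ``# toadhop <schema> v1`` stamping the schema
version. Readers validate the documented header and raise
:class:`~toadhop.errors.SchemaError` naming the offending column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .stereo import Trajectory3D

SCHEMA_VERSION = 1

#: schema name -> (all columns in order, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "landmarks": (
        ("camera", "frame", "landmark", "u", "v", "visible"),
        ("frame", "u", "v"),
    ),
    "brightness": (
        ("camera", "frame", "brightness"),
        ("frame", "brightness"),
    ),
    "correspondences": (
        ("view_id", "corner_id", "x_board", "y_board", "X", "Y", "Z",
         "u_left", "v_left", "u_right", "v_right"),
        ("view_id", "corner_id", "x_board", "y_board", "X", "Y", "Z",
         "u_left", "v_left", "u_right", "v_right"),
    ),
    "trajectory": (
        ("frame", "t", "snout_x", "snout_y", "snout_z",
         "cloaca_x", "cloaca_y", "cloaca_z", "interpolated"),
        ("frame", "t", "snout_x", "snout_y", "snout_z",
         "cloaca_x", "cloaca_y", "cloaca_z"),
    ),
    "kinematics": (
        ("animal_id", "trial_id", "mean_velocity", "max_velocity",
         "distance", "height", "angle_takeoff", "angle_landing", "best"),
        ("mean_velocity", "max_velocity", "distance", "height",
         "angle_takeoff", "angle_landing"),
    ),
    "morphology": (
        ("animal_id", "population", "invasion_category", "class", "generation",
         "svl", "mass", "femur", "tibiofibula", "hindfoot", "forefoot",
         "head_width", "humerus", "radioulna"),
        ("svl", "mass", "femur", "tibiofibula", "hindfoot", "forefoot",
         "head_width", "humerus", "radioulna"),
    ),
    "residuals": (
        ("animal_id", "trait", "group", "residual", "slope", "intercept"),
        ("residual", "slope", "intercept"),
    ),
    "raceway_events": (
        ("animal_id", "event", "timestamp", "position"),
        ("timestamp",),
    ),
    "raceway_summary": (
        ("animal_id", "n_hops", "total_time_s", "mean_hop_distance_m",
         "mean_speed_m_s", "finished", "terminated_early"),
        ("n_hops", "total_time_s", "mean_hop_distance_m", "mean_speed_m_s"),
    ),
    "qc": (
        ("view_id", "inaccuracy", "threshold", "accepted", "reason"),
        ("inaccuracy", "threshold"),
    ),
    "stats": (
        ("analysis", "response", "term", "df_num", "df_den", "statistic", "p"),
        ("statistic",),
    ),
    "ground_truth": (
        ("trial_id", "distance", "height", "flight_time",
         "angle_takeoff", "angle_landing"),
        ("distance", "height", "flight_time", "angle_takeoff", "angle_landing"),
    ),
}


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a table under its schema, stamping the version comment line."""
    cols, _ = _schema(schema)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema!r}: missing column {missing[0]!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# toadhop {schema} v{SCHEMA_VERSION}\n")
        df.loc[:, list(cols)].to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a table against its documented schema."""
    cols, numeric = _schema(schema)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing column {c!r} "
                              f"required by schema {schema!r}")
    unknown = [c for c in df.columns if c not in cols]
    if unknown:
        raise SchemaError(f"{Path(path).name}: unknown column {unknown[0]!r} "
                          f"for schema {schema!r}")
    for c in numeric:
        raw = df[c].replace("", np.nan)
        try:
            df[c] = pd.to_numeric(raw)
        except (ValueError, TypeError):
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            sample = str(bad.iloc[0]) if len(bad) else "?"
            hint = (" (locale-style comma decimals are not accepted; "
                    "use a decimal point)") if "," in sample else ""
            raise SchemaError(
                f"{Path(path).name}: column {c!r} is not numeric "
                f"(e.g. {sample!r}){hint}"
            ) from None
    for c in ("visible", "best", "accepted", "finished", "terminated_early",
              "interpolated"):
        if c in df.columns:
            df[c] = df[c].str.lower().isin(("true", "1", "t", "yes"))
    return df


def _schema(name: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if name not in SCHEMAS:
        raise SchemaError(f"unknown schema {name!r}")
    return SCHEMAS[name]


# --------------------------------------------------------------------------
# converters between in-memory objects and table rows
# --------------------------------------------------------------------------

def trajectory_to_frame(traj: Trajectory3D) -> pd.DataFrame:
    n = len(traj)
    return pd.DataFrame({
        "frame": np.arange(n),
        "t": traj.timestamps,
        "snout_x": traj.snout[:, 0], "snout_y": traj.snout[:, 1],
        "snout_z": traj.snout[:, 2],
        "cloaca_x": traj.cloaca[:, 0], "cloaca_y": traj.cloaca[:, 1],
        "cloaca_z": traj.cloaca[:, 2],
        "interpolated": traj.interpolated,
    })


def frame_to_trajectory(df: pd.DataFrame, frame_rate: float,
                        aligned: bool = False) -> Trajectory3D:
    return Trajectory3D(
        timestamps=df["t"].to_numpy(dtype=float),
        snout=df[["snout_x", "snout_y", "snout_z"]].to_numpy(dtype=float),
        cloaca=df[["cloaca_x", "cloaca_y", "cloaca_z"]].to_numpy(dtype=float),
        frame_rate=frame_rate,
        aligned=aligned,
        interpolated=df["interpolated"].to_numpy(dtype=bool),
    )


def views_to_frame(views) -> pd.DataFrame:
    rows = []
    for v in views:
        world = v.corners_world
        for k in range(len(v.corners_3d)):
            rows.append((v.board_id, k,
                         v.corners_3d[k, 0], v.corners_3d[k, 1],
                         world[k, 0], world[k, 1], world[k, 2],
                         v.corners_px_left[k, 0], v.corners_px_left[k, 1],
                         v.corners_px_right[k, 0], v.corners_px_right[k, 1]))
    return pd.DataFrame(rows, columns=SCHEMAS["correspondences"][0])


@dataclass
class LoadedCalibrationView:
    """Checkerboard view reconstructed from a correspondence table."""

    board_id: int
    corners_3d: np.ndarray       # board frame, z = 0
    corners_world: np.ndarray
    corners_px_left: np.ndarray
    corners_px_right: np.ndarray


def frame_to_views(df: pd.DataFrame) -> list[LoadedCalibrationView]:
    views = []
    for vid, sub in df.groupby("view_id"):
        sub = sub.sort_values("corner_id")
        b = np.column_stack([sub["x_board"], sub["y_board"], np.zeros(len(sub))])
        views.append(LoadedCalibrationView(
            board_id=int(vid),
            corners_3d=b.astype(float),
            corners_world=sub[["X", "Y", "Z"]].to_numpy(dtype=float),
            corners_px_left=sub[["u_left", "v_left"]].to_numpy(dtype=float),
            corners_px_right=sub[["u_right", "v_right"]].to_numpy(dtype=float),
        ))
    return views


def kinematics_to_frame(jumps, best_ids=None) -> pd.DataFrame:
    best_ids = best_ids or set()
    rows = [{
        "animal_id": j.animal_id, "trial_id": j.trial_id,
        "mean_velocity": j.mean_velocity, "max_velocity": j.max_velocity,
        "distance": j.distance, "height": j.height,
        "angle_takeoff": j.angle_takeoff, "angle_landing": j.angle_landing,
        "best": j.trial_id in best_ids,
    } for j in jumps]
    return pd.DataFrame(rows, columns=SCHEMAS["kinematics"][0])
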