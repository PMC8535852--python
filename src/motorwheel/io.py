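"""Readers and writers for the pipeline's file formats.

Delimited text formats:

* paw table — columns ``frame, left_x, left_y, right_x, right_y`` (pixels);
* ROI table — columns ``day, id, x_px, y_px``;
* trace matrix — neurons x frames CSV (one row per neuron).

The HDF5 container groups everything for one session: ``/dff`` (neurons x
frames), ``/events``, ``/meta`` attributes (frame_rate, pixel_size_um),
``/meta/layer``, ``/meta/centroids``, ``/rois/day_k`` tables and a ``/truth``
group for synthetic ground truth.  Schema violations are reported with the
offending row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventRaster, TraceMatrix
from .kinematics import PawTrajectory
from .registration import ROITable
from .synthetic import GroundTruth

__all__ = [
    "read_paws",
    "write_paws",
    "read_rois",
    "write_rois",
    "read_traces_csv",
    "write_traces_csv",
    "read_session_h5",
    "write_session_h5",
    "write_ground_truth_json",
    "read_ground_truth_json",
]

PAW_COLUMNS = ["frame", "left_x", "left_y", "right_x", "right_y"]
ROI_COLUMNS = ["day", "id", "x_px", "y_px"]


def _validated_numeric(df: pd.DataFrame, columns: list[str], path: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        out[col] = coerced
    return pd.DataFrame(out)


def write_paws(path: str | Path, left: PawTrajectory, right: PawTrajectory) -> None:
    if left.n_frames != right.n_frames:
        raise ValueError("left and right trajectories differ in length")
    df = pd.DataFrame(
        {
            "frame": np.arange(left.n_frames),
            "left_x": left.x_raw,
            "left_y": left.y_raw,
            "right_x": right.x_raw,
            "right_y": right.y_raw,
        }
    )
    df.to_csv(path, index=False)


def read_paws(path: str | Path, frame_rate: float = 71.5) -> tuple[PawTrajectory, PawTrajectory]:
    df = _validated_numeric(pd.read_csv(path), PAW_COLUMNS, str(path))
    left = PawTrajectory(frame_rate, df["left_x"].to_numpy(), df["left_y"].to_numpy(), "left")
    right = PawTrajectory(frame_rate, df["right_x"].to_numpy(), df["right_y"].to_numpy(), "right")
    return left, right


def write_rois(path: str | Path, tables: list[ROITable]) -> None:
    frames = []
    for t in tables:
        frames.append(
            pd.DataFrame({"day": t.day, "id": t.ids, "x_px": t.xy[:, 0], "y_px": t.xy[:, 1]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rois(path: str | Path, field_px: int = 512) -> list[ROITable]:
    df = _validated_numeric(pd.read_csv(path), ROI_COLUMNS, str(path))
    tables = []
    for day, grp in df.groupby("day", sort=True):
        tables.append(
            ROITable(
                int(day),
                grp["id"].to_numpy().astype(int),
                grp[["x_px", "y_px"]].to_numpy(),
                field_px,
            )
        )
    return tables


def write_traces_csv(path: str | Path, traces: TraceMatrix) -> None:
    pd.DataFrame(traces.dff).to_csv(path, index=False)


def read_traces_csv(
    path: str | Path,
    frame_rate: float,
    layer: np.ndarray | None = None,
    centroids: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> TraceMatrix:
    df = pd.read_csv(path)
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {i}, column {df.columns[j]!r}"
        )
    return TraceMatrix(arr, frame_rate, layer, centroids, pixel_size_um)


def write_session_h5(
    path: str | Path,
    traces: TraceMatrix | None = None,
    raster: EventRaster | None = None,
    rois: list[ROITable] | None = None,
    truth: GroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        if traces is not None:
            f.create_dataset("dff", data=traces.dff)
            meta.attrs["frame_rate"] = traces.frame_rate
            if traces.pixel_size_um is not None:
                meta.attrs["pixel_size_um"] = traces.pixel_size_um
            if traces.layer is not None:
                meta.create_dataset(
                    "layer", data=np.asarray(traces.layer, dtype="S")
                )
            if traces.centroids is not None:
                meta.create_dataset("centroids", data=traces.centroids)
        if raster is not None:
            d = f.create_dataset("events", data=raster.events.astype(np.uint8))
            d.attrs["params"] = json.dumps(raster.params)
            d.attrs["frame_rate"] = raster.frame_rate
        if rois is not None:
            g = f.create_group("rois")
            for t in rois:
                gd = g.create_group(f"day_{t.day}")
                gd.create_dataset("ids", data=np.asarray(t.ids, dtype=int))
                gd.create_dataset("xy", data=t.xy)
                gd.attrs["field_px"] = t.field_px
        if truth is not None:
            g = f.create_group("truth")
            if truth.coupling is not None:
                g.create_dataset("coupling", data=truth.coupling)
            if truth.responder_labels is not None:
                g.create_dataset("responder_labels", data=truth.responder_labels)
            if truth.day_shifts is not None:
                g.create_dataset("day_shifts", data=np.asarray(truth.day_shifts))


def read_session_h5(path: str | Path) -> dict:
    """Load a session container; returns a dict with any of
    ``traces``, ``raster``, ``rois``, ``truth`` that the file holds."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        meta = f["meta"] if "meta" in f else None
        if "dff" in f:
            layer = None
            centroids = None
            pixel = None
            if meta is not None:
                if "layer" in meta:
                    layer = meta["layer"][:].astype(str)
                if "centroids" in meta:
                    centroids = meta["centroids"][:]
                pixel = meta.attrs.get("pixel_size_um")
            out["traces"] = TraceMatrix(
                f["dff"][:], float(meta.attrs["frame_rate"]), layer, centroids, pixel
            )
        if "events" in f:
            d = f["events"]
            out["raster"] = EventRaster(
                d[:].astype(bool),
                float(d.attrs["frame_rate"]),
                json.loads(d.attrs["params"]),
            )
        if "rois" in f:
            tables = []
            for name in sorted(f["rois"], key=lambda s: int(s.split("_")[1])):
                gd = f["rois"][name]
                tables.append(
                    ROITable(
                        int(name.split("_")[1]),
                        gd["ids"][:],
                        gd["xy"][:],
                        int(gd.attrs["field_px"]),
                    )
                )
            out["rois"] = tables
        if "truth" in f:
            g = f["truth"]
            out["truth"] = GroundTruth(
                coupling=g["coupling"][:] if "coupling" in g else None,
                responder_labels=(
                    g["responder_labels"][:].astype(bool)
                    if "responder_labels" in g
                    else None
                ),
                day_shifts=(
                    [tuple(int(v) for v in row) for row in g["day_shifts"][:]]
                    if "day_shifts" in g
                    else None
                ),
            )
    return out


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> None:
    payload: dict = {}
    if truth.stride_times is not None:
        payload["stride_times"] = [
            [paw, int(s), int(p), float(l)] for paw, s, p, l in truth.stride_times
        ]
    if truth.coupling is not None:
        payload["coupling"] = truth.coupling.tolist()
    if truth.responder_labels is not None:
        payload["responder_labels"] = truth.responder_labels.astype(int).tolist()
    if truth.day_shifts is not None:
        payload["day_shifts"] = [list(map(int, s)) for s in truth.day_shifts]
    if truth.identity_map is not None:
        payload["identity_map"] = {
            str(day): {str(k): v for k, v in m.items()}
            for day, m in truth.identity_map.items()
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        stride_times=(
            [(p, s, pk, l) for p, s, pk, l in payload["stride_times"]]
            if "stride_times" in payload
            else None
        ),
        coupling=np.array(payload["coupling"]) if "coupling" in payload else None,
        responder_labels=(
            np.array(payload["responder_labels"], dtype=bool)
            if "responder_labels" in payload
            else None
        ),
        day_shifts=(
            [tuple(s) for s in payload["day_shifts"]] if "day_shifts" in payload else None
        ),
        identity_map=(
            {int(d): {int(k): v for k, v in m.items()} for d, m in payload["identity_map"].items()}
            if "identity_map" in payload
            else None
        ),
    )
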