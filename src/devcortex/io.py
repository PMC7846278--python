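"""Shared I/O: movies, catalogs, traces, configs, provenance.

All numeric payloads round-trip losslessly (float64 end to end unless the
source array is a narrower type, which is preserved).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .synthetic import RoiTraceSet
from .widefield import EventCatalog, FluorescenceMovie, RegionMask

__all__ = [
    "ProvenanceRecord",
    "read_movie",
    "write_movie",
    "write_catalog",
    "read_catalog",
    "read_traces",
    "write_traces",
    "read_region_masks",
    "load_config",
    "write_provenance",
]

CATALOG_COLUMNS = ["onset_s", "duration_s", "n_voxels", "restricted_area_um2", "peak_dff", "region"]
POSITION_COLUMNS = ["cell_id", "x_um", "y_um"]


@dataclass
class ProvenanceRecord:
    stage: str
    parameters: dict
    seed: int | None
    timestamp: str
    config_hash: str
    software_version: str


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_provenance(path: Path | str, stage: str, parameters: dict, seed: int | None = None) -> ProvenanceRecord:
    """Serialize a provenance record next to a stage's outputs."""
    params = _jsonable(parameters)
    digest = hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]
    rec = ProvenanceRecord(
        stage=stage,
        parameters=params,
        seed=seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config_hash=digest,
        software_version=__version__,
    )
    Path(path).write_text(json.dumps(asdict(rec), indent=2))
    return rec


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

def write_movie(movie: FluorescenceMovie, path: Path | str) -> None:
    tifffile.imwrite(
        str(path),
        movie.frames,
        metadata={"frame_rate_hz": movie.frame_rate_hz, "pixel_size_um": movie.pixel_size_um},
    )


def read_movie(
    path: Path | str,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> FluorescenceMovie:
    """Read a multi-page TIFF; metadata written by :func:`write_movie` is
    recovered automatically, otherwise frame rate / pixel size must be given."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except Exception as exc:  # pragma: no cover - malformed input
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    fr = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if fr is None or px is None:
        raise ValueError("frame_rate_hz and pixel_size_um required (not found in TIFF metadata)")
    return FluorescenceMovie(frames=frames, frame_rate_hz=float(fr), pixel_size_um=float(px))


# --------------------------------------------------------------------------
# event catalogs
# --------------------------------------------------------------------------

def write_catalog(catalog: EventCatalog, path: Path | str) -> pd.DataFrame:
    """One row per event; an empty catalog yields a header-only CSV."""
    rows = [
        {
            "onset_s": ev.onset_s,
            "duration_s": ev.duration_s,
            "n_voxels": ev.n_voxels,
            "restricted_area_um2": ev.restricted_area_um2,
            "peak_dff": ev.peak_dff,
            "region": ev.region,
        }
        for ev in catalog.events
    ]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_catalog(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing columns: {missing}")
    return df


# --------------------------------------------------------------------------
# ROI traces
# --------------------------------------------------------------------------

def write_traces(traces: RoiTraceSet, h5_path: Path | str, positions_csv: Path | str | None = None) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("traces", data=traces.traces)
        f.create_dataset("cell_id", data=np.asarray(traces.cell_ids))
        f.create_dataset("x_um", data=traces.positions_um[:, 0])
        f.create_dataset("y_um", data=traces.positions_um[:, 1])
        f.attrs["frame_rate_hz"] = traces.frame_rate_hz
        f.attrs["application_time_s"] = traces.application_time_s
        f.attrs["baseline_span_s"] = traces.baseline_span_s
    if positions_csv is not None:
        pd.DataFrame(
            {
                "cell_id": np.asarray(traces.cell_ids),
                "x_um": traces.positions_um[:, 0],
                "y_um": traces.positions_um[:, 1],
            }
        ).to_csv(positions_csv, index=False)


def read_traces(h5_path: Path | str) -> RoiTraceSet:
    with h5py.File(h5_path, "r") as f:
        for key in ("traces", "cell_id", "x_um", "y_um"):
            if key not in f:
                raise ValueError(f"trace file {h5_path} missing dataset {key!r}")
        return RoiTraceSet(
            cell_ids=f["cell_id"][:],
            positions_um=np.stack([f["x_um"][:], f["y_um"][:]], axis=1),
            traces=f["traces"][:],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            application_time_s=float(f.attrs["application_time_s"]),
            baseline_span_s=float(f.attrs.get("baseline_span_s", 2700.0)),
        )


def read_positions(csv_path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"positions file {csv_path} missing columns: {missing}")
    return df


# --------------------------------------------------------------------------
# region masks and configs
# --------------------------------------------------------------------------

def read_region_masks(path: Path | str, shape: tuple[int, int] | None = None) -> list[RegionMask]:
    """Region masks from ``.npz`` (one boolean array per name) or JSON
    rectangles ``{"V1": [y0, y1, x0, x1], ...}`` (requires ``shape``)."""
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path)
        return [RegionMask(name=k, mask=data[k]) for k in data.files]
    if path.suffix == ".json":
        if shape is None:
            raise ValueError("shape required for rectangle-JSON region masks")
        spec = json.loads(path.read_text())
        masks = []
        for name, (y0, y1, x0, x1) in spec.items():
            m = np.zeros(shape, dtype=bool)
            m[y0:y1, x0:x1] = True
            masks.append(RegionMask(name=name, mask=m))
        return masks
    raise ValueError(f"unsupported region-mask format {path.suffix!r}")


def load_config(path: Path | str) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format {path.suffix!r}")
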