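"""HDF5 recording container and plain-text result export.

Container layout (schema_version "1"):

* ``/responses`` -- units x timepoints float32 dF/F
* ``/unit_labels`` -- int16 area code per unit (0 = background)
* ``/unit_coords`` -- units x 2 int32 pixel coordinates (wide-field only)
* ``/trials`` -- table of (stimulus_id, onset_frame, n_frames), half-open
  0-based frame windows
* ``/area_map`` -- rows x cols int16 raster (wide-field only)
* attributes -- ``schema_version``, ``frame_rate_hz``, ``mode``, ``seed``,
  ``sim_params`` (JSON string)

Results are exported as CSV/JSON (accuracy tables, confusion matrices,
merge logs) and parcellation rasters as portable graymaps (PGM, ASCII
``P2``) plus ``row,col,label`` CSV. Every exported file embeds the seed and
config hash that produced it, as a ``#``-comment header or a JSON field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .types import AreaMap, Recording, Trial

SCHEMA_VERSION = "1"

_TRIAL_DTYPE = np.dtype(
    [("stimulus_id", "<i8"), ("onset_frame", "<i8"), ("n_frames", "<i8")]
)


def write_container(
    path,
    rec: Recording,
    area_map: AreaMap | None = None,
    sim_params: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a recording (and optional area map) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=rec.responses.astype(np.float32))
        f.create_dataset("unit_labels", data=rec.unit_labels.astype(np.int16))
        trials = np.array(
            [(t.stimulus_id, t.onset_frame, t.n_frames) for t in rec.trials],
            dtype=_TRIAL_DTYPE,
        )
        f.create_dataset("trials", data=trials)
        if rec.unit_coords is not None:
            f.create_dataset("unit_coords", data=rec.unit_coords.astype(np.int32))
        if area_map is not None:
            f.create_dataset("area_map", data=area_map.labels.astype(np.int16))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate_hz"] = float(rec.frame_rate)
        f.attrs["mode"] = rec.mode
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if sim_params is not None:
            f.attrs["sim_params"] = json.dumps(sim_params)


def read_container(path) -> tuple[Recording, AreaMap | None]:
    """Read and validate a container; raises SchemaError on layout problems."""
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise SchemaError("missing schema_version attribute")
        version = str(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version!r}")
        mode = str(f.attrs.get("mode", ""))
        required = ["responses", "unit_labels", "trials"]
        if mode == "widefield":
            required += ["unit_coords"]
        for name in required:
            if name not in f:
                raise SchemaError(f"missing dataset /{name}")
        responses = f["responses"][...]
        labels = f["unit_labels"][...]
        trials = [Trial(int(t[0]), int(t[1]), int(t[2])) for t in f["trials"][...]]
        coords = f["unit_coords"][...] if "unit_coords" in f else None
        amap = None
        if "area_map" in f:
            amap = AreaMap(labels=f["area_map"][...].astype(np.int16))
        rec = Recording(
            responses=responses,
            unit_labels=labels,
            trials=trials,
            frame_rate=float(f.attrs["frame_rate_hz"]),
            mode=mode,
            unit_coords=coords,
        )
    rec.validate(amap)
    return rec, amap


# ---------------------------------------------------------------------------
# result export


def _header(seed=None, config_hash=None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return "# " + " ".join(parts) + "\n" if parts else ""


def write_eval_report(report, out_dir, seed=None, config_hash=None) -> dict[str, Path]:
    """Export an EvalReport as an accuracy CSV, confusion CSV and JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"supervised_{report.classifier}_{report.stimulus}"
    acc_path = out_dir / f"{stem}_accuracy.csv"
    with open(acc_path, "w") as fh:
        fh.write(_header(seed, config_hash))
        fh.write("repeat,classifier,stimulus,accuracy\n")
        for i, a in enumerate(report.accuracies):
            fh.write(f"{i},{report.classifier},{report.stimulus},{a!r}\n")
    conf_path = out_dir / f"{stem}_confusion.csv"
    with open(conf_path, "w") as fh:
        fh.write(_header(seed, config_hash))
        report.confusion.to_csv(fh)
    json_path = out_dir / f"{stem}_summary.json"
    payload = report.to_dict()
    payload.update({"seed": seed, "config_hash": config_hash})
    json_path.write_text(json.dumps(payload, indent=2))
    return {"accuracy": acc_path, "confusion": conf_path, "summary": json_path}


def write_pgm(path, raster: np.ndarray) -> None:
    """ASCII portable graymap (P2) of an integer raster."""
    raster = np.asarray(raster)
    rows, cols = raster.shape
    maxval = max(1, int(raster.max()))
    with open(path, "w") as fh:
        fh.write(f"P2\n{cols} {rows}\n{maxval}\n")
        for row in raster:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if tokens[0] != "P2":
        raise SchemaError("not an ASCII PGM (P2) file")
    cols, rows, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:], dtype=np.int64)
    return data.reshape(rows, cols)


def write_parcellation(
    raster: np.ndarray, out_dir, stem: str = "parcellation", seed=None, config_hash=None
) -> dict[str, Path]:
    """Export a label raster as PGM and as row,col,label CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pgm_path = out_dir / f"{stem}.pgm"
    write_pgm(pgm_path, raster)
    csv_path = out_dir / f"{stem}.csv"
    with open(csv_path, "w") as fh:
        fh.write(_header(seed, config_hash))
        fh.write("row,col,label\n")
        for r in range(raster.shape[0]):
            for c in range(raster.shape[1]):
                fh.write(f"{r},{c},{int(raster[r, c])}\n")
    return {"pgm": pgm_path, "csv": csv_path}


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None) -> Path:
    """Generic CSV export (merge logs, duration sweeps) with provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, config_hash))
        df.to_csv(fh, index=False)
    return path


def area_map_to_csv(area_map: AreaMap, path) -> Path:
    return write_table(
        pd.DataFrame(
            [
                {"row": r, "col": c, "label": int(area_map.labels[r, c])}
                for r in range(area_map.shape[0])
                for c in range(area_map.shape[1])
            ]
        ),
        path,
    )
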