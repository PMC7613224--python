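"""Plain-text I/O for spectra, metadata and bucket tables.

Spectra travel as two-column text: either CSV with a ``ppm,intensity``
header or JCAMP-DX-style whitespace/comma-separated pairs with ``##``
comment lines.  Bucket tables are CSV (header row of bucket centers) with
a JSON sidecar recording the grid and any fitted scaling parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import BucketTable, ScalingModel, Spectrum


def read_spectrum(path, sample_id: str | None = None) -> Spectrum:
    """Read a (ppm, intensity) trace from CSV or JCAMP-DX-like text."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("##") or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            continue  # header row
    if len(rows) < 2:
        raise DataError(f"{path}: no numeric (ppm, intensity) pairs found")
    arr = np.asarray(rows, dtype=float)
    return Spectrum(arr[:, 0], arr[:, 1], sample_id or path.stem)


def write_spectrum(s: Spectrum, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity})
    df.to_csv(path, index=False, float_format="%.8g")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata CSV: sample_id, label, referral_order[, ...]."""
    df = pd.read_csv(path)
    missing = {"sample_id", "label"} - set(df.columns)
    if missing:
        raise DataError(f"metadata is missing columns: {sorted(missing)}")
    return df


def write_bucket_table(t: BucketTable, path, scaling: ScalingModel | None = None) -> None:
    """CSV with bucket-center header plus a JSON sidecar of the grid."""
    path = Path(path)
    df = pd.DataFrame(t.matrix, index=t.sample_ids,
                      columns=[f"{c:.3f}" for c in t.bucket_centers])
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.8g")
    sidecar = {
        "bucket_width": t.bucket_width,
        "bucket_centers": [round(float(c), 6) for c in t.bucket_centers],
        "excluded_regions": [list(e) for e in t.excluded_regions],
        "scaled": t.scaled,
    }
    if scaling is not None:
        sidecar["scaling"] = {
            "mean": scaling.mean.tolist(),
            "scale": scaling.scale.tolist(),
            "degenerate": scaling.degenerate.astype(int).tolist(),
            "n_fitted": scaling.n_fitted,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_bucket_table(path, labels=None) -> BucketTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        centers = np.asarray(sidecar["bucket_centers"], dtype=float)
        width = sidecar["bucket_width"]
        excluded = tuple(tuple(e) for e in sidecar["excluded_regions"])
        scaled = sidecar.get("scaled", False)
    else:
        centers = df.columns.to_numpy(dtype=float)
        width = float(np.median(np.diff(centers))) if centers.size > 1 else 0.01
        excluded = ()
        scaled = False
    return BucketTable(df.to_numpy(dtype=float), centers, width,
                       list(df.index), labels, excluded, scaled)
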