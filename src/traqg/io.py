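"""File formats: TIFF image pairs, CSV tables, JSON calibration/manifests.

Channel order in 2-plane TIFF stacks is a convention, not metadata, in
most acquisitions; the default is FP first, SiR second, overridable
everywhere a stack is read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .pipeline import CellMeasurement
from .sensor import CalibrationCurve, SensorParams, TitrationSeries

__all__ = [
    "read_channel_pair",
    "write_channel_pair",
    "read_label_map",
    "write_label_map",
    "write_ratio_image",
    "read_titration_csv",
    "write_titration_csv",
    "read_calibration_json",
    "write_calibration_json",
    "write_sensor_params_json",
    "read_sensor_params_json",
    "measurements_to_frame",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_manifest",
    "package_version",
]


def package_version() -> str:
    try:
        return version("traqg")
    except PackageNotFoundError:  # running from a source tree
        return "0+unknown"


# ---------------------------------------------------------------------------
# images


def read_channel_pair(path, channel_order: str = "fp-first"):
    """Read a 2-plane TIFF stack into an FP/SiR pair of float arrays."""
    from .simulate import ChannelPair

    arr = tifffile.imread(str(path))
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError(
            f"{path}: expected a TIFF stack with >= 2 planes, got shape {arr.shape}"
        )
    a, b = arr[0].astype(np.float64), arr[1].astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"{path}: channel shapes differ: {a.shape} vs {b.shape}")
    if channel_order == "fp-first":
        fp, sir = a, b
    elif channel_order == "sir-first":
        fp, sir = b, a
    else:
        raise ValueError(f"unknown channel_order {channel_order!r}")
    return ChannelPair(fp=fp, sir=sir)


def write_channel_pair(path, pair) -> None:
    """Write an FP/SiR pair as a 2-plane float32 TIFF (FP first)."""
    stack = np.stack([pair.fp, pair.sir]).astype(np.float32)
    tifffile.imwrite(
        str(path), stack, metadata={"axes": "CYX", "channels": ["FP", "SiR"]}
    )


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_label_map(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16))


def write_ratio_image(path, values: np.ndarray) -> None:
    """Calibrated or raw ratio image as 32-bit float TIFF (NaN = undefined)."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


# ---------------------------------------------------------------------------
# tables


def write_titration_csv(path, series: TitrationSeries) -> None:
    sd = series.replicate_sd or [np.nan] * len(series)
    pd.DataFrame(
        {"conc_mM": series.concentrations_mM, "response": series.responses, "sd": sd}
    ).to_csv(path, index=False)


def read_titration_csv(path, response_kind: str = "sir_intensity") -> TitrationSeries:
    df = pd.read_csv(path)
    required = {"conc_mM", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: titration CSV needs columns {sorted(required)}")
    sd = None
    if "sd" in df.columns and df["sd"].notna().all():
        sd = tuple(float(v) for v in df["sd"])
    return TitrationSeries(
        concentrations_mM=tuple(float(v) for v in df["conc_mM"]),
        responses=tuple(float(v) for v in df["response"]),
        replicate_sd=sd,
        response_kind=response_kind,
    )


def measurements_to_frame(
    measurements: Sequence[CellMeasurement], fov: str = ""
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "fov": fov,
                "label": m.label,
                "area_px": m.area_px,
                "row": m.centroid[0],
                "col": m.centroid[1],
                "mean_ratio": m.mean_ratio,
                "gsh_mM": m.gsh_mM if m.gsh_mM is not None else np.nan,
                "extrapolated": m.extrapolated,
                "outlier": m.outlier,
                "n_valid_px": m.n_valid_px,
            }
        )
    cols = [
        "fov", "label", "area_px", "row", "col", "mean_ratio",
        "gsh_mM", "extrapolated", "outlier", "n_valid_px",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_measurements_csv(path, measurements, fov: str = "", calibrated=True) -> None:
    df = measurements_to_frame(measurements, fov=fov)
    if not calibrated:
        df = df.drop(columns=["gsh_mM", "extrapolated"])
    df.to_csv(path, index=False)


def read_measurements_csv(path) -> list[CellMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        gsh = r.get("gsh_mM", np.nan)
        out.append(
            CellMeasurement(
                label=int(r["label"]),
                area_px=int(r["area_px"]),
                centroid=(float(r["row"]), float(r["col"])),
                mean_ratio=float(r["mean_ratio"]),
                n_valid_px=int(r["n_valid_px"]),
                gsh_mM=None if pd.isna(gsh) else float(gsh),
                extrapolated=bool(r.get("extrapolated", False)),
                outlier=bool(r.get("outlier", False)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# JSON


def write_calibration_json(path, curve: CalibrationCurve) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2) + "\n")


def read_calibration_json(path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(json.loads(Path(path).read_text()))


def write_sensor_params_json(path, params: SensorParams) -> None:
    d = asdict(params)
    d["units"] = {
        "kd_mM": "mM",
        "brightness": "photons per expression unit per exposure",
        "kon_per_mM_s": "1/(mM s)",
        "koff_per_s": "1/s",
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_sensor_params_json(path) -> SensorParams:
    d = json.loads(Path(path).read_text())
    d.pop("units", None)
    return SensorParams(**d)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, stage: str, config: dict, outputs: Sequence[str],
                   counts: dict | None = None, seed: int | None = None) -> dict:
    """Run manifest: everything needed to reproduce a deterministic stage."""
    manifest = {
        "stage": stage,
        "schema_version": 1,
        "software_version": package_version(),
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
        "outputs": list(outputs),
        "counts": counts or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
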