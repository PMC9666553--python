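"""Readers and writers for images, masks, phase maps and CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .hydraulics import PressureSeries

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_phase_map",
    "read_phase_map",
    "read_pressure_csv",
    "write_pressure_csv",
    "QUANT_COLUMNS",
    "write_quant_csv",
    "read_quant_csv",
    "write_aggregate_csv",
]

#: Fixed header of the per-position quantification table.
QUANT_COLUMNS = [
    "position",
    "x_mm",
    "bact_coverage_um2",
    "bact_count",
    "bact_conc_per_mL",
    "n_crystals",
    "mean_D_um",
    "mass_g",
    "PV_l_uL",
    "efficiency_pct",
]

PRESSURE_COLUMNS = ["time_s", "p1_mbar", "p2_mbar"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG image and normalize intensities to float [0, 1].

    Integer images are divided by the dtype maximum (255 for 8-bit, 65535
    for 16-bit); float images pass through.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / float(np.iinfo(img.dtype).max)
    return np.asarray(img, dtype=float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float raster as 32-bit TIFF or 8-bit PNG by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG (or TIFF)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    img = read_image(path)
    return img > 0.5


def write_phase_map(path: str | Path, labels: np.ndarray) -> None:
    """Write a {0..3} label raster as an indexed 8-bit PNG."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 3:
        raise ValueError("phase map labels must lie in {0, 1, 2, 3}")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_phase_map(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr.astype(np.uint8)


def read_pressure_csv(
    path: str | Path,
    flow_phases: Iterable[tuple[float, float]] = (),
) -> PressureSeries:
    """Read a pressure CSV with columns time_s, p1_mbar, p2_mbar."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: cannot parse pressure CSV ({exc})") from exc
    missing = [c for c in PRESSURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pressure columns {missing}")
    try:
        return PressureSeries(
            time_s=df["time_s"].to_numpy(dtype=float),
            p1_mbar=df["p1_mbar"].to_numpy(dtype=float),
            p2_mbar=df["p2_mbar"].to_numpy(dtype=float),
            flow_phases=tuple(flow_phases),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_pressure_csv(path: str | Path, series: PressureSeries) -> None:
    pd.DataFrame(
        {
            "time_s": series.time_s,
            "p1_mbar": series.p1_mbar,
            "p2_mbar": series.p2_mbar,
        }
    ).to_csv(path, index=False)


def write_quant_csv(path: str | Path, rows: list[dict]) -> None:
    """Write per-position quantities with the fixed QUANT_COLUMNS header."""
    df = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_quant_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing quantification columns {missing}")
    return df


def write_aggregate_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
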