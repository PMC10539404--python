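"""Readers and writers for stacks, metric planes, tile tables, and counts.

Interferometric stacks travel either as OME-TIFF (16-bit, axes TYX, frame
interval in the OME metadata) or as raw little-endian binary with a JSON
sidecar recording shape, dtype, and frame rate.  Metric planes are written
as a 3-plane 32-bit float TIFF (mean frequency, frequency spread, amplitude)
with a JSON sidecar for the processing configuration; renders as 8-bit PNG.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .dynamics import DynamicMetrics, MetricConfig
from .signal_model import (
    CameraConfig,
    InterferometricStack,
    OpticsConfig,
    StainedZStack,
    TileSet,
    quantize_counts,
)

__all__ = [
    "write_stack_ome_tiff",
    "read_stack_ome_tiff",
    "write_stack_raw",
    "read_stack_raw",
    "write_metrics_tiff",
    "read_metrics_tiff",
    "write_render_png",
    "write_tile_positions_csv",
    "read_tile_positions_csv",
    "write_tile_set",
    "write_zstack_tiff",
    "write_zstack_truth",
]


def write_stack_ome_tiff(stack: InterferometricStack, path: str | Path) -> None:
    """Write a stack as 16-bit OME-TIFF with the frame interval in metadata."""
    data = quantize_counts(stack.intensities)
    metadata = {
        "axes": "TYX",
        "TimeIncrement": 1.0 / stack.frame_rate_hz,
        "TimeIncrementUnit": "s",
    }
    if stack.camera is not None:
        metadata["ExposureTime"] = stack.camera.exposure_s
        metadata["ExposureTimeUnit"] = "s"
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def read_stack_ome_tiff(path: str | Path) -> InterferometricStack:
    """Read a stack written by :func:`write_stack_ome_tiff`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome = tifffile.xml2dict(tif.ome_metadata)
    pixels = ome["OME"]["Image"]["Pixels"]
    increment = float(pixels["TimeIncrement"])
    return InterferometricStack(
        intensities=data.astype(np.float64),
        frame_rate_hz=1.0 / increment,
    )


def write_stack_raw(stack: InterferometricStack, path: str | Path) -> None:
    """Write a stack as raw uint16 (little-endian) plus a JSON sidecar."""
    path = Path(path)
    data = quantize_counts(stack.intensities).astype("<u2")
    data.tofile(path)
    sidecar = {
        "shape": list(stack.shape),
        "dtype": "<u2",
        "frame_rate_hz": stack.frame_rate_hz,
    }
    if stack.camera is not None:
        sidecar["camera"] = dataclasses.asdict(stack.camera)
    if stack.optics is not None:
        sidecar["optics"] = dataclasses.asdict(stack.optics)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_stack_raw(path: str | Path) -> InterferometricStack:
    """Read a raw binary stack and its JSON sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    camera = (
        CameraConfig(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in sidecar["camera"].items()})
        if "camera" in sidecar
        else None
    )
    optics = OpticsConfig(**sidecar["optics"]) if "optics" in sidecar else None
    return InterferometricStack(
        intensities=data.astype(np.float64),
        frame_rate_hz=float(sidecar["frame_rate_hz"]),
        camera=camera,
        optics=optics,
    )


def write_metrics_tiff(metrics: DynamicMetrics, path: str | Path) -> None:
    """Write the three metric planes as one 32-bit float TIFF + JSON sidecar.

    Plane order: mean frequency (Hz), frequency spread (Hz), amplitude
    (counts).
    """
    path = Path(path)
    planes = np.stack(
        [
            metrics.mean_frequency_hz,
            metrics.frequency_std_hz,
            metrics.amplitude,
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(dataclasses.asdict(metrics.config), indent=2)
    )


def read_metrics_tiff(path: str | Path) -> DynamicMetrics:
    """Read metric planes written by :func:`write_metrics_tiff`."""
    path = Path(path)
    planes = tifffile.imread(path).astype(np.float64)
    raw = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw["brightness_percentiles"] = tuple(raw["brightness_percentiles"])
    config = MetricConfig(**raw)
    return DynamicMetrics(
        mean_frequency_hz=planes[0],
        frequency_std_hz=planes[1],
        amplitude=planes[2],
        config=config,
    )


def write_render_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write an RGB render in [0, 1] as an 8-bit PNG."""
    iio.imwrite(
        Path(path), np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    )


def write_tile_positions_csv(
    positions: np.ndarray, grid_shape: tuple[int, int], path: str | Path
) -> None:
    """Write tile top-left corners as CSV.

    Columns: ``tile_id, grid_row, grid_col, x_px, y_px`` with 0-based pixel
    coordinates, x rightward and y downward.
    """
    g_rows, g_cols = grid_shape
    rows = [
        {
            "tile_id": i,
            "grid_row": i // g_cols,
            "grid_col": i % g_cols,
            "x_px": int(positions[i, 1]),
            "y_px": int(positions[i, 0]),
        }
        for i in range(len(positions))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tile_positions_csv(path: str | Path) -> np.ndarray:
    """Read a tile position table back into an (n, 2) array of (y, x)."""
    df = pd.read_csv(path).sort_values("tile_id")
    return df[["y_px", "x_px"]].to_numpy(dtype=np.int64)


def write_tile_set(tile_set: TileSet, directory: str | Path) -> None:
    """Write each tile as TIFF plus the true-offset table as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, tile in enumerate(tile_set.tiles):
        tifffile.imwrite(directory / f"tile_{i:03d}.tif", tile.astype(np.float32))
    write_tile_positions_csv(
        tile_set.true_offsets, tile_set.grid_shape, directory / "true_offsets.csv"
    )


def write_zstack_tiff(zstack: StainedZStack, path: str | Path) -> None:
    """Write a stained z-stack as a 16-bit multi-page TIFF."""
    tifffile.imwrite(path, quantize_counts(zstack.stack))


def write_zstack_truth(zstack: StainedZStack, path: str | Path) -> None:
    """Write the ground-truth count and nucleus centers as JSON."""
    truth = {
        "n_cells": int(len(zstack.centers)),
        "cell_area_px": zstack.cell_area_px,
        "centers_rc": zstack.centers.tolist(),
        "planes": zstack.planes.tolist(),
    }
    Path(path).write_text(json.dumps(truth, indent=2))
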