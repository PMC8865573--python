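"""File formats: multi-page 16-bit TIFF stacks with JSON manifests, and
CSV/JSON result artifacts.

The manifest (not filename conventions) is authoritative for grid
coordinates: it records the grid definition, the seed and the configuration
hash alongside the stack.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .classify import ClassMetrics, ConfusionMatrix
from .demux import DemuxResult
from .extract import IntensityMap, KtMap
from .optics import FarFieldImage, RelayOptics
from .simulate import ScanGrid

__all__ = [
    "write_stack",
    "read_stack",
    "write_manifest",
    "read_manifest",
    "write_results",
]


def write_stack(
    stack: Sequence[FarFieldImage], path: str | Path, relay: RelayOptics
) -> Path:
    """Write a far-field stack as a multi-page 16-bit grayscale TIFF,
    pages in stack (grid row-major) order."""
    path = Path(path)
    pages = np.stack(
        [np.clip(np.rint(img.intensity), 0, 2**16 - 1).astype(np.uint16) for img in stack]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


def read_stack(path: str | Path, relay: RelayOptics) -> list[FarFieldImage]:
    """Read a multi-page grayscale TIFF back into FarFieldImage objects,
    validating shape against the relay configuration."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing TIFF file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise ValueError(f"not a readable TIFF file: {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected grayscale pages, got array of shape {arr.shape}")
    if arr.shape[1:] != tuple(relay.image_shape):
        raise ValueError(
            f"page shape {arr.shape[1:]} does not match relay {relay.image_shape}"
        )
    return [
        FarFieldImage(
            intensity=page.astype(float),
            pixel_pitch=relay.pixel_pitch,
            center=relay.center,
            meta={"page": k},
        )
        for k, page in enumerate(arr)
    ]


def write_manifest(
    path: str | Path,
    grid: ScanGrid | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    doc: dict = {}
    if grid is not None:
        doc["grid"] = {
            "n_x": grid.n_x,
            "n_z": grid.n_z,
            "spacing": grid.spacing,
            "origin": list(grid.origin),
            "points": [[float(x), float(z)] for x, z in grid.points],
        }
    if seed is not None:
        doc["seed"] = int(seed)
    if config_hash is not None:
        doc["config_hash"] = config_hash
    doc.update(extra or {})
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"malformed manifest: {path}")
    return doc


def grid_from_manifest(doc: dict) -> ScanGrid:
    g = doc["grid"]
    return ScanGrid(
        n_x=int(g["n_x"]),
        n_z=int(g["n_z"]),
        spacing=float(g["spacing"]),
        origin=tuple(g["origin"]),
    )


def write_results(
    outdir: str | Path,
    ktmap: KtMap | None = None,
    imap: IntensityMap | None = None,
    cm: ConfusionMatrix | None = None,
    metrics: ClassMetrics | None = None,
    demux_result: DemuxResult | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> dict:
    """Write CSV/JSON artifacts plus a manifest; returns the manifest dict.

    Re-running with identical inputs overwrites the files identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    if ktmap is not None:
        df = ktmap.as_frame()
        if imap is not None:
            df = df.assign(intensity=imap.values)
        df.to_csv(outdir / "kt_map.csv", index=False)
        files["kt_map"] = "kt_map.csv"
    elif imap is not None:
        imap.as_frame().to_csv(outdir / "intensity_map.csv", index=False)
        files["intensity_map"] = "intensity_map.csv"
    if cm is not None:
        cm.as_frame().to_csv(outdir / "confusion_matrix.csv")
        files["confusion_matrix"] = "confusion_matrix.csv"
    if metrics is not None:
        metrics.as_frame().to_csv(outdir / "class_metrics.csv")
        (outdir / "class_metrics.json").write_text(
            json.dumps(
                {
                    "overall_accuracy": metrics.overall_accuracy,
                    "per_class": json.loads(
                        metrics.as_frame().to_json(orient="index")
                    ),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        files["class_metrics"] = "class_metrics.csv"
    if demux_result is not None:
        demux_result.as_frame().to_csv(outdir / "demux_percentages.csv")
        files["demux_percentages"] = "demux_percentages.csv"
    manifest = {"files": files}
    if seed is not None:
        manifest["seed"] = int(seed)
    if config_hash is not None:
        manifest["config_hash"] = config_hash
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
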