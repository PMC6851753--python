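"""Plain-text output: ESRI ASCII grids, CSV tables and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import LandscapeGrid

__all__ = ["write_ascii_grid", "write_landscape_layers", "write_manifest"]


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    n_rows: int,
    n_cols: int,
    cellsize: float = 1000.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999,
) -> Path:
    """Write one layer as an ESRI ASCII grid (row-major, north-up)."""
    path = Path(path)
    arr = np.asarray(values).reshape(n_rows, n_cols)
    with path.open("w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in arr:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")
    return path


def write_landscape_layers(grid: LandscapeGrid, out_dir: str | Path) -> list[Path]:
    """Write each landscape layer as a single-band ASCII grid."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    layers = {
        "ecoregion": grid.ecoregion,
        "county": grid.county,
        "ownership": grid.ownership,
        "state_class": grid.state_class,
        "age": grid.age,
        "tst": grid.tst,
        "protected": grid.protected.astype(int),
        "npp_multiplier": grid.npp_multiplier,
        "fire_rel_prob": grid.fire_rel_prob,
        "drought_rel_prob": grid.drought_rel_prob,
    }
    cellsize = float(np.sqrt(grid.cell_area)) * 1000.0  # km -> m
    for name, vals in layers.items():
        written.append(
            write_ascii_grid(out_dir / f"{name}.asc", vals, grid.n_rows, grid.n_cols, cellsize)
        )
    return written


def write_manifest(path: str | Path, **entries) -> Path:
    """Record seeds and run parameters as JSON for reproducibility."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
    return path
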