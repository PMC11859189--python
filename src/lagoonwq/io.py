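"""Raster and tabular input/output.

Scenes and thematic maps are written as multiband TIFF (bands last in
memory, first on disk) with a JSON metadata tag carrying the
processing state, band labels, geotransform, units and provenance.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import tifffile

from .bands import PERUSAT1
from .mapping import ThematicMap
from .radiometry import Scene, SceneState

__all__ = ["write_scene", "read_scene", "write_thematic_map"]


def write_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene as a band-first multiband TIFF with JSON metadata."""
    meta = {
        "state": scene.state.value,
        "bands": scene.band_set.labels,
        "transform": list(scene.transform),
        "crs": scene.crs,
        "date": scene.date.isoformat() if scene.date else None,
    }
    tifffile.imwrite(
        str(path),
        np.moveaxis(scene.data, -1, 0),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_scene(path: str | Path) -> Scene:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    date = meta.get("date")
    return Scene(
        data=np.moveaxis(data, 0, -1),
        state=SceneState(meta.get("state", "DN")),
        band_set=PERUSAT1,
        transform=tuple(meta.get("transform", (0.0, 1.0, 0.0, -1.0))),
        crs=meta.get("crs", "local"),
        date=_dt.date.fromisoformat(date) if date else None,
    )


def write_thematic_map(tmap: ThematicMap, path: str | Path) -> None:
    """Write a single-band thematic map with units/provenance metadata."""
    meta = {
        "variable": tmap.variable,
        "units": tmap.units,
        "date": tmap.date.isoformat() if tmap.date else None,
        "season": tmap.season,
        "mask_provenance": tmap.mask_provenance,
        "clamp_low": tmap.clamp_low,
        "clamp_high": tmap.clamp_high,
        **tmap.metadata,
    }
    tifffile.imwrite(str(path), tmap.data.astype(np.float32), description=json.dumps(meta))
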