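"""Thematic mapping: apply retrieval models to masked reflectance rasters.

Water is separated from land by its low near-infrared reflectance
(band B4 below a threshold, default 0.2). A retrieval model evaluates
pixelwise on the water pixels; outputs are clamped to the model's
valid range with clamp counts recorded, and everything else carries
the nodata value. Maps can be grouped into a season-ordered series
(meteorological seasons: DJF winter, MAM spring, JJA summer, SON
autumn) and two sensors' point predictions can be compared against
field data side by side.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import summary_stats
from .radiometry import Scene, SceneState
from .registry import RetrievalModel
from .samples import FieldSample

__all__ = [
    "ThematicMap",
    "water_mask",
    "apply_model",
    "compare_sensors",
    "seasonal_map_series",
    "season_of",
]

DEFAULT_NIR_THRESHOLD = 0.2

_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
SEASON_ORDER = ["winter", "spring", "summer", "autumn"]


def season_of(date: _dt.date) -> str:
    """Meteorological season of a calendar date."""
    return _SEASONS[date.month]


@dataclass
class ThematicMap:
    """A retrieved-variable raster with units and clamp accounting."""

    data: np.ndarray
    variable: str
    units: str
    date: _dt.date | None = None
    season: str | None = None
    mask_provenance: str = ""
    clamp_low: int = 0
    clamp_high: int = 0
    n_nodata: int = 0
    nodata: float = np.nan
    metadata: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.data)))


def water_mask(
    scene: Scene,
    nir_threshold: float = DEFAULT_NIR_THRESHOLD,
) -> np.ndarray:
    """Boolean water raster: NIR (B4) surface reflectance below threshold."""
    if scene.state != SceneState.SURFACE_REFLECTANCE:
        raise ValueError("water_mask requires a surface-reflectance scene")
    mask = scene.band("B4") < nir_threshold
    if not mask.any():
        warnings.warn(
            "water mask is empty: no pixel below the NIR threshold", RuntimeWarning
        )
    return mask


def apply_model(
    scene: Scene,
    model: RetrievalModel,
    mask: np.ndarray,
) -> ThematicMap:
    """Evaluate a retrieval model over the water pixels of a scene.

    Division-by-zero pixels become nodata (counted); outputs are
    clamped to the model's valid range with low/high clamp counts.
    """
    if scene.state != SceneState.SURFACE_REFLECTANCE:
        raise ValueError("apply_model requires a surface-reflectance scene")
    if mask.shape != scene.shape:
        raise ValueError("mask dimensions do not match the scene")
    if not mask.any():
        raise ValueError("cannot apply a model on an empty water mask")
    spectra = scene.data[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.asarray(model.predict(spectra), dtype=float)
    lo, hi = model.valid_output_range
    finite = np.isfinite(values)
    clamp_low = int(np.sum(finite & (values < lo)))
    clamp_high = int(np.sum(finite & (values > hi)))
    values = np.where(finite, np.clip(values, lo, hi), np.nan)
    out = np.full(scene.shape, np.nan)
    out[mask] = values
    date = scene.date
    return ThematicMap(
        data=out,
        variable=model.variable,
        units=model.units,
        date=date,
        season=season_of(date) if date else None,
        mask_provenance=f"NIR threshold mask, {int(mask.sum())} water px",
        clamp_low=clamp_low,
        clamp_high=clamp_high,
        n_nodata=int(out.size - np.sum(np.isfinite(out))),
        metadata={"model": model.expression, "sensor": model.sensor},
    )


def compare_sensors(
    predictions_a: dict[str, float],
    predictions_b: dict[str, float],
    fieldsamples: list[FieldSample],
    variable: str,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Side-by-side validation statistics of two sensors' point predictions.

    Predictions are keyed by point id; only points present in both
    prediction sets and carrying a finite field value enter the
    comparison.
    """
    field_vals = {
        s.point_id: getattr(s, variable)
        for s in fieldsamples
        if np.isfinite(getattr(s, variable))
    }
    common = sorted(set(predictions_a) & set(predictions_b) & set(field_vals))
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 common points with field {variable}, got {len(common)}"
        )
    obs = np.array([field_vals[p] for p in common])
    rows = []
    for label, preds in zip(labels, (predictions_a, predictions_b)):
        est = np.array([preds[p] for p in common])
        st = summary_stats(obs, est)
        rows.append(
            {
                "variable": variable,
                "satellite": label,
                "r2": st.r_squared,
                "rmse": st.rmse,
                "nrmse_pct": st.nrmse_pct,
                "mae": st.mae,
                "bias": st.bias,
                "n": st.n,
            }
        )
    return pd.DataFrame(rows)


def seasonal_map_series(
    scenes: dict[_dt.date, Scene],
    model: RetrievalModel,
    masks: dict[_dt.date, np.ndarray],
) -> list[ThematicMap]:
    """One thematic map per scene, ordered winter -> autumn then by date."""
    if not scenes:
        raise ValueError("scene collection is empty")
    maps = []
    for date in sorted(scenes):
        scene = scenes[date]
        if scene.date is None:
            scene.date = date
        maps.append(apply_model(scene, model, masks[date]))
    maps.sort(key=lambda m: (SEASON_ORDER.index(m.season), m.date))
    return maps
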