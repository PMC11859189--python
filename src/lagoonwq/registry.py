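"""Published water-quality retrieval models.

Two model families are registered verbatim:

* the five PerúSAT-1 algorithms calibrated over the hypertrophic
  Albufera lagoon (linear functions of one two-band index of the
  4-band set B1..B4), and
* the five Sentinel-2 algorithms from earlier Albufera studies, which
  use reflectance at named wavelengths (R490, R560, R665, R705, R740,
  R783), including the three-band Chl-a model
  TBDO = R740 * (1/R665 - 1/R705).

PerúSAT-1 models evaluate on a 4-band spectrum (or directly on an
index value); Sentinel-2 models evaluate on a 6-value mapping keyed by
wavelength name. No spectral resampling between the two sensors is
attempted.

Default valid output ranges for thematic mapping extend the observed
calibration range by 50% headroom above the maximum and floor it at 0
(Secchi depth at 0.01 m): empirical regressions extrapolate poorly,
and display palettes are bounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .bands import PERUSAT1
from .calibration import FitModel
from .indices import IndexSpec, compute_index
from .samples import UNITS

__all__ = ["RetrievalModel", "published_registry", "get_model", "S2_BAND_NAMES"]

S2_BAND_NAMES = ["R490", "R560", "R665", "R705", "R740", "R783"]


@dataclass(frozen=True)
class RetrievalModel:
    """One published retrieval algorithm with its validation pedigree."""

    sensor: str
    variable: str
    units: str
    expression: str
    valid_output_range: tuple[float, float]
    observed_range: tuple[float, float]
    n: int | None = None
    r_squared: float | None = None
    rmse: float | None = None
    nrmse_pct: float | None = None
    mae: float | None = None
    bias: float | None = None
    provenance: str = ""
    fit: FitModel | None = field(default=None, compare=False)
    _evaluator: Callable | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.valid_output_range
        if not lo < hi:
            raise ValueError("valid_output_range min must be < max")

    def evaluate_index(self, x) -> np.ndarray | float:
        """Evaluate the fitted function at given index value(s)."""
        if self.fit is None:
            raise ValueError(
                f"{self.sensor} {self.variable} model is not a single-index fit"
            )
        out = self.fit.predict(np.asarray(x, dtype=float))
        if np.ndim(out) == 0:
            return float(out)
        return out

    def predict(self, spectrum) -> np.ndarray | float:
        """Evaluate on reflectance: (..., 4) array or wavelength-keyed mapping."""
        if self._evaluator is not None:
            return self._evaluator(spectrum)
        x = compute_index(spectrum, self.fit.index, PERUSAT1.labels)
        return self.fit.predict(np.asarray(x))


def _linear(sensor, variable, slope, intercept, index, obs_range, printed, **stats):
    fit = FitModel("linear", (slope, intercept), variable=variable, index=index)
    lo, hi = obs_range
    vmin = 0.01 if variable == "sdd" else 0.0
    return RetrievalModel(
        sensor=sensor,
        variable=variable,
        units=UNITS[variable],
        expression=printed,
        valid_output_range=(vmin, hi * 1.5),
        observed_range=obs_range,
        fit=fit,
        **stats,
    )


def _s2_model(variable, expression, evaluator, obs_range, **stats):
    lo, hi = obs_range
    vmin = 0.01 if variable == "sdd" else 0.0
    return RetrievalModel(
        sensor="Sentinel-2",
        variable=variable,
        units=UNITS[variable],
        expression=expression,
        valid_output_range=(vmin, hi * 1.5),
        observed_range=obs_range,
        _evaluator=evaluator,
        **stats,
    )


def _s2_get(spectrum: Mapping, name: str):
    try:
        return np.asarray(spectrum[name], dtype=float)
    except KeyError as exc:
        raise KeyError(f"Sentinel-2 model needs reflectance {name}") from exc


def _s2_chla(spectrum):
    tbdo = _s2_get(spectrum, "R740") * (
        1.0 / _s2_get(spectrum, "R665") - 1.0 / _s2_get(spectrum, "R705")
    )
    return 104.1 * tbdo**2 + 221.1 * tbdo + 2.0


def _s2_sdd(spectrum):
    return 0.224 * (_s2_get(spectrum, "R560") / _s2_get(spectrum, "R705")) + 0.0836


def _s2_tsm(spectrum):
    return 705.98 * _s2_get(spectrum, "R783") * _s2_get(spectrum, "R705") / _s2_get(
        spectrum, "R490"
    )


def _s2_pim(spectrum):
    return 259.4 * _s2_get(spectrum, "R705")


def _s2_pom(spectrum):
    return 40.48 * _s2_get(spectrum, "R783") / _s2_get(spectrum, "R490")


def published_registry() -> list[RetrievalModel]:
    """The ten published retrieval models (five per sensor), verbatim."""
    p1 = "PerúSAT-1"
    models = [
        _linear(
            p1, "chl_a", 323.77, 198.95, IndexSpec("ND", "B4", "B1"),
            (21.0, 331.0), "Chl-a = 323.77 ND(B4,B1) + 198.95",
            n=21, r_squared=0.76, rmse=50.8, nrmse_pct=16, mae=43.9, bias=-0.0049,
            provenance="summary of best 4-band algorithms; range 21-331 ug/L",
        ),
        _linear(
            p1, "sdd", -0.2539, 0.2608, IndexSpec("ND", "B4", "B1"),
            (0.16, 0.42), "SDD = -0.2539 ND(B4,B1) + 0.2608",
            n=22, r_squared=0.76, rmse=0.039, nrmse_pct=15, mae=0.031, bias=0.00003,
            provenance="summary of best 4-band algorithms; range 0.16-0.42 m",
        ),
        _linear(
            p1, "tsm", -38.259, 129.38, IndexSpec("SR", "B1", "B4"),
            (39.0, 136.0), "TSM = -38.259 (B1/B4) + 129.38",
            n=12, r_squared=0.85, rmse=11.1, nrmse_pct=11, mae=7.0, bias=0.0033,
            provenance=(
                "summary of best 4-band algorithms; working range 39-136 mg/L "
                "(summary table prints 50-136; only 39-136 is consistent with "
                "the printed NRMSE of 11%)"
            ),
        ),
        _linear(
            p1, "pim", 116.08, 31.36, IndexSpec("ND", "B3", "B1"),
            (2.0, 75.0), "PIM = 116.08 ND(B3,B1) + 31.36",
            n=12, r_squared=0.76, rmse=10.7, nrmse_pct=15, mae=8.0, bias=0.0002,
            provenance="summary of best 4-band algorithms; range 2-75 mg/L",
        ),
        _linear(
            p1, "pom", -18.775, 70.925, IndexSpec("SR", "B3", "B4"),
            (7.0, 60.0), "POM = -18.775 (B3/B4) + 70.925",
            n=12, r_squared=0.87, rmse=4.7, nrmse_pct=9, mae=4.2, bias=-0.0003,
            provenance="summary of best 4-band algorithms; range 7-60 mg/L",
        ),
        _s2_model(
            "chl_a",
            "Chl-a = 104.1 TBDO^2 + 221.1 TBDO + 2; TBDO = R740 (1/R665 - 1/R705)",
            _s2_chla, (21.0, 331.0), r_squared=0.99, rmse=40.0,
            provenance="three-band (TBDO) Albufera Chl-a model",
        ),
        _s2_model(
            "sdd", "SDD = 0.224 (R560/R705) + 0.0836",
            _s2_sdd, (0.16, 0.42), r_squared=0.67, rmse=0.07,
            provenance="Albufera Secchi-depth model",
        ),
        _s2_model(
            "tsm", "TSM = 705.98 R783 R705 / R490",
            _s2_tsm, (39.0, 136.0), r_squared=0.91, rmse=26.64,
            provenance="Albufera TSM model",
        ),
        _s2_model(
            "pim", "PIM = 259.4 R705",
            _s2_pim, (2.0, 75.0), r_squared=0.79, rmse=25.83,
            provenance="Albufera PIM model",
        ),
        _s2_model(
            "pom", "POM = 40.48 R783 / R490",
            _s2_pom, (7.0, 60.0), r_squared=0.91, rmse=14.42,
            provenance="Albufera POM model",
        ),
    ]
    return models


def get_model(sensor: str, variable: str) -> RetrievalModel:
    """Registry lookup by sensor label and variable short name."""
    for m in published_registry():
        if m.sensor == sensor and m.variable == variable:
            return m
    raise KeyError(f"no published model for sensor={sensor!r}, variable={variable!r}")


def registry_to_json(path: str | Path) -> None:
    """Serialize the registry (coefficients and pedigree) to JSON."""
    rows = []
    for m in published_registry():
        rows.append(
            {
                "sensor": m.sensor,
                "variable": m.variable,
                "units": m.units,
                "expression": m.expression,
                "coefficients": list(m.fit.coefficients) if m.fit else None,
                "index": m.fit.index.name if m.fit and m.fit.index else None,
                "observed_range": list(m.observed_range),
                "valid_output_range": list(m.valid_output_range),
                "n": m.n,
                "r2": m.r_squared,
                "rmse": m.rmse,
                "nrmse_pct": m.nrmse_pct,
                "mae": m.mae,
                "bias": m.bias,
                "provenance": m.provenance,
            }
        )
    Path(path).write_text(json.dumps(rows, indent=2))
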