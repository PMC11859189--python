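"""Field-sample records for water-quality variables.

A field sample holds the five limnological variables measured at one
sampling point: chlorophyll-a (µg/L), Secchi disk depth (m), total
suspended matter and its inorganic and organic fractions (mg/L).
Gravimetry determines TSM and PIM directly; POM is the difference, so
TSM = PIM + POM holds by construction whenever all three are present.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Variable short names, in canonical order.
VARIABLES = ["chl_a", "sdd", "tsm", "pim", "pom"]

UNITS = {
    "chl_a": "ug/L",
    "sdd": "m",
    "tsm": "mg/L",
    "pim": "mg/L",
    "pom": "mg/L",
}

#: Observed variable ranges in the hypertrophic-lagoon calibration data.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "chl_a": (21.0, 331.0),
    "sdd": (0.16, 0.42),
    "tsm": (39.0, 136.0),
    "pim": (2.0, 75.0),
    "pom": (7.0, 60.0),
}

#: CSV column header used for campaign tables.
CSV_COLUMNS = [
    "point_id",
    "date",
    "chl_a_ug_L",
    "sdd_m",
    "tsm_mg_L",
    "pim_mg_L",
    "pom_mg_L",
]

_CSV_TO_VAR = {
    "chl_a_ug_L": "chl_a",
    "sdd_m": "sdd",
    "tsm_mg_L": "tsm",
    "pim_mg_L": "pim",
    "pom_mg_L": "pom",
}
_VAR_TO_CSV = {v: k for k, v in _CSV_TO_VAR.items()}

_TSM_ADDITIVITY_TOL = 1e-9


@dataclass
class FieldSample:
    """One sampling point's water-quality variables; any may be missing (NaN)."""

    point_id: str
    campaign_date: _dt.date
    chl_a: float = np.nan
    sdd: float = np.nan
    tsm: float = np.nan
    pim: float = np.nan
    pom: float = np.nan

    def __post_init__(self) -> None:
        for name in ("chl_a", "tsm", "pim", "pom"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if np.isfinite(self.sdd) and self.sdd <= 0:
            raise ValueError(f"sdd must be > 0, got {self.sdd}")
        if all(np.isfinite([self.tsm, self.pim, self.pom])):
            if abs(self.tsm - self.pim - self.pom) > _TSM_ADDITIVITY_TOL:
                raise ValueError(
                    "TSM = PIM + POM violated: "
                    f"{self.tsm} != {self.pim} + {self.pom}"
                )

    def is_complete(self, variables: list[str] | None = None) -> bool:
        variables = variables or VARIABLES
        return bool(np.all(np.isfinite([getattr(self, v) for v in variables])))


def samples_to_frame(samples: list[FieldSample]) -> pd.DataFrame:
    """Tabulate samples with the canonical CSV column names."""
    rows = []
    for s in samples:
        rows.append(
            {
                "point_id": s.point_id,
                "date": s.campaign_date.isoformat(),
                **{_VAR_TO_CSV[v]: getattr(s, v) for v in VARIABLES},
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_samples(frame: pd.DataFrame) -> list[FieldSample]:
    out = []
    for _, row in frame.iterrows():
        date = row["date"]
        if not isinstance(date, _dt.date):
            date = _dt.date.fromisoformat(str(date)[:10])
        kwargs = {
            v: float(row[c]) if pd.notna(row[c]) else np.nan
            for c, v in _CSV_TO_VAR.items()
        }
        out.append(FieldSample(str(row["point_id"]), date, **kwargs))
    return out


def read_samples(path: str | Path) -> list[FieldSample]:
    return frame_to_samples(pd.read_csv(path))


def write_samples(samples: list[FieldSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)
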