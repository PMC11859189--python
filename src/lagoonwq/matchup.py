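"""Matchup construction: pairing ROI-mean image spectra with field samples.

A matchup pairs one field sample with the nearest-in-time scene whose
acquisition lies within an allowed lag (default 3 days). Around each
sampling point a square region of interest is grown until its
water-pixel count falls in a target range (default 100-150 pixels),
and the per-band mean and standard deviation over water pixels form
the matchup spectrum.

Two supporting statistics accompany the database: a paired Student's
t-test on band reflectance comparing the water spectrum at the image
and sampling dates (spectral stability under nonzero lag), and the
cross-correlation of the field variables gated by a Shapiro-Wilk
normality test — Pearson where both margins pass, Spearman otherwise,
with pairwise-complete sample counts reported per coefficient.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .radiometry import Scene, SceneState
from .samples import FieldSample, VARIABLES

__all__ = [
    "MatchupRecord",
    "extract_roi",
    "build_matchups",
    "spectral_stability_test",
    "cross_correlate",
    "CorrelationMatrix",
]

DEFAULT_TARGET_PIXELS = (100, 150)


@dataclass
class MatchupRecord:
    """One paired (ROI-mean spectrum, field sample) calibration record."""

    point_id: str
    image_date: _dt.date
    sample_date: _dt.date
    lag_days: int
    spectrum: np.ndarray
    spectrum_sd: np.ndarray
    n_pixels: int
    sample: FieldSample

    def __post_init__(self) -> None:
        expected = abs((self.image_date - self.sample_date).days)
        if self.lag_days != expected:
            raise ValueError(
                f"lag_days {self.lag_days} != |image_date - sample_date| = {expected}"
            )


def extract_roi(
    scene: Scene,
    point: tuple[float, float],
    water_mask: np.ndarray,
    target_pixels: tuple[int, int] = DEFAULT_TARGET_PIXELS,
    min_side: int = 12,
    max_side: int = 40,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-band mean/sd over the water pixels of a grown square window.

    The window is centred on the point's pixel and grown from
    ``min_side`` in steps of 2 until its water-pixel count enters
    ``target_pixels``. Returns (mean spectrum, sd spectrum, n_pixels).
    """
    if scene.state != SceneState.SURFACE_REFLECTANCE:
        raise ValueError("extract_roi requires a surface-reflectance scene")
    rows, cols = scene.shape
    r, c = scene.point_to_rowcol(*point)
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"point {point} falls outside the raster extent")
    lo, hi = target_pixels
    for side in range(min_side, max_side + 1, 2):
        half = side // 2
        r0, r1 = max(r - half, 0), min(r - half + side, rows)
        c0, c1 = max(c - half, 0), min(c - half + side, cols)
        window_mask = water_mask[r0:r1, c0:c1]
        n = int(window_mask.sum())
        if lo <= n <= hi:
            block = scene.data[r0:r1, c0:c1][window_mask]
            return block.mean(axis=0), block.std(axis=0), n
    raise ValueError(
        f"no window up to {max_side}x{max_side} around {point} holds "
        f"{lo}-{hi} water pixels"
    )


def build_matchups(
    scenes: dict[_dt.date, Scene],
    samples: list[FieldSample],
    points: dict[str, tuple[float, float]],
    water_masks: dict[_dt.date, np.ndarray],
    max_lag_days: int = 3,
    target_pixels: tuple[int, int] = DEFAULT_TARGET_PIXELS,
    **roi_kwargs,
) -> tuple[list[MatchupRecord], list[dict]]:
    """Pair each sample with the nearest-in-time scene within the lag window.

    Equidistant earlier/later scenes break toward the earlier one.
    Returns (records, unpaired) where ``unpaired`` lists each excluded
    sample with the reason.
    """
    if not scenes:
        raise ValueError("scene collection is empty")
    if max_lag_days < 0:
        raise ValueError("max_lag_days must be >= 0")
    dates = sorted(scenes)
    records: list[MatchupRecord] = []
    unpaired: list[dict] = []
    for sample in samples:
        lags = [abs((d - sample.campaign_date).days) for d in dates]
        best = min(range(len(dates)), key=lambda i: (lags[i], dates[i]))
        if lags[best] > max_lag_days:
            unpaired.append(
                {
                    "point_id": sample.point_id,
                    "sample_date": sample.campaign_date,
                    "reason": f"nearest scene lag {lags[best]} d > {max_lag_days} d",
                }
            )
            continue
        date = dates[best]
        if sample.point_id not in points:
            unpaired.append(
                {
                    "point_id": sample.point_id,
                    "sample_date": sample.campaign_date,
                    "reason": "no geolocation for point",
                }
            )
            continue
        try:
            mean, sd, n = extract_roi(
                scenes[date],
                points[sample.point_id],
                water_masks[date],
                target_pixels=target_pixels,
                **roi_kwargs,
            )
        except ValueError as exc:
            unpaired.append(
                {
                    "point_id": sample.point_id,
                    "sample_date": sample.campaign_date,
                    "reason": str(exc),
                }
            )
            continue
        records.append(
            MatchupRecord(
                point_id=sample.point_id,
                image_date=date,
                sample_date=sample.campaign_date,
                lag_days=lags[best],
                spectrum=mean,
                spectrum_sd=sd,
                n_pixels=n,
                sample=sample,
            )
        )
    return records, unpaired


def matchups_to_frame(records: list[MatchupRecord]) -> pd.DataFrame:
    """Flatten matchup records to one row each (spectra as B1..B4 columns)."""
    rows = []
    for rec in records:
        row = {
            "point_id": rec.point_id,
            "image_date": rec.image_date.isoformat(),
            "sample_date": rec.sample_date.isoformat(),
            "lag_days": rec.lag_days,
            "n_pixels": rec.n_pixels,
        }
        for i, b in enumerate(["B1", "B2", "B3", "B4"]):
            row[b] = rec.spectrum[i]
            row[f"{b}_sd"] = rec.spectrum_sd[i]
        for v in VARIABLES:
            row[v] = getattr(rec.sample, v)
        rows.append(row)
    return pd.DataFrame(rows)


def spectral_stability_test(
    spectra_a,
    spectra_b,
    alpha: float = 0.05,
    paired: bool = True,
) -> dict:
    """Student's t-test for water-spectrum stability between two dates.

    ``paired=True`` (default) runs a paired two-sided t-test on
    per-band reflectance; ``paired=False`` pools both spectra and runs
    a two-sample test. The spectra are declared *stable* when
    p >= alpha. Identical sets give t = 0, p = 1 (stable); a constant
    nonzero difference with zero spread is reported unstable with
    p = 0 by convention.
    """
    a = np.asarray(spectra_a, dtype=float).ravel()
    b = np.asarray(spectra_b, dtype=float).ravel()
    if paired and a.shape != b.shape:
        raise ValueError("paired test requires equal-length spectra")
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 values per set")
    if paired:
        diff = a - b
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(diff[0]), 0.0
        else:
            t, p = sstats.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            equal = a[0] == b[0]
            t, p = (0.0, 1.0) if equal else (np.inf * np.sign(a[0] - b[0]), 0.0)
        else:
            t, p = sstats.ttest_ind(a, b)
    return {
        "statistic": float(t),
        "p_value": float(p),
        "stable": bool(p >= alpha),
        "alpha": alpha,
    }


@dataclass
class CorrelationMatrix:
    """Pairwise correlations with per-pair method, n, and p-value."""

    coefficients: pd.DataFrame
    n: pd.DataFrame
    method: pd.DataFrame
    p_values: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.coefficients.to_numpy(dtype=float)
        if not np.allclose(c, c.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")


def cross_correlate(
    samples: list[FieldSample] | pd.DataFrame,
    alpha_normality: float = 0.05,
    variables: list[str] | None = None,
) -> CorrelationMatrix:
    """Normality-gated pairwise correlation of the field variables.

    Per variable pair, a Shapiro-Wilk test runs on each pairwise-
    complete margin; Pearson applies when both pass at
    ``alpha_normality``, Spearman otherwise. Constant margins yield an
    undefined (NaN) coefficient.
    """
    variables = variables or VARIABLES
    if isinstance(samples, pd.DataFrame):
        data = samples[variables].astype(float)
    else:
        data = pd.DataFrame(
            {v: [getattr(s, v) for s in samples] for v in variables}, dtype=float
        )
    k = len(variables)
    coef = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    nmat = pd.DataFrame(0, index=variables, columns=variables)
    method = pd.DataFrame("", index=variables, columns=variables)
    pmat = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i in range(k):
        nmat.iloc[i, i] = int(data[variables[i]].notna().sum())
        for j in range(i + 1, k):
            sub = data[[variables[i], variables[j]]].dropna()
            n = len(sub)
            nmat.iloc[i, j] = nmat.iloc[j, i] = n
            if n < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for {variables[i]}/{variables[j]}, got {n}"
                )
            x = sub[variables[i]].to_numpy()
            y = sub[variables[j]].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                coef.iloc[i, j] = coef.iloc[j, i] = np.nan
                method.iloc[i, j] = method.iloc[j, i] = "undefined"
                pmat.iloc[i, j] = pmat.iloc[j, i] = np.nan
                continue
            normal = (
                sstats.shapiro(x).pvalue >= alpha_normality
                and sstats.shapiro(y).pvalue >= alpha_normality
            )
            if normal:
                res = sstats.pearsonr(x, y)
                used = "pearson"
            else:
                res = sstats.spearmanr(x, y)
                used = "spearman"
            coef.iloc[i, j] = coef.iloc[j, i] = res.statistic
            pmat.iloc[i, j] = pmat.iloc[j, i] = res.pvalue
            method.iloc[i, j] = method.iloc[j, i] = used
    return CorrelationMatrix(coef, nmat, method, pmat)
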