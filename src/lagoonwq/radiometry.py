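"""Radiometric calibration and Lambertian atmospheric-correction inversion.

The sensor delivers raw digital numbers (DN). Per band, an affine
calibration converts DN to top-of-atmosphere (TOA) radiance; under the
``divide`` convention

    L_TOA = DN / gain + bias

and under ``multiply``

    L_TOA = DN * gain + bias.

The TOA radiance over a Lambertian surface of reflectance rho is

    L_TOA = L0 + (I0 * Tg * Tud / pi) * rho / (1 - S * rho)

with path radiance L0, composite solar irradiance term I0 (already
scaled by Earth-Sun distance and solar zenith cosine), gas
transmittance Tg, total two-way scattering transmittance Tud, and
spherical albedo S. Surface reflectance is retrieved by solving for
rho:

    y = pi * (L - L0) / (I0 * Tg * Tud);   rho = y / (1 + S * y)

which is the exact algebraic inverse. The atmospheric terms themselves
(from a radiative-transfer code driven by reanalysis atmospheres) are
inputs, not computed here.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .bands import PERUSAT1, BandSet

__all__ = [
    "SceneState",
    "Scene",
    "RadiometricCalibration",
    "AtmosphericTerms",
    "dn_to_radiance",
    "radiance_to_dn",
    "toa_radiance_forward",
    "invert_surface_reflectance",
    "convolve_to_bands",
    "validate_correction",
]

#: Lower clip bound for retrieved surface reflectance. Slightly negative
#: values are a normal outcome of over-correction over dark water; values
#: below this bound are clipped and counted.
REFLECTANCE_FLOOR = -0.05


class SceneState(str, Enum):
    DN = "DN"
    TOA_RADIANCE = "TOA_radiance"
    SURFACE_REFLECTANCE = "surface_reflectance"


_STATE_ORDER = [SceneState.DN, SceneState.TOA_RADIANCE, SceneState.SURFACE_REFLECTANCE]


@dataclass
class Scene:
    """A rows x cols x n_bands raster plus its processing state and metadata.

    ``transform`` is ``(x0, dx, y0, dy)`` mapping pixel (row, col) centres
    to map coordinates ``x = x0 + (col + 0.5) * dx``,
    ``y = y0 + (row + 0.5) * dy``.
    """

    data: np.ndarray
    state: SceneState = SceneState.DN
    band_set: BandSet = PERUSAT1
    transform: tuple[float, float, float, float] = (0.0, 1.0, 0.0, -1.0)
    crs: str = "local"
    nodata: float = np.nan
    date: _dt.date | None = None
    #: pixel counts clipped/flagged during the last state transition
    clip_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.band_set):
            raise ValueError(
                f"scene data must be rows x cols x {len(self.band_set)}, "
                f"got shape {self.data.shape}"
            )
        self.state = SceneState(self.state)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def band(self, label: str) -> np.ndarray:
        """2-D view of one band by label."""
        return self.data[:, :, self.band_set.index(label)]

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        x0, dx, y0, dy = self.transform
        col = int(np.floor((x - x0) / dx))
        row = int(np.floor((y - y0) / dy))
        return row, col


def _require_state(scene: Scene, state: SceneState, op: str) -> None:
    if scene.state != state:
        raise ValueError(
            f"{op} requires a scene in state {state.value!r}, "
            f"got {scene.state.value!r}"
        )


def _per_band(values, n_bands: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_bands, float(arr))
    if arr.shape != (n_bands,):
        raise ValueError(f"{name} must have one value per band ({n_bands})")
    return arr


@dataclass
class RadiometricCalibration:
    """Per-band affine DN-to-radiance calibration."""

    gain: np.ndarray
    bias: np.ndarray
    convention: str = "divide"  # 'divide': L = DN/gain + bias; 'multiply': L = DN*gain + bias
    n_bands: int = 4

    def __post_init__(self) -> None:
        self.gain = _per_band(self.gain, self.n_bands, "gain")
        self.bias = _per_band(self.bias, self.n_bands, "bias")
        if self.convention not in ("divide", "multiply"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if np.any(self.gain <= 0):
            raise ValueError("gain must be > 0 for every band")

    @classmethod
    def from_mapping(cls, mapping: dict, band_labels: list[str]) -> "RadiometricCalibration":
        """Build from a per-band mapping ``{label: {gain, bias}}``."""
        gain = [mapping[b]["gain"] for b in band_labels]
        bias = [mapping[b]["bias"] for b in band_labels]
        convention = mapping.get("convention", "divide")
        return cls(gain, bias, convention=convention, n_bands=len(band_labels))

    @classmethod
    def from_yaml(cls, path: str | Path, band_labels: list[str] | None = None) -> "RadiometricCalibration":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        labels = band_labels or [k for k in mapping if k != "convention"]
        return cls.from_mapping(mapping, labels)


@dataclass
class AtmosphericTerms:
    """Per-band terms of the Lambertian TOA radiance model."""

    path_radiance: np.ndarray        # L0, same units as TOA radiance
    solar_irradiance: np.ndarray     # I0, composite band effective irradiance
    gas_transmittance: np.ndarray    # Tg in (0, 1]
    total_transmittance: np.ndarray  # Tud, two-way scattering transmittance in (0, 1]
    spherical_albedo: np.ndarray     # S in [0, 1)
    n_bands: int = 4

    def __post_init__(self) -> None:
        n = self.n_bands
        self.path_radiance = _per_band(self.path_radiance, n, "path_radiance")
        self.solar_irradiance = _per_band(self.solar_irradiance, n, "solar_irradiance")
        self.gas_transmittance = _per_band(self.gas_transmittance, n, "gas_transmittance")
        self.total_transmittance = _per_band(self.total_transmittance, n, "total_transmittance")
        self.spherical_albedo = _per_band(self.spherical_albedo, n, "spherical_albedo")
        if np.any(self.path_radiance < 0):
            raise ValueError("path_radiance must be >= 0")
        if np.any(self.solar_irradiance <= 0):
            raise ValueError("solar_irradiance must be > 0")
        for name in ("gas_transmittance", "total_transmittance"):
            v = getattr(self, name)
            if np.any((v <= 0) | (v > 1)):
                raise ValueError(f"{name} must be in (0, 1]")
        s = self.spherical_albedo
        if np.any((s < 0) | (s >= 1)):
            raise ValueError("spherical_albedo must be in [0, 1)")

    @property
    def direct_term(self) -> np.ndarray:
        """I0 * Tg * Tud / pi, the reflectance-to-radiance scaling."""
        return (
            self.solar_irradiance
            * self.gas_transmittance
            * self.total_transmittance
            / np.pi
        )

    @classmethod
    def from_mapping(cls, mapping: dict, band_labels: list[str]) -> "AtmosphericTerms":
        keys = [
            "path_radiance",
            "solar_irradiance",
            "gas_transmittance",
            "total_transmittance",
            "spherical_albedo",
        ]
        arrays = {k: [mapping[b][k] for b in band_labels] for k in keys}
        return cls(n_bands=len(band_labels), **arrays)

    @classmethod
    def from_yaml(cls, path: str | Path, band_labels: list[str] | None = None) -> "AtmosphericTerms":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        labels = band_labels or list(mapping)
        return cls.from_mapping(mapping, labels)


def dn_to_radiance(scene: Scene, calibration: RadiometricCalibration) -> Scene:
    """Convert a DN scene to TOA radiance via the per-band affine calibration."""
    _require_state(scene, SceneState.DN, "dn_to_radiance")
    dn = scene.data.astype(float)
    if calibration.convention == "divide":
        radiance = dn / calibration.gain + calibration.bias
    else:
        radiance = dn * calibration.gain + calibration.bias
    nodata_mask = ~np.isfinite(dn)
    radiance[nodata_mask] = np.nan
    return replace(scene, data=radiance, state=SceneState.TOA_RADIANCE, clip_counts={})


def radiance_to_dn(
    scene: Scene,
    calibration: RadiometricCalibration,
    bit_depth: int = 12,
    quantize: bool = True,
) -> Scene:
    """Inverse of :func:`dn_to_radiance`, with optional integer quantization."""
    _require_state(scene, SceneState.TOA_RADIANCE, "radiance_to_dn")
    L = scene.data
    if calibration.convention == "divide":
        dn = (L - calibration.bias) * calibration.gain
    else:
        dn = (L - calibration.bias) / calibration.gain
    if quantize:
        dn = np.clip(np.rint(dn), 0, 2**bit_depth - 1)
    return replace(scene, data=dn, state=SceneState.DN, clip_counts={})


def toa_radiance_forward(
    reflectance, terms: AtmosphericTerms
) -> np.ndarray:
    """TOA radiance from surface reflectance under the Lambertian model.

    ``reflectance`` broadcasts against the per-band terms; pass shape
    ``(..., n_bands)`` for multiband input or a scalar with scalar-valued
    terms.
    """
    rho = np.asarray(reflectance, dtype=float)
    s = terms.spherical_albedo
    with np.errstate(invalid="ignore"):
        singular = (s > 0) & (rho * s >= 1)
    if np.any(singular & np.isfinite(rho)):
        raise ValueError(
            "reflectance at or beyond the 1/S singularity of the Lambertian model"
        )
    return terms.path_radiance + terms.direct_term * rho / (1.0 - s * rho)


def invert_surface_reflectance(scene: Scene, terms: AtmosphericTerms) -> Scene:
    """Solve the Lambertian TOA model for surface reflectance, per band.

    Negative retrievals down to the floor are retained (flagged via
    ``clip_counts['negative']``); values outside [floor, 1] are clipped
    and counted.
    """
    _require_state(scene, SceneState.TOA_RADIANCE, "invert_surface_reflectance")
    L = scene.data
    y = np.pi * (L - terms.path_radiance) / (
        terms.solar_irradiance * terms.gas_transmittance * terms.total_transmittance
    )
    rho = y / (1.0 + terms.spherical_albedo * y)
    finite = np.isfinite(rho)
    counts = {
        "negative": int(np.sum((rho < 0) & finite)),
        "clipped_low": int(np.sum((rho < REFLECTANCE_FLOOR) & finite)),
        "clipped_high": int(np.sum((rho > 1) & finite)),
    }
    rho = np.clip(rho, REFLECTANCE_FLOOR, 1.0)
    return replace(
        scene, data=rho, state=SceneState.SURFACE_REFLECTANCE, clip_counts=counts
    )


def invert_reflectance_values(radiance, terms: AtmosphericTerms) -> np.ndarray:
    """Pointwise inverse of :func:`toa_radiance_forward` (no clipping)."""
    L = np.asarray(radiance, dtype=float)
    y = np.pi * (L - terms.path_radiance) / (
        terms.solar_irradiance * terms.gas_transmittance * terms.total_transmittance
    )
    return y / (1.0 + terms.spherical_albedo * y)


def convolve_to_bands(
    wavelength_nm,
    rrs,
    band_set: BandSet = PERUSAT1,
) -> np.ndarray:
    """Band-average a hyperspectral reflectance curve.

    The spectrum is treated as piecewise linear between samples and
    averaged over each band's wavelength range under a rectangular
    spectral response (the mean of the curve over the band interval).

    Raises if the spectrum does not cover a band's full range, naming
    the band.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    r = np.asarray(rrs, dtype=float)
    if wl.shape != r.shape or wl.ndim != 1:
        raise ValueError("wavelength and Rrs must be 1-D arrays of equal length")
    order = np.argsort(wl)
    wl, r = wl[order], r[order]
    out = np.empty(len(band_set))
    for i, band in enumerate(band_set):
        lo, hi = band.wavelength_min, band.wavelength_max
        if wl[0] > lo or wl[-1] < hi:
            raise ValueError(
                f"spectrum does not cover band {band.label} ({lo}-{hi} nm)"
            )
        inside = wl[(wl > lo) & (wl < hi)]
        grid = np.concatenate(([lo], inside, [hi]))
        vals = np.interp(grid, wl, r)
        out[i] = np.trapezoid(vals, grid) / (hi - lo)
    return out


def validate_correction(
    image_spectra,
    insitu_spectra,
    per_band: bool = False,
):
    """Scatter statistics comparing image reflectance with in-situ Rrs.

    Both inputs are (n_points, n_bands). Returns a dict with the pooled
    RMSE, least-squares line (slope, intercept) of image vs in-situ, and
    n; with ``per_band=True`` adds a per-band RMSE array.
    """
    img = np.asarray(image_spectra, dtype=float)
    ref = np.asarray(insitu_spectra, dtype=float)
    if img.shape != ref.shape:
        raise ValueError(
            f"paired spectra shapes differ: {img.shape} vs {ref.shape}"
        )
    if img.ndim == 1:
        img = img[:, None]
        ref = ref[:, None]
    if img.shape[0] * img.shape[1] < 2:
        raise ValueError("need at least 2 paired values")
    diff = (img - ref).ravel()
    rmse = float(np.sqrt(np.mean(diff**2)))
    slope, intercept = np.polyfit(ref.ravel(), img.ravel(), 1)
    out = {
        "rmse": rmse,
        "slope": float(slope),
        "intercept": float(intercept),
        "n": int(img.shape[0]),
    }
    if per_band:
        out["rmse_per_band"] = np.sqrt(np.mean((img - ref) ** 2, axis=0))
    return out
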