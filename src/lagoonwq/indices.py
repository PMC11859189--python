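"""Two-band spectral indices: simple ratio (SR) and normalized difference (ND).

SR(a, b) = Ra / Rb and ND(a, b) = (Ra - Rb) / (Ra + Rb). SR pairs are
ordered (Ra/Rb and Rb/Ra are distinct regressors); ND pairs are
enumerated once per unordered pair, stored in a canonical orientation
with the longer-wavelength band first — reversing an ND only flips its
sign, which any fit with a free slope absorbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .bands import PERUSAT1, BandSet

__all__ = ["IndexSpec", "enumerate_indices", "compute_index"]


@dataclass(frozen=True)
class IndexSpec:
    """One two-band index: ``kind`` is 'SR' or 'ND', bands by label."""

    kind: str
    band_a: str
    band_b: str

    def __post_init__(self) -> None:
        if self.kind not in ("SR", "ND"):
            raise ValueError(f"unknown index kind {self.kind!r}")
        if self.band_a == self.band_b:
            raise ValueError("index bands must differ")

    @property
    def name(self) -> str:
        if self.kind == "SR":
            return f"{self.band_a}/{self.band_b}"
        return f"ND({self.band_a},{self.band_b})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def enumerate_indices(band_set: BandSet = PERUSAT1) -> list[IndexSpec]:
    """All ordered SR pairs plus unordered canonical ND pairs.

    For n bands: n(n-1) SR + C(n, 2) ND specs (18 for 4 bands).
    """
    labels = band_set.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 bands")
    specs = [IndexSpec("SR", a, b) for a, b in permutations(labels, 2)]
    # canonical ND orientation: longer-wavelength band first, as published
    specs += [IndexSpec("ND", b, a) for a, b in combinations(labels, 2)]
    return specs


def compute_index(
    spectrum,
    spec: IndexSpec,
    band_labels: list[str] | None = None,
) -> np.ndarray | float:
    """Evaluate an index on reflectance spectra.

    ``spectrum`` has band values along its last axis, ordered as
    ``band_labels`` (default the 4-band standard order). Zero
    denominators yield NaN with a warning rather than raising, so that
    a single bad pixel does not abort a full-raster evaluation.
    """
    labels = band_labels or PERUSAT1.labels
    arr = np.asarray(spectrum, dtype=float)
    if arr.shape[-1] != len(labels):
        raise ValueError(
            f"spectrum last axis ({arr.shape[-1]}) != number of bands ({len(labels)})"
        )
    ra = arr[..., labels.index(spec.band_a)]
    rb = arr[..., labels.index(spec.band_b)]
    if spec.kind == "SR":
        denom = rb
        num = ra
    else:
        denom = ra + rb
        num = ra - rb
    zero = denom == 0
    if np.any(zero):
        warnings.warn(
            f"{spec.name}: {int(np.sum(zero))} zero-denominator value(s) set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, num / np.where(zero, 1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out
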