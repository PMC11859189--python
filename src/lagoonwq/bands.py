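"""Multispectral band definitions.

The default band set models a 4-band very-high-resolution pushbroom
imager (NAOMI class): blue, green, red and near-infrared bands at 2.8 m
ground sampling. Band wavelength ranges are used for convolving
hyperspectral in-situ reflectance to the sensor bands under a
rectangular spectral response.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Band:
    """A single spectral band.

    Parameters
    ----------
    label : str
        Band label, e.g. ``"B1"``.
    wavelength_min, wavelength_max : float
        Band edges in nanometres.
    resolution_m : float
        Ground sampling distance in metres.
    """

    label: str
    wavelength_min: float
    wavelength_max: float
    resolution_m: float = 2.8

    def __post_init__(self) -> None:
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError(
                f"band {self.label}: wavelength_min must be < wavelength_max"
            )

    @property
    def center(self) -> float:
        """Band-range midpoint in nanometres."""
        return 0.5 * (self.wavelength_min + self.wavelength_max)


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of non-overlapping, ascending bands."""

    bands: tuple[Band, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate band labels: {labels}")
        for lo, hi in zip(self.bands, self.bands[1:]):
            if hi.wavelength_min < lo.wavelength_max:
                raise ValueError(
                    f"bands {lo.label} and {hi.label} overlap or are out of order"
                )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, label: str) -> Band:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def index(self, label: str) -> int:
        """Position of the band with the given label."""
        return self.labels.index(label)


#: Default 4-band set: blue, green, red, NIR at 2.8 m.
PERUSAT1 = BandSet(
    (
        Band("B1", 450.0, 520.0),
        Band("B2", 530.0, 590.0),
        Band("B3", 630.0, 700.0),
        Band("B4", 752.0, 885.0),
    )
)
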