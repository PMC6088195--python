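"""Frequency band definitions.

The default registry holds the eight canonical electrophysiological rhythms
(delta through high gamma) commonly used for band-limited source-space
connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band ``[f_low, f_high]`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    @property
    def center(self) -> float:
        """Arithmetic band center (f_low + f_high) / 2 in Hz."""
        return 0.5 * (self.f_low + self.f_high)

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 13.0),
    BandSpec("beta1", 13.0, 20.0),
    BandSpec("beta2", 20.0, 30.0),
    BandSpec("gamma1", 30.0, 45.0),
    BandSpec("gamma2", 55.0, 90.0),
)

_REGISTRY = {b.name: b for b in DEFAULT_BANDS}


def get_band(name: str) -> BandSpec:
    """Look up a band from the default registry by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
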