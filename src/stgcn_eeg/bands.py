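"""Clinical EEG frequency bands.

Band edges follow standard clinical convention; the full band spans
0.5-48 Hz so that every band fits under the 50 Hz Nyquist limit of the
100 Hz working rate.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band edges: low={self.low_hz}, high={self.high_hz}"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    def contains(self, freq_hz: float) -> bool:
        return self.low_hz <= freq_hz <= self.high_hz


DELTA = BandSpec("Delta", 0.5, 4.0)
THETA = BandSpec("Theta", 4.0, 8.0)
ALPHA = BandSpec("Alpha", 8.0, 13.0)
BETA = BandSpec("Beta", 13.0, 30.0)
GAMMA = BandSpec("Gamma", 30.0, 48.0)
FULL = BandSpec("Full", 0.5, 48.0)

STANDARD_BANDS: dict[str, BandSpec] = {
    b.name: b for b in (DELTA, THETA, ALPHA, BETA, GAMMA, FULL)
}


def get_band(name: str) -> BandSpec:
    """Look up a standard band by (case-insensitive) name."""
    key = name.capitalize()
    if key not in STANDARD_BANDS:
        raise KeyError(f"unknown band {name!r}; known: {sorted(STANDARD_BANDS)}")
    return STANDARD_BANDS[key]
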