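"""Canonical frequency-band definitions for iEEG band-power analysis.

Five bands are used throughout: delta, theta, alpha, beta, and gamma.
The gamma band is a union of three sub-intervals chosen to exclude the
50 Hz power-line frequency and its surroundings (47.5-52.5 Hz and
57.5-62.5 Hz notches around 50 and 60 Hz harmonics-adjacent ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BandDefinition", "DEFAULT_BANDS", "BAND_NAMES"]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency bands, each a list of (low, high) Hz sub-intervals.

    Attributes
    ----------
    bands
        Mapping band name -> tuple of (low, high) sub-intervals in Hz.
        Sub-intervals within a band must be non-overlapping.
    """

    bands: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "delta": ((1.0, 4.0),),
            "theta": ((4.0, 8.0),),
            "alpha": ((8.0, 13.0),),
            "beta": ((13.0, 30.0),),
            "gamma": ((30.0, 47.5), (52.5, 57.5), (62.5, 77.5)),
        }
    )

    def __post_init__(self) -> None:
        for name, intervals in self.bands.items():
            for lo, hi in intervals:
                if not lo < hi:
                    raise ValueError(f"band {name}: empty interval ({lo}, {hi})")
            ordered = sorted(intervals)
            for (_, hi_a), (lo_b, _) in zip(ordered, ordered[1:]):
                if lo_b < hi_a:
                    raise ValueError(f"band {name}: overlapping sub-intervals")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def bandwidth(self, name: str) -> float:
        """Total width in Hz of a band's sub-intervals."""
        return sum(hi - lo for lo, hi in self.bands[name])

    @property
    def max_edge(self) -> float:
        return max(hi for ivs in self.bands.values() for _, hi in ivs)


DEFAULT_BANDS = BandDefinition()
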