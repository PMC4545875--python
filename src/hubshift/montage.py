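"""The 21-channel 10-20 electrode layout used throughout the package.

Coordinates are a schematic 2-D projection of the 10-20 placement scheme:
the head is the unit disc, Cz sits at the origin, y > 0 points to the
front (nasion) and x > 0 to the right ear.  Channels live on two
concentric rings (outer ring radius 0.90, inner ring radius 0.45); the
table below is a fixed, versioned constant so the layout is bit-stable
across runs.  All hub-location statistics are computed in these "head
units" (head radius = 1).

The analysis clusters channels into three named regions:

* anterior:  Fp1, Fp2, F7, F3, Fz, F4, F8
* central:   T3, C3, Cz, C4, T4
* posterior: T5, P3, Pz, P4, T6, O1, O2

Two additional midline electrodes (Fpz, Oz) complete the 21-channel
recording montage but belong to no cluster; by default the analytic set
is the 19 clustered channels, with a switch to include the two extras.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "standard_montage",
    "REGION_NAMES",
    "CLUSTERS",
    "UNCLUSTERED",
]

REGION_NAMES = ("anterior", "central", "posterior")

CLUSTERS: dict[str, tuple[str, ...]] = {
    "anterior": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("T3", "C3", "Cz", "C4", "T4"),
    "posterior": ("T5", "P3", "Pz", "P4", "T6", "O1", "O2"),
}

#: The two 10-20 positions recorded beyond the 19 clustered ones.  Their
#: identity is not dictated by the clustering scheme; midline Fpz/Oz are
#: the package's documented choice and are configurable only by building
#: a custom Montage.
UNCLUSTERED: tuple[str, ...] = ("Fpz", "Oz")

# Versioned schematic coordinate table (x, y), head radius = 1.
# Left/right homologues carry exactly mirrored x so the layout is
# mirror-symmetric to the last bit, and the front/back rows mirror in y
# so the 19-channel centroid is exactly (0, 0).
_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.2781, 0.8560),
    "Fp2": (0.2781, 0.8560),
    "F7": (-0.7281, 0.5290),
    "F8": (0.7281, 0.5290),
    "F3": (-0.3182, 0.3182),
    "F4": (0.3182, 0.3182),
    "Fz": (0.0, 0.45),
    "T3": (-0.9, 0.0),
    "T4": (0.9, 0.0),
    "C3": (-0.45, 0.0),
    "C4": (0.45, 0.0),
    "Cz": (0.0, 0.0),
    "T5": (-0.7281, -0.5290),
    "T6": (0.7281, -0.5290),
    "P3": (-0.3182, -0.3182),
    "P4": (0.3182, -0.3182),
    "Pz": (0.0, -0.45),
    "O1": (-0.2781, -0.8560),
    "O2": (0.2781, -0.8560),
    "Fpz": (0.0, 0.9),
    "Oz": (0.0, -0.9),
}

_CHANNEL_ORDER_19: tuple[str, ...] = (
    CLUSTERS["anterior"] + CLUSTERS["central"] + CLUSTERS["posterior"]
)
_CHANNEL_ORDER_21: tuple[str, ...] = _CHANNEL_ORDER_19 + UNCLUSTERED


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with 2-D coordinates and region labels.

    Parameters
    ----------
    channels
        Ordered channel labels; this order fixes the row order of every
        data tensor and connectivity matrix downstream.
    coords
        Map channel -> (x, y) in head units.
    regions
        Map channel -> region name, or ``None`` for recorded-but-
        unclustered channels.
    """

    channels: tuple[str, ...]
    coords: dict[str, tuple[float, float]]
    regions: dict[str, str | None]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels in montage")
        missing = [c for c in self.channels if c not in self.coords]
        if missing:
            raise ValueError(f"channels without coordinates: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def coord_array(self) -> np.ndarray:
        """(n_channels, 2) array of coordinates in channel order."""
        return np.array([self.coords[c] for c in self.channels], dtype=float)

    def region_of(self, channel: str) -> str | None:
        if channel not in self.regions:
            raise KeyError(f"unknown channel {channel!r}")
        return self.regions[channel]

    def region_channels(self, region: str) -> list[str]:
        """Channels of one named cluster; ``"global"`` returns all."""
        if region == "global":
            return list(self.channels)
        if region not in REGION_NAMES:
            raise KeyError(
                f"unknown region {region!r}; expected one of "
                f"{REGION_NAMES + ('global',)}"
            )
        return [c for c in self.channels if self.regions.get(c) == region]

    def region_indices(self, region: str) -> np.ndarray:
        return np.array(
            [self.channels.index(c) for c in self.region_channels(region)],
            dtype=int,
        )

    # -- plain-text round trip ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        xy = self.coord_array()
        return pd.DataFrame(
            {
                "channel": list(self.channels),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "region": [self.regions.get(c) or "" for c in self.channels],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Montage":
        channels = tuple(frame["channel"])
        coords = {
            r.channel: (float(r.x), float(r.y)) for r in frame.itertuples()
        }
        regions = {
            r.channel: (r.region if r.region else None)
            for r in frame.itertuples()
        }
        return cls(channels=channels, coords=coords, regions=regions)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def standard_montage(include_unclustered: bool = False) -> Montage:
    """The standard 10-20 layout.

    Parameters
    ----------
    include_unclustered
        If False (default) return the 19-channel analytic set (the three
        named clusters).  If True, append the two unclustered midline
        channels (Fpz, Oz) for the full 21-channel recording montage.
    """
    order = _CHANNEL_ORDER_21 if include_unclustered else _CHANNEL_ORDER_19
    regions: dict[str, str | None] = {}
    for name, chans in CLUSTERS.items():
        for c in chans:
            regions[c] = name
    for c in UNCLUSTERED:
        regions[c] = None
    return Montage(
        channels=order,
        coords={c: _COORDS[c] for c in order},
        regions={c: regions[c] for c in order},
    )
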