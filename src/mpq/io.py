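"""Multi-channel image container and TIFF round-trip.

Coordinate convention shared by every module: 0-based pixel indices,
origin top-left, ``x`` = column, ``y`` = row, and microns = pixels ×
``pixel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class MultiChannelImage:
    """A 2-D pixel grid per named fluorescence channel.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"SMAD23"``) to a
        2-D float array. All channels must share one shape.
    pixel_size
        Physical size of one pixel in µm/px.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def save_tiff(self, path) -> None:
        """Write one TIFF page per channel; names go in the description tag."""
        # float64 pages so that a save/load round trip is bit-exact
        stack = np.stack([self.channels[n].astype(np.float64) for n in self.channels])
        desc = json.dumps(
            {"channels": self.channel_names, "pixel_size_um": self.pixel_size,
             **({"meta": self.meta} if self.meta else {})},
            sort_keys=True,
        )
        tifffile.imwrite(path, stack, description=desc, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path) -> "MultiChannelImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        info = json.loads(desc)
        names = info["channels"]
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(names):
            raise ValueError(
                f"TIFF has {stack.shape[0]} pages but {len(names)} channel names"
            )
        channels = {n: stack[i].astype(np.float64) for i, n in enumerate(names)}
        return cls(channels, float(info["pixel_size_um"]), info.get("meta", {}))
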