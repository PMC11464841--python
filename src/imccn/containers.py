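"""Shared data containers: multiplexed images, spillover matrices, label masks.

Coordinate convention (used everywhere in this package): pixel-centered,
origin at the top-left pixel, x increases rightwards (array columns), y
increases downwards (array rows), 0-based. Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelMismatchError, ValidationError


@dataclass
class MultiplexImage:
    """A stack of per-marker intensity planes.

    Parameters
    ----------
    data
        Array of shape ``(C, H, W)``; one nonnegative intensity plane per
        channel, in arbitrary ion-count units.
    channels
        Channel names, one per plane, unique, in plane order.
    pixel_size_um
        Physical pixel edge length in micrometres, if known.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise ValidationError("image data must have shape (channels, height, width)")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")
        if self.data.size and self.data.min() < 0:
            raise ValidationError("intensities must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.data.shape[1:]

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise ChannelMismatchError(
                f"channel {channel!r} not in image channels {self.channels}"
            ) from None

    def plane(self, channel: str) -> np.ndarray:
        return self.data[self.index(channel)]

    def copy(self) -> "MultiplexImage":
        return MultiplexImage(self.data.copy(), list(self.channels), self.pixel_size_um)

    def to_tiff(self, path: str | Path) -> None:
        """Write as a multi-page float32 TIFF, one page per channel."""
        tifffile.imwrite(str(path), self.data.astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | Path, channels: list[str],
                  pixel_size_um: float | None = None) -> "MultiplexImage":
        data = np.asarray(tifffile.imread(str(path)), dtype=float)
        if data.ndim == 2:
            data = data[None]
        return cls(data, channels, pixel_size_um)


@dataclass
class SpilloverMatrix:
    """Square channel-mixing matrix.

    ``matrix[i, j]`` is the fraction of channel ``i``'s true signal that is
    observed in channel ``j`` (true-signal-in-rows convention): the observed
    pixel vector is ``o = t @ S``.
    """

    matrix: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.channels = list(self.channels)
        C = len(self.channels)
        if self.matrix.shape != (C, C):
            raise ValidationError(
                f"spillover matrix shape {self.matrix.shape} does not match "
                f"{C} channel names"
            )
        if self.matrix.size and self.matrix.min() < 0:
            raise ValidationError("spillover fractions must be nonnegative")
        if np.any(np.diag(self.matrix) <= 0):
            raise ValidationError("spillover diagonal entries must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), list(channels))

    def reordered(self, channels: list[str]) -> "SpilloverMatrix":
        """Return a copy with rows/columns permuted into ``channels`` order."""
        if set(channels) != set(self.channels):
            raise ChannelMismatchError(
                f"cannot map spillover channels {self.channels} onto {list(channels)}"
            )
        idx = [self.channels.index(c) for c in channels]
        return SpilloverMatrix(self.matrix[np.ix_(idx, idx)], list(channels))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("spillover CSV must have matching row/column names")
        return cls(df.to_numpy(dtype=float), list(df.columns))


@dataclass
class LabelMask:
    """Integer segmentation mask plus the nucleus-center table.

    ``labels`` is ``(H, W)``; 0 is background and cells carry the contiguous
    labels ``1..N``. ``centers`` has one row per label with columns
    ``label, x, y`` (nucleus centroid, pixel coordinates).
    """

    labels: np.ndarray
    centers: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label mask must be integer-typed")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if present.size != n:
            raise ValidationError("labels must form a contiguous range 1..N")
        if self.centers is None:
            self.centers = _centroid_table(self.labels)
        if list(self.centers["label"]) != list(range(1, n + 1)):
            raise ValidationError("centers table must list labels 1..N in order")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def center_array(self) -> np.ndarray:
        """Centers as an (N, 2) array of (x, y), row i for label i+1."""
        return self.centers[["x", "y"]].to_numpy(dtype=float)

    def to_tiff(self, path: str | Path) -> None:
        if self.labels.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValidationError("too many labels for a 16-bit mask")
        tifffile.imwrite(str(path), self.labels.astype(np.uint16))


def _centroid_table(labels: np.ndarray) -> pd.DataFrame:
    from scipy import ndimage

    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        return pd.DataFrame({"label": pd.Series(dtype=int),
                             "x": pd.Series(dtype=float),
                             "y": pd.Series(dtype=float)})
    cyx = ndimage.center_of_mass(np.ones_like(labels), labels, present)
    cyx = np.asarray(cyx, dtype=float)
    return pd.DataFrame({"label": present.astype(int), "x": cyx[:, 1], "y": cyx[:, 0]})
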