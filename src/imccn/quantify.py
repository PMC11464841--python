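"""Per-cell feature extraction and 99th-percentile normalization.

The cell table is a plain :class:`pandas.DataFrame` with a documented,
stable column order::

    cell_id, image_id, patient_id, group, x, y, area,
    raw_<channel>..., norm_<channel>..., phenotype, cn

``raw_<ch>`` is the mean intensity of channel ``ch`` over the cell's pixels;
``norm_<ch>`` is that value divided by the channel's 99th percentile within
the normalization unit (per image by default), clipped at 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .containers import LabelMask, MultiplexImage
from .errors import ValidationError

ID_COLUMNS = ["cell_id", "image_id", "patient_id", "group", "x", "y", "area"]


def raw_column(channel: str) -> str:
    return f"raw_{channel}"


def norm_column(channel: str) -> str:
    return f"norm_{channel}"


def extract_features(image: MultiplexImage, mask: LabelMask, *,
                     image_id: str = "image0", patient_id: str = "patient0",
                     group: str = "none") -> pd.DataFrame:
    """One row per segmented cell: centroid, area, per-channel mean intensity."""
    if mask.labels.shape != image.shape:
        raise ValidationError(
            f"mask shape {mask.labels.shape} does not match image {image.shape}")
    if mask.n_cells == 0:
        cols = ID_COLUMNS + [raw_column(c) for c in image.channels]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    stack = np.moveaxis(image.data, 0, -1)
    props = regionprops_table(mask.labels, intensity_image=stack,
                              properties=("label", "centroid", "area",
                                          "intensity_mean"))
    df = pd.DataFrame({
        "cell_id": props["label"].astype(int),
        "image_id": image_id, "patient_id": patient_id, "group": group,
        "x": props["centroid-1"], "y": props["centroid-0"],
        "area": props["area"].astype(int),
    })
    for i, ch in enumerate(image.channels):
        df[raw_column(ch)] = props[f"intensity_mean-{i}"]
    return df


def normalize_p99(table: pd.DataFrame, channels: list[str], *,
                  percentile: float = 99.0, clip: bool = True,
                  unit: str | None = "image_id") -> pd.DataFrame:
    """Divide each channel by its percentile within each normalization unit.

    The percentile uses linear interpolation between order statistics (the
    numpy default); results depend on this definition. A channel whose
    percentile is 0 within a unit is left at 0 with a warning. With
    ``clip=True`` (default) normalized values above 1 are clipped to 1.
    """
    out = table.copy()
    groups = [(None, out)] if unit is None else list(out.groupby(unit, sort=False))
    for key, sub in groups:
        if len(sub) < 2:
            warnings.warn(f"normalization unit {key!r} has fewer than 2 cells")
        for ch in channels:
            vals = sub[raw_column(ch)].to_numpy(dtype=float)
            p = np.percentile(vals, percentile)
            if p == 0:
                warnings.warn(f"channel {ch!r} has zero {percentile:g}th "
                              f"percentile in unit {key!r}; left at 0")
                normed = np.zeros_like(vals)
            else:
                normed = vals / p
                if clip:
                    normed = np.minimum(normed, 1.0)
            out.loc[sub.index, norm_column(ch)] = normed
    return out


def write_cell_table(table: pd.DataFrame, path) -> None:
    """CSV export in the documented column order (extra columns trail)."""
    known = [c for c in ID_COLUMNS if c in table.columns]
    raws = sorted(c for c in table.columns if c.startswith("raw_"))
    norms = sorted(c for c in table.columns if c.startswith("norm_"))
    tail = [c for c in ("phenotype", "cn") if c in table.columns]
    rest = [c for c in table.columns
            if c not in known + raws + norms + tail]
    table[known + raws + norms + tail + rest].to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
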