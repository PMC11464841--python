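"""Cell delineation: nucleus detection, connected components, membrane rule.

Nuclei are thresholded (Otsu by default) and labeled by connectivity.
Membrane-positive fragments are then attached to the nearest nucleus center;
fragments more than ``max_dist`` pixels (default 15) from every nucleus
center are treated as artifacts and discarded. Touching nuclei are not split
by default — incomplete separation of adjacent cells is a known limitation
of the modality at this resolution — but a watershed split is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import filters, measure, morphology, segmentation as _sks

from .containers import LabelMask, MultiplexImage
from .errors import ValidationError

logger = logging.getLogger(__name__)

_CONNECTIVITY = {4: 1, 8: 2}  # pixel connectivity -> skimage connectivity rank


@dataclass
class SegmentationConfig:
    """Configuration for :func:`segment_cells`.

    The nuclear channel has no default: it must be named explicitly.
    ``threshold`` is ``'otsu'`` or a fixed intensity value applied to both
    the nuclear and membrane channels.
    """

    nuclear_channel: str
    membrane_channels: tuple[str, ...] = ()
    threshold: str | float = "otsu"
    min_area: int = 0
    connectivity: int = 8
    max_dist: float = 15.0
    split_touching: bool = False


def detect_nuclei(nuclear_plane: np.ndarray, threshold: str | float = "otsu",
                  min_area: int = 0) -> np.ndarray:
    """Binary nucleus mask: pixels above threshold, small objects removed."""
    plane = np.asarray(nuclear_plane, dtype=float)
    if plane.size == 0:
        raise ValidationError("nuclear plane is empty")
    if threshold == "otsu":
        if plane.max() == plane.min():
            warnings.warn("constant nuclear plane: nothing to detect")
            return np.zeros(plane.shape, dtype=bool)
        thr = filters.threshold_otsu(plane)
    else:
        thr = float(threshold)
    mask = plane > thr
    if min_area > 0 and mask.any():
        # drop objects strictly smaller than min_area
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1,
                                               connectivity=2)
    if not mask.any():
        warnings.warn("nucleus detection produced an all-background mask")
    return mask


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabelMask:
    """Label maximal connected regions 1..N and tabulate their centroids."""
    if connectivity not in _CONNECTIVITY:
        raise ValidationError("connectivity must be 4 or 8")
    labels = measure.label(np.asarray(mask, dtype=bool),
                           connectivity=_CONNECTIVITY[connectivity])
    return LabelMask(labels.astype(np.int32))


def _watershed_split(mask: np.ndarray, min_distance: int = 3) -> LabelMask:
    """Optional distance-transform watershed for touching nuclei."""
    from skimage.feature import peak_local_max

    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = _sks.watershed(-dist, markers, mask=mask)
    # watershed can drop markers; compact to 1..N
    out, _, _ = _sks.relabel_sequential(labels)
    return LabelMask(out.astype(np.int32))


def assign_membrane(membrane_mask: np.ndarray, nuclei: LabelMask,
                    max_dist: float = 15.0, connectivity: int = 8) -> LabelMask:
    """Attach membrane fragments to cells; discard distant artifacts.

    Each membrane-positive connected fragment is assigned to the nucleus
    whose center is nearest to the fragment centroid (Euclidean). Fragments
    whose nearest center is more than ``max_dist`` pixels away are discarded.
    Equidistant ties go to the lower label index (deterministic).
    """
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if membrane_mask.shape != nuclei.labels.shape:
        raise ValidationError("membrane mask and nucleus mask shapes differ")
    out = nuclei.labels.copy()
    if nuclei.n_cells == 0:
        if membrane_mask.any():
            warnings.warn("no nuclei: all membrane fragments discarded")
        return LabelMask(out, nuclei.centers.copy())
    frags = measure.label(membrane_mask, connectivity=_CONNECTIVITY[connectivity])
    n_frag = frags.max()
    if n_frag == 0:
        return LabelMask(out, nuclei.centers.copy())
    cyx = ndimage.center_of_mass(membrane_mask, frags, np.arange(1, n_frag + 1))
    frag_xy = np.asarray(cyx, dtype=float)[:, ::-1]
    centers = nuclei.center_array()  # ordered by label, so argmin ties -> lowest label
    d = cdist(frag_xy, centers)
    nearest = np.argmin(d, axis=1)
    keep = d[np.arange(n_frag), nearest] <= max_dist
    assigned = np.where(keep, nearest + 1, 0)
    frag_map = np.concatenate([[0], assigned]).astype(out.dtype)
    membrane_labels = frag_map[frags]
    np.copyto(out, membrane_labels, where=(out == 0) & (membrane_labels > 0))
    logger.info("membrane fragments: %d total, %d retained", n_frag, int(keep.sum()))
    return LabelMask(out, nuclei.centers.copy())


def segment_cells(image: MultiplexImage, config: SegmentationConfig) -> LabelMask:
    """Full delineation: detect nuclei -> label -> attach membrane."""
    nuclear = image.plane(config.nuclear_channel)
    if nuclear.max() == nuclear.min() == 0:
        warnings.warn("empty nuclear channel: no cells segmented")
        return LabelMask(np.zeros(image.shape, dtype=np.int32))
    nmask = detect_nuclei(nuclear, config.threshold, config.min_area)
    logger.info("nucleus mask: %d pixels", int(nmask.sum()))
    if config.split_touching:
        nuclei = _watershed_split(nmask)
    else:
        nuclei = label_components(nmask, config.connectivity)
    logger.info("nuclei labeled: %d", nuclei.n_cells)
    if not config.membrane_channels:
        return nuclei
    membrane = np.zeros(image.shape, dtype=bool)
    for ch in config.membrane_channels:
        plane = image.plane(ch)
        if plane.max() == plane.min():
            warnings.warn(f"constant membrane channel {ch!r} skipped")
            continue
        if config.threshold == "otsu":
            thr = filters.threshold_otsu(plane)
        else:
            thr = float(config.threshold)
        membrane |= plane > thr
    cells = assign_membrane(membrane, nuclei, config.max_dist,
                            config.connectivity)
    logger.info("cells after membrane assignment: %d", cells.n_cells)
    return cells
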