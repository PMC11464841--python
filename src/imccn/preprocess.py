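"""Image preparation: spillover compensation, median refinement, rescaling.

The fixed processing order is compensate -> median filter -> full-range
rescale; segmentation (the fourth phase) lives in :mod:`imccn.segment`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .containers import MultiplexImage, SpilloverMatrix
from .errors import UnmixingError, ValidationError

# condition numbers beyond this make per-pixel unmixing meaningless
_MAX_CONDITION = 1e12


def compensate(image: MultiplexImage, spill: SpilloverMatrix,
               method: str = "solve") -> MultiplexImage:
    """Unmix channel spillover.

    Per pixel the observed vector ``o`` is the true vector ``t`` mixed through
    the spillover matrix, ``o = t @ S`` (true signal in rows). ``method
    ='solve'`` inverts that linear system for all pixels at once and clips
    negative solutions to zero; ``method='nnls'`` solves the nonnegative
    least-squares problem per pixel instead (slower, never negative).

    Channels are matched by name, so the matrix may list them in any order.
    """
    S = spill.reordered(image.channels).matrix
    if np.linalg.cond(S) > _MAX_CONDITION:
        raise UnmixingError("spillover matrix is singular or near-singular")
    C = image.n_channels
    obs = image.data.reshape(C, -1)
    if method == "solve":
        try:
            true = np.linalg.solve(S.T, obs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - cond guard first
            raise UnmixingError(f"unmixing failed: {exc}") from exc
        true = np.clip(true, 0, None)
    elif method == "nnls":
        A = S.T
        true = np.empty_like(obs)
        for j in range(obs.shape[1]):
            true[:, j] = nnls(A, obs[:, j])[0]
    else:
        raise ValidationError(f"unknown compensation method {method!r}")
    return MultiplexImage(true.reshape(image.data.shape), list(image.channels),
                          image.pixel_size_um)


def median_filter(plane: np.ndarray, window: int = 3) -> np.ndarray:
    """Replace each pixel by the median of its ``window x window`` area.

    Borders are handled by edge replication. ``window`` must be odd;
    ``window=1`` is the identity.
    """
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise ValidationError(f"median window must be an odd integer >= 1, got {window}")
    return ndimage.median_filter(np.asarray(plane, dtype=float), size=window,
                                 mode="nearest")


def rescale_full_range(plane: np.ndarray) -> np.ndarray:
    """Linearly map a plane onto the full 0..255 intensity range.

    The plane minimum maps to 0 and the maximum to 255. A constant plane maps
    to all zeros (declared convention for the degenerate case).
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValidationError("cannot rescale an empty plane")
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) * (255.0 / (hi - lo))


def preprocess_image(image: MultiplexImage,
                     spill: SpilloverMatrix | None = None, *,
                     median_window: int = 3, rescale: bool = True,
                     method: str = "solve") -> MultiplexImage:
    """Run the full preparation sequence on every channel.

    Rescaling is per-channel (each channel independently mapped to 0..255);
    pass ``rescale=False`` to keep compensated/median-filtered ion counts.
    """
    out = compensate(image, spill, method=method) if spill is not None else image.copy()
    planes = [median_filter(p, median_window) for p in out.data]
    if rescale:
        planes = [rescale_full_range(p) for p in planes]
    return MultiplexImage(np.stack(planes), list(image.channels), image.pixel_size_um)
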