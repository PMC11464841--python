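"""Ground-truthed synthetic multiplexed tissue, images and trial tables.

This module generates the inputs every downstream stage is tested against:
a planted tissue (cell centers, phenotypes, spatial niches), a rendered
multi-channel image with channel spillover and Poisson counting noise, and
per-patient response/survival tables for the endpoint statistics.

Cells are drawn as a filled nuclear disk plus a thin membrane annulus —
deliberately simple shapes that still exercise spillover compensation,
nucleus detection, the membrane-assignment rule and per-cell quantification.
Spatial niches emulate the motifs the neighborhood analysis looks for:
uniform parenchyma and dense aggregates (e.g. a tertiary-lymphoid-structure-
like cluster of two lymphocyte types, or a vessel-like focus).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .containers import MultiplexImage, SpilloverMatrix
from .errors import PlacementError, ValidationError

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class NicheSpec:
    """One spatial niche: a proportion of cells, their type palette and layout.

    ``kind='uniform'`` scatters cells over the whole field; ``kind='aggregate'``
    concentrates them around ``n_foci`` focus points with Gaussian spread
    ``focus_sd`` (pixels), emulating dense structures such as TLS;
    ``kind='block'`` confines the niche to its own vertical strip of the
    field (strip widths proportional to the block niches' proportions),
    emulating contiguous tissue compartments such as tumor vs. stroma.
    """

    name: str
    proportion: float
    type_probs: tuple[float, ...]
    kind: str = "uniform"
    n_foci: int = 1
    focus_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "aggregate", "block"):
            raise ValidationError(f"unknown niche kind {self.kind!r}")
        if not 0 <= self.proportion <= 1:
            raise ValidationError("niche proportion must lie in [0, 1]")
        p = np.asarray(self.type_probs, dtype=float)
        if p.size == 0 or p.min() < 0 or abs(p.sum() - 1) > 1e-8:
            raise ValidationError(f"niche {self.name!r}: type_probs must sum to 1")


@dataclass
class GroundTruthTissue:
    """Planted cell positions, types and niche labels for one synthetic ROI."""

    centers: np.ndarray          # (n, 2) float, (x, y) pixel coordinates
    cell_types: np.ndarray       # (n,) int in 0..T-1
    niche_labels: np.ndarray     # (n,) int niche index
    field_size: tuple[int, int]  # (width, height) pixels
    radius_range: tuple[int, int]
    radii: np.ndarray = field(default=None)  # type: ignore[assignment]
    membrane_halo: int = 3       # annulus outer radius = nucleus radius + halo
    min_spacing: float = 0.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.cell_types = np.asarray(self.cell_types, dtype=int)
        self.niche_labels = np.asarray(self.niche_labels, dtype=int)
        n = len(self.centers)
        if self.radii is None:
            self.radii = np.full(n, self.radius_range[0], dtype=int)
        self.radii = np.asarray(self.radii, dtype=int)
        if not (len(self.cell_types) == len(self.niche_labels) == len(self.radii) == n):
            raise ValidationError("centers/types/niche_labels/radii lengths differ")
        w, h = self.field_size
        if n and (self.centers[:, 0].min() < 0 or self.centers[:, 0].max() >= w
                  or self.centers[:, 1].min() < 0 or self.centers[:, 1].max() >= h):
            raise ValidationError("cell centers must lie inside the field bounds")
        if n > 1 and self.min_spacing > 0:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(self.centers).query(self.centers, k=2)
            if d[:, 1].min() < self.min_spacing - 1e-9:
                raise ValidationError("pairwise center distance below min_spacing")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(1, self.n_cells + 1),
            "x": self.centers[:, 0], "y": self.centers[:, 1],
            "cell_type": self.cell_types, "niche": self.niche_labels,
            "radius": self.radii,
        })


@dataclass
class PanelSpec:
    """Marker panel: channel names, per-type mean expression and noise model.

    ``means`` is (T types x C channels) in arbitrary intensity units. Exactly
    one nuclear channel (expressed on the nuclear disk), one or more membrane
    channels (expressed on the annulus); all remaining channels are lineage
    markers expressed over the whole cell. ``poisson_scale`` sets the counts
    per intensity unit of the Poisson noise (0 disables noise and background);
    ``background`` is a uniform additive intensity. ``expression_cv`` is the
    cell-to-cell coefficient of variation of expression: each cell scales
    every channel mean by an independent log-normal factor, reproducing the
    multi-dimensional biological heterogeneity real marker intensities show
    (0 disables it).
    """

    channels: list[str]
    means: np.ndarray
    nuclear_channel: str
    membrane_channels: tuple[str, ...]
    background: float = 0.0
    poisson_scale: float = 0.0
    expression_cv: float = 0.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.channels = list(self.channels)
        if len(self.channels) < 2:
            raise ValidationError("panel needs at least 2 channels")
        if self.means.ndim != 2 or self.means.shape[1] != len(self.channels):
            raise ValidationError("means must be (n_types, n_channels)")
        if self.means.min() < 0:
            raise ValidationError("expression means must be nonnegative")
        if self.nuclear_channel not in self.channels:
            raise ValidationError("nuclear channel must be in the panel")
        for c in self.membrane_channels:
            if c not in self.channels:
                raise ValidationError(f"membrane channel {c!r} not in the panel")
        if self.nuclear_channel in self.membrane_channels:
            raise ValidationError("nuclear channel cannot also be a membrane channel")

    @property
    def n_types(self) -> int:
        return self.means.shape[0]


def default_panel(n_types: int, *, nuclear_mean: float = 40.0,
                  membrane_mean: float = 30.0, lineage_mean: float = 25.0,
                  off_target: float = 0.5, background: float = 0.2,
                  poisson_scale: float = 1.0,
                  expression_cv: float = 0.25) -> PanelSpec:
    """A minimal realistic panel: DNA, membrane, one lineage marker per type.

    Lineage markers are near-binary (high on their own type, a small
    off-target level elsewhere), which is how gating-grade IMC markers behave.
    """
    channels = ["DNA", "Membrane"] + [f"Lin{t}" for t in range(n_types)]
    means = np.full((n_types, len(channels)), off_target)
    means[:, 0] = nuclear_mean
    means[:, 1] = membrane_mean
    for t in range(n_types):
        means[t, 2 + t] = lineage_mean
    return PanelSpec(channels, means, "DNA", ("Membrane",),
                     background=background, poisson_scale=poisson_scale,
                     expression_cv=expression_cv)


def _niche_counts(n_cells: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment: exact up to rounding."""
    raw = proportions * n_cells
    counts = np.floor(raw).astype(int)
    rem = n_cells - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_tissue(n_cells: int, n_types: int,
                    niche_spec: list[NicheSpec] | None = None,
                    field_size: tuple[int, int] = (512, 512), seed: int = 0, *,
                    radius_range: tuple[int, int] = (3, 5), membrane_halo: int = 3,
                    min_spacing: float | None = None,
                    max_attempts: int = 500) -> GroundTruthTissue:
    """Place cells in the field by rejection sampling under a minimum spacing.

    The default spacing keeps whole cells (nucleus + membrane annulus) from
    touching, so a noise-free rendering segments into exactly ``n_cells``
    objects. Niche proportions must sum to 1; exceeding ``max_attempts``
    placements for any cell raises :class:`PlacementError` rather than
    silently truncating the tissue.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if n_types < 1:
        raise ValidationError("n_types must be >= 1")
    if niche_spec is None:
        niche_spec = [NicheSpec("uniform", 1.0, tuple(np.full(n_types, 1 / n_types)))]
    props = np.array([s.proportion for s in niche_spec], dtype=float)
    if abs(props.sum() - 1) > 1e-6:
        raise ValidationError(f"niche proportions sum to {props.sum():.6f}, not 1")
    for s in niche_spec:
        if len(s.type_probs) != n_types:
            raise ValidationError(
                f"niche {s.name!r} has {len(s.type_probs)} type probabilities "
                f"for {n_types} types")

    rng = np.random.default_rng(seed)
    w, h = field_size
    margin = radius_range[1] + membrane_halo + 1
    if w <= 2 * margin or h <= 2 * margin:
        raise PlacementError(
            f"field {field_size} too small for cell radius {radius_range[1]} "
            f"plus membrane halo {membrane_halo}")
    if min_spacing is None:
        min_spacing = 2 * (radius_range[1] + membrane_halo) + 2

    counts = _niche_counts(n_cells, props)

    # vertical strips for block niches, widths proportional to proportion
    block_props = np.array([s.proportion if s.kind == "block" else 0.0
                            for s in niche_spec])
    strips: dict[int, tuple[float, float]] = {}
    if block_props.sum() > 0:
        edges = np.concatenate([[0.0], np.cumsum(block_props / block_props.sum())])
        usable = (w - 1 - 2 * margin)
        j = 0
        for i, s in enumerate(niche_spec):
            if s.kind == "block":
                strips[i] = (margin + edges[j] * usable,
                             margin + edges[j + 1] * usable)
                j += 1

    placed: list[np.ndarray] = []
    types: list[int] = []
    niches: list[int] = []
    for ni, (spec, cnt) in enumerate(zip(niche_spec, counts)):
        if cnt == 0:
            continue
        if spec.kind == "aggregate":
            foci = np.column_stack([
                rng.uniform(0.25 * w, 0.75 * w, spec.n_foci),
                rng.uniform(0.25 * h, 0.75 * h, spec.n_foci),
            ])
        for _ in range(cnt):
            for attempt in range(max_attempts):
                if spec.kind == "uniform":
                    pos = np.array([rng.uniform(margin, w - 1 - margin),
                                    rng.uniform(margin, h - 1 - margin)])
                elif spec.kind == "block":
                    x0, x1 = strips[ni]
                    pos = np.array([rng.uniform(x0, x1),
                                    rng.uniform(margin, h - 1 - margin)])
                else:
                    focus = foci[rng.integers(spec.n_foci)]
                    pos = focus + rng.normal(0, spec.focus_sd, 2)
                    pos = np.clip(pos, margin, [w - 1 - margin, h - 1 - margin])
                if not placed:
                    break
                d2 = np.sum((np.asarray(placed) - pos) ** 2, axis=1)
                if d2.min() >= min_spacing ** 2:
                    break
            else:
                raise PlacementError(
                    f"failed to place cell {len(placed) + 1}/{n_cells} after "
                    f"{max_attempts} attempts at min_spacing={min_spacing} in a "
                    f"{w}x{h} field")
            placed.append(pos)
            types.append(int(rng.choice(n_types, p=np.asarray(spec.type_probs))))
            niches.append(ni)

    radii = rng.integers(radius_range[0], radius_range[1] + 1, n_cells)
    return GroundTruthTissue(np.asarray(placed), np.asarray(types),
                             np.asarray(niches), field_size, radius_range,
                             radii=radii, membrane_halo=membrane_halo,
                             min_spacing=float(min_spacing))


def _cell_pixels(center: np.ndarray, radius: int, halo: int,
                 shape: tuple[int, int]):
    """Pixel index sets for the nuclear disk and the membrane annulus."""
    y, x = center[1], center[0]
    nuc = _disk((y, x), radius + 0.5, shape=shape)
    outer = _disk((y, x), radius + halo + 0.5, shape=shape)
    inner = _disk((y, x), radius + halo - 0.5, shape=shape)
    inner_set = set(zip(inner[0].tolist(), inner[1].tolist()))
    ann = [(r, c) for r, c in zip(outer[0].tolist(), outer[1].tolist())
           if (r, c) not in inner_set]
    ann_rr = np.array([p[0] for p in ann], dtype=int)
    ann_cc = np.array([p[1] for p in ann], dtype=int)
    return nuc, (ann_rr, ann_cc)


def mix_channels(image: MultiplexImage, spill: SpilloverMatrix) -> MultiplexImage:
    """Forward spillover mixing: observed = true @ S, per pixel."""
    S = spill.reordered(image.channels).matrix
    mixed = np.einsum("chw,ck->khw", image.data, S)
    return MultiplexImage(mixed, list(image.channels), image.pixel_size_um)


def render_image(tissue: GroundTruthTissue, panel: PanelSpec,
                 spillover: SpilloverMatrix | None = None,
                 seed: int = 0) -> tuple[MultiplexImage, np.ndarray]:
    """Render a tissue into an observed image stack plus its truth mask.

    True signal is laid down per cell (disk in the nuclear channel, annulus in
    membrane channels, whole cell for lineage markers), mixed through the
    spillover matrix, then — if the panel's ``poisson_scale`` is positive —
    degraded with uniform background and Poisson counting noise. The returned
    mask labels each cell's pixels (disk plus annulus) with its 1-based index.
    """
    if tissue.n_cells and tissue.cell_types.max() >= panel.n_types:
        raise ValidationError(
            f"tissue has type index {tissue.cell_types.max()} but the panel "
            f"defines only {panel.n_types} types")
    C = len(panel.channels)
    w, h = tissue.field_size
    true = np.zeros((C, h, w))
    mask = np.zeros((h, w), dtype=np.int32)
    nuc_idx = panel.channels.index(panel.nuclear_channel)
    mem_idx = [panel.channels.index(c) for c in panel.membrane_channels]
    lin_idx = [i for i in range(C) if i != nuc_idx and i not in mem_idx]

    rng = np.random.default_rng(seed)
    if panel.expression_cv > 0:
        sigma = np.sqrt(np.log1p(panel.expression_cv ** 2))
        factors = rng.lognormal(-sigma ** 2 / 2, sigma, (tissue.n_cells, C))
    else:
        factors = np.ones((tissue.n_cells, C))

    for i in range(tissue.n_cells):
        t = tissue.cell_types[i]
        levels = panel.means[t] * factors[i]
        (nrr, ncc), (arr, acc) = _cell_pixels(tissue.centers[i],
                                              int(tissue.radii[i]),
                                              tissue.membrane_halo, (h, w))
        mask[nrr, ncc] = i + 1
        mask[arr, acc] = i + 1
        true[nuc_idx, nrr, ncc] = levels[nuc_idx]
        for c in mem_idx:
            true[c, arr, acc] = levels[c]
        for c in lin_idx:
            true[c, nrr, ncc] = levels[c]
            true[c, arr, acc] = levels[c]

    if spillover is not None:
        if spillover.n_channels != C:
            raise ValidationError(
                f"spillover is {spillover.n_channels}x{spillover.n_channels} "
                f"but the panel has {C} channels")
        S = spillover.reordered(panel.channels).matrix
        obs = np.einsum("chw,ck->khw", true, S)
    else:
        obs = true

    if panel.poisson_scale > 0:
        lam = (obs + panel.background) * panel.poisson_scale
        obs = rng.poisson(lam).astype(float) / panel.poisson_scale

    return MultiplexImage(obs, list(panel.channels)), mask


@dataclass(frozen=True)
class SurvivalParams:
    """Event-time model for synthetic trial tables: exponential event times
    (parameterized by their medians, months) with administrative censoring at
    a per-patient follow-up horizon."""

    median_pfs: float = 7.58
    median_os: float = 19.9
    followup: float = 16.9
    followup_jitter: float = 3.0


def generate_trial_table(n_patients: int,
                         response_probs=(0.0, 0.5, 1 / 3, 1 / 6),
                         survival_params: SurvivalParams | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Per-patient best response and PFS/OS event or censoring times.

    ``response_probs`` are probabilities over (CR, PR, SD, PD) and must sum
    to 1. ``n_patients=0`` returns an empty, correctly-typed table.
    """
    probs = np.asarray(response_probs, dtype=float)
    if probs.shape != (4,) or probs.min() < 0 or abs(probs.sum() - 1) > 1e-6:
        raise ValidationError("response_probs must be 4 probabilities over "
                              "(CR, PR, SD, PD) summing to 1")
    if survival_params is None:
        survival_params = SurvivalParams()
    cols = ["patient_id", "best_response", "pfs_months", "pfs_event",
            "os_months", "os_event", "fas", "pps", "ss"]
    if n_patients == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            cols, [str, str, float, bool, float, bool, bool, bool, bool])})

    rng = np.random.default_rng(seed)
    responses = rng.choice(list(RESPONSE_CATEGORIES), size=n_patients, p=probs)
    lam_pfs = np.log(2) / survival_params.median_pfs
    lam_os = np.log(2) / survival_params.median_os
    t_pfs = rng.exponential(1 / lam_pfs, n_patients)
    t_os = np.maximum(t_pfs, rng.exponential(1 / lam_os, n_patients))
    horizon = survival_params.followup + rng.uniform(
        -survival_params.followup_jitter, survival_params.followup_jitter,
        n_patients)
    horizon = np.maximum(horizon, 0.5)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
        "best_response": responses,
        "pfs_months": np.minimum(t_pfs, horizon),
        "pfs_event": t_pfs <= horizon,
        "os_months": np.minimum(t_os, horizon),
        "os_event": t_os <= horizon,
        "fas": True, "pps": True, "ss": True,
    })


def write_simulation(out_dir: str | Path, tissue: GroundTruthTissue,
                     image: MultiplexImage, mask: np.ndarray,
                     provenance: dict) -> None:
    """Write a simulated ROI: image TIFF, 16-bit truth-mask TIFF, truth CSV,
    provenance JSON (seed and parameters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image.to_tiff(out / "image.tiff")
    import tifffile

    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("too many cells for a 16-bit mask")
    tifffile.imwrite(str(out / "mask.tiff"), mask.astype(np.uint16))
    tissue.to_frame().to_csv(out / "truth_cells.csv", index=False)
    provenance = dict(provenance)
    provenance["channels"] = list(image.channels)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
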