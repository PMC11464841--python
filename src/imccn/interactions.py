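"""Permutation interaction testing and patient-level composition tensors.

The interaction test follows the classic label-permutation scheme used
throughout multiplexed-imaging analysis: for each ordered pair of cell
types (A, B) the statistic is the mean, over cells of type A, of the number
of type-B neighbors. The null is built by shuffling phenotype labels within
each image while keeping positions (and hence the neighbor graph) fixed.
Empirical p-values use the +1 correction, so they are never exactly zero,
and enrichment/avoidance are the two tails of the same null sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import ValidationError


def neighbor_pairs(centroids: np.ndarray, *, radius: float | None = None,
                   windows: list[np.ndarray] | None = None) -> np.ndarray:
    """Undirected unique neighbor pairs under the declared rule.

    Exactly one of ``radius`` (fixed-radius graph) or ``windows`` (the CN
    windows from :func:`imccn.neighborhoods.knn_windows`) must be given.
    Returns an (m, 2) array with ``pair[0] < pair[1]``.
    """
    if (radius is None) == (windows is None):
        raise ValidationError("specify exactly one of radius= or windows=")
    if radius is not None:
        pts = np.atleast_2d(np.asarray(centroids, dtype=float))
        if radius <= 0 or len(pts) < 2:
            return np.empty((0, 2), dtype=int)
        pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
        return np.sort(pairs, axis=1)
    seen = set()
    for win in windows:
        center = win[0]
        for j in win[1:]:
            seen.add((min(center, int(j)), max(center, int(j))))
    if not seen:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(seen), dtype=int)


def _adjacency(pairs: np.ndarray, n: int) -> sparse.csr_matrix:
    if len(pairs) == 0:
        return sparse.csr_matrix((n, n))
    i, j = pairs[:, 0], pairs[:, 1]
    data = np.ones(2 * len(pairs))
    return sparse.csr_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))


@dataclass
class InteractionResult:
    """Observed pairwise statistics, the permutation null, and p-values.

    All matrices are (T, T) indexed by ``types``; entry (a, b) concerns
    type-b neighbors of type-a cells. Entries for a type with no cells are
    NaN. ``per_image`` holds the observed matrix per image with NaN rows for
    types absent from that image (reported as missing, not zero).
    """

    types: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_std: np.ndarray
    p_enrich: np.ndarray
    p_avoid: np.ndarray
    n_perm: int
    seed: int
    per_image: dict | None = None

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.types, name="type_a")
        cols = pd.Index(self.types, name="type_b")
        return {
            "observed": pd.DataFrame(self.observed, idx, cols),
            "p_enrich": pd.DataFrame(self.p_enrich, idx, cols),
            "p_avoid": pd.DataFrame(self.p_avoid, idx, cols),
        }


def _pair_stat(counts: np.ndarray, codes: np.ndarray, T: int) -> np.ndarray:
    """Mean type-B neighbor count over type-A cells; NaN for absent types."""
    out = np.full((T, T), np.nan)
    for a in range(T):
        sel = codes == a
        if sel.any():
            out[a] = counts[sel].mean(axis=0)
    return out


def permutation_test(table: pd.DataFrame, *, radius: float | None = None,
                     windows: list[np.ndarray] | None = None,
                     n_perm: int = 999, seed: int = 0,
                     type_col: str = "phenotype",
                     image_col: str = "image_id") -> InteractionResult:
    """Label-shuffling interaction/avoidance test, stratified within image.

    Positions are fixed; the null shuffles ``type_col`` labels within each
    image (never across images or patients). For each ordered type pair,
    ``p_enrich = (1 + #{null >= obs}) / (1 + n_perm)`` and ``p_avoid`` is the
    mirrored tail of the same null sample.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-values are coarse")
    types, codes = np.unique(table[type_col].to_numpy(), return_inverse=True)
    T = len(types)
    n = len(table)
    pts = table[["x", "y"]].to_numpy(dtype=float)
    images = table[image_col].to_numpy()
    rng = np.random.default_rng(seed)

    # per-image adjacency over global indices (windows already per-image)
    if windows is not None:
        A = _adjacency(neighbor_pairs(pts, windows=windows), n)
    else:
        blocks = []
        for img in pd.unique(images):
            sel = np.flatnonzero(images == img)
            pairs = neighbor_pairs(pts[sel], radius=radius)
            blocks.append(sel[pairs] if len(pairs) else np.empty((0, 2), int))
        all_pairs = np.vstack(blocks) if blocks else np.empty((0, 2), int)
        A = _adjacency(all_pairs, n)

    onehot = np.zeros((n, T))
    onehot[np.arange(n), codes] = 1
    observed = _pair_stat(A @ onehot, codes, T)

    per_image = {}
    for img in pd.unique(images):
        sel = np.flatnonzero(images == img)
        sub = A[sel][:, sel]
        per_image[img] = _pair_stat(sub @ onehot[sel], codes[sel], T)

    strata = [np.flatnonzero(images == img) for img in pd.unique(images)]
    ge = np.zeros((T, T))
    le = np.zeros((T, T))
    acc = np.zeros((T, T))
    acc2 = np.zeros((T, T))
    perm_codes = codes.copy()
    for _ in range(n_perm):
        for sel in strata:
            perm_codes[sel] = codes[sel][rng.permutation(len(sel))]
        oh = np.zeros((n, T))
        oh[np.arange(n), perm_codes] = 1
        null = _pair_stat(A @ oh, perm_codes, T)
        with np.errstate(invalid="ignore"):
            ge += (null >= observed)
            le += (null <= observed)
        acc += np.nan_to_num(null)
        acc2 += np.nan_to_num(null) ** 2
    nanmask = np.isnan(observed)
    p_enrich = (1.0 + ge) / (1.0 + n_perm)
    p_avoid = (1.0 + le) / (1.0 + n_perm)
    p_enrich[nanmask] = np.nan
    p_avoid[nanmask] = np.nan
    null_mean = acc / n_perm
    null_std = np.sqrt(np.maximum(acc2 / n_perm - null_mean ** 2, 0))
    return InteractionResult(types=types, observed=observed,
                             null_mean=null_mean, null_std=null_std,
                             p_enrich=p_enrich, p_avoid=p_avoid,
                             n_perm=n_perm, seed=seed, per_image=per_image)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment over the finite entries of a matrix."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


@dataclass
class GroupTensorSet:
    """Per-patient CN x cell-type count matrices with group labels."""

    counts: np.ndarray           # (P, K, T)
    patients: list
    groups: list                 # group label per patient
    cn_values: np.ndarray
    type_values: np.ndarray

    def type_marginal(self) -> np.ndarray:
        """Marginal over CN: per-patient overall type counts (P, T)."""
        return self.counts.sum(axis=1)

    def group_mean_composition(self) -> dict:
        """Per-group mean of patient-normalized CN x type compositions."""
        out = {}
        for g in sorted(set(self.groups)):
            sel = [i for i, gi in enumerate(self.groups) if gi == g]
            mats = self.counts[sel].astype(float)
            totals = mats.sum(axis=(1, 2), keepdims=True)
            totals[totals == 0] = 1
            out[g] = (mats / totals).mean(axis=0)
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for pi, (pat, grp) in enumerate(zip(self.patients, self.groups)):
            for ki, cn in enumerate(self.cn_values):
                for ti, t in enumerate(self.type_values):
                    rows.append((pat, grp, cn, t, int(self.counts[pi, ki, ti])))
        return pd.DataFrame(rows, columns=["patient_id", "group", "cn",
                                           "cell_type", "count"])


def group_tensor(table: pd.DataFrame, *, type_col: str = "phenotype",
                 cn_col: str = "cn", patient_col: str = "patient_id",
                 group_col: str = "group") -> GroupTensorSet:
    """Tabulate each cell type within every CN, per patient.

    Cells with a missing phenotype or CN label are excluded (their count is
    logged via a warning). Each patient's matrix sums to that patient's
    labeled cell count.
    """
    work = table[[patient_col, group_col, cn_col, type_col]].copy()
    labeled = work.dropna(subset=[cn_col, type_col])
    dropped = len(work) - len(labeled)
    if dropped:
        warnings.warn(f"{dropped} unlabeled cells excluded from the tensor")
    cn_values = np.unique(labeled[cn_col].to_numpy())
    type_values = np.unique(labeled[type_col].to_numpy())
    patients = list(pd.unique(labeled[patient_col]))
    groups = [labeled.loc[labeled[patient_col] == p, group_col].iloc[0]
              for p in patients]
    counts = np.zeros((len(patients), len(cn_values), len(type_values)),
                      dtype=int)
    cn_index = {v: i for i, v in enumerate(cn_values)}
    t_index = {v: i for i, v in enumerate(type_values)}
    p_index = {v: i for i, v in enumerate(patients)}
    for pat, _, cn, t in labeled.itertuples(index=False):
        counts[p_index[pat], cn_index[cn], t_index[t]] += 1
    return GroupTensorSet(counts=counts, patients=patients, groups=groups,
                          cn_values=cn_values, type_values=type_values)
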