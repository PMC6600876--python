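"""Weighted structural network construction and edge-class bookkeeping.

Networks are built from a streamline-count matrix and a per-edge mean-FA
matrix: the count matrix is thresholded (strictly, ``counts > tau``) and
binarized, and the resulting mask selects which FA values survive as edge
weights. Alternative edge-weight definitions (raw streamline count, count
normalized by ROI size, count normalized by mean streamline length) are
supported for sensitivity analyses.

Edges are classified into four anatomical classes — subcortical,
left-hemispheric cortical, right-hemispheric cortical, interhemispheric
cortical — and class-mean weights average over *all* region pairs of the
class, counting absent edges as zero, so sparser connectivity lowers the
class mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .netgen import Parcellation

__all__ = [
    "WeightedNetwork",
    "EDGE_CLASSES",
    "WEIGHT_MODES",
    "symmetric_density",
    "build_weighted_network",
    "consensus_mask",
    "apply_mask",
    "edge_class_of",
    "edge_class_matrix",
    "edge_class_mean_weights",
]

EDGE_CLASSES: tuple[str, ...] = (
    "subcortical",
    "left",
    "right",
    "interhemispheric",
)

WEIGHT_MODES: tuple[str, ...] = (
    "fa",
    "count",
    "count_roi_norm",
    "count_length_norm",
)


@dataclass(frozen=True)
class WeightedNetwork:
    """A symmetric nonnegative weight matrix bound to a parcellation."""

    weights: np.ndarray
    parcellation: Parcellation
    weight_mode: str = "fa"
    threshold_used: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = self.parcellation.n_regions
        if w.shape != (n, n):
            raise ValidationError(
                f"weights shape {w.shape} != parcellation size {(n, n)}"
            )
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("weight matrix diagonal must be zero")
        if np.any(w < 0):
            raise ValidationError("weights must be nonnegative")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        if self.weight_mode == "fa" and np.any(w > 1.0):
            raise ValidationError("FA weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.parcellation.n_regions

    @property
    def support(self) -> np.ndarray:
        return self.weights > 0


def symmetric_density(raw_counts: np.ndarray) -> np.ndarray:
    """Symmetric intersection of a directed streamline-count matrix.

    Streamline counts are direction-dependent in tractography; the
    symmetric count averages the two directions,
    ``out_ij = (raw_ij + raw_ji) / 2``, and zeroes the diagonal.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValidationError(f"expected square matrix, got {raw.shape}")
    if np.any(raw < 0):
        raise ValidationError("streamline counts must be nonnegative")
    out = (raw + raw.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def build_weighted_network(
    counts: np.ndarray,
    fa: np.ndarray,
    threshold: float,
    parcellation: Parcellation,
    weight_mode: str = "fa",
    roi_sizes: np.ndarray | None = None,
    lengths: np.ndarray | None = None,
) -> WeightedNetwork:
    """Threshold the count matrix, binarize, and weight the surviving edges.

    The mask is ``counts > threshold`` (strict, so a threshold of zero
    removes only zero-count pairs). Weight modes:

    - ``fa``: FA value of surviving edges (the primary definition);
    - ``count``: symmetric streamline count;
    - ``count_roi_norm``: count divided by the mean size of the two ROIs;
    - ``count_length_norm``: count divided by mean streamline length.
    """
    counts = np.asarray(counts, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if counts.shape != fa.shape:
        raise ValidationError("counts and fa must have the same shape")
    if weight_mode not in WEIGHT_MODES:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    if weight_mode == "fa" and (np.any(fa < 0) or np.any(fa > 1)):
        raise ValidationError("FA values must lie in [0, 1]")

    mask = counts > threshold
    np.fill_diagonal(mask, False)
    if weight_mode == "fa":
        weights = np.where(mask, fa, 0.0)
    elif weight_mode == "count":
        weights = np.where(mask, counts, 0.0)
    elif weight_mode == "count_roi_norm":
        if roi_sizes is None:
            raise ValidationError("count_roi_norm requires roi_sizes")
        sizes = np.asarray(roi_sizes, dtype=float)
        if np.any(sizes <= 0):
            raise ValidationError("roi_sizes must be positive")
        pair_size = (sizes[:, None] + sizes[None, :]) / 2.0
        weights = np.where(mask, counts / pair_size, 0.0)
    else:  # count_length_norm
        if lengths is None:
            raise ValidationError("count_length_norm requires lengths")
        lens = np.asarray(lengths, dtype=float)
        if lens.shape != counts.shape:
            raise ValidationError("lengths must match counts shape")
        safe = np.where(lens > 0, lens, np.inf)
        weights = np.where(mask, counts / safe, 0.0)
    np.fill_diagonal(weights, 0.0)
    return WeightedNetwork(
        weights=weights,
        parcellation=parcellation,
        weight_mode=weight_mode,
        threshold_used=float(threshold),
    )


def consensus_mask(networks: Iterable[WeightedNetwork]) -> np.ndarray:
    """Edges present in *every* network (group-consensus thresholding).

    Consensus thresholding equalizes network density across subjects, so
    density-sensitive metrics (clustering, efficiency) compare like with
    like. Returns a boolean matrix: 1 iff the edge weight is positive in
    all inputs.
    """
    networks = list(networks)
    if not networks:
        raise ValidationError("need at least one network")
    parc = networks[0].parcellation
    mask = np.ones((parc.n_regions, parc.n_regions), dtype=bool)
    for net in networks:
        if net.parcellation.labels != parc.labels:
            raise ValidationError("networks use different parcellations")
        mask &= net.support
    np.fill_diagonal(mask, False)
    return mask


def apply_mask(network: WeightedNetwork, mask: np.ndarray) -> WeightedNetwork:
    """Restrict a network to the edges of a binary mask."""
    mask = np.asarray(mask)
    if mask.shape != network.weights.shape:
        raise ValidationError("mask shape mismatch")
    if not np.array_equal(mask, mask.T):
        raise ValidationError("mask must be symmetric")
    return WeightedNetwork(
        weights=network.weights * (mask != 0),
        parcellation=network.parcellation,
        weight_mode=network.weight_mode,
        threshold_used=network.threshold_used,
    )


def edge_class_of(parcellation: Parcellation, i: int, j: int) -> str:
    """Anatomical class of the edge between regions ``i`` and ``j``.

    Any edge touching a subcortical region is ``subcortical`` (this
    includes subcortical-subcortical pairs); cortico-cortical edges are
    ``left``, ``right`` or ``interhemispheric`` by hemisphere.
    """
    if i == j:
        raise ValidationError("self-loops have no edge class")
    a, b = parcellation.regions[i], parcellation.regions[j]
    if a.tissue == "subcortical" or b.tissue == "subcortical":
        return "subcortical"
    if a.hemisphere == b.hemisphere:
        return a.hemisphere  # 'left' or 'right'
    return "interhemispheric"


def edge_class_matrix(parcellation: Parcellation) -> np.ndarray:
    """n x n matrix of edge-class names (empty string on the diagonal)."""
    hemi = parcellation.hemispheres
    subcort = parcellation.tissues == "subcortical"
    n = parcellation.n_regions
    out = np.empty((n, n), dtype=object)
    any_subcort = subcort[:, None] | subcort[None, :]
    same_hemi = hemi[:, None] == hemi[None, :]
    left = (hemi == "left")[:, None] & (hemi == "left")[None, :]
    right = (hemi == "right")[:, None] & (hemi == "right")[None, :]
    out[:] = "interhemispheric"
    out[same_hemi & left] = "left"
    out[same_hemi & right] = "right"
    out[any_subcort] = "subcortical"
    np.fill_diagonal(out, "")
    return out


def edge_class_mean_weights(
    network: WeightedNetwork,
    parcellation: Parcellation | None = None,
) -> Mapping[str, float]:
    """Mean weight per edge class over *all* unordered pairs of the class.

    Absent edges contribute zeros, so the class mean reflects both edge
    weight and how densely the class is connected.
    """
    parc = parcellation or network.parcellation
    classes = edge_class_matrix(parc)
    iu = np.triu_indices(parc.n_regions, k=1)
    flat_class = classes[iu]
    flat_w = network.weights[iu]
    out: dict[str, float] = {}
    for cls in EDGE_CLASSES:
        sel = flat_class == cls
        if np.any(sel):
            out[cls] = float(flat_w[sel].mean())
    return out
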