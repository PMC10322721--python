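"""Relating receptor gradients to cognitive networks and functional maps.

Functional activation z-maps (meta-analytic likelihood maps) are
binarized at z > 3.1 and embedded along a gradient by Dice overlap with
20 equal-count percentile bins of the gradient's vertex map; the scalar
embedding position is the Dice-weighted bin centroid (an argmax-bin
alternative is available).  Per-network summaries pool vertex values
within each of the 7 cognitive networks, excluding the limbic network
by default, and functional receptor fingerprints average receptor
density over the significantly activated vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_maps import LIMBIC_NETWORK, NETWORK_NAMES
from .exceptions import DataError, ParameterError

__all__ = [
    "FunctionalMap",
    "EmbeddingResult",
    "binarize",
    "dice_embedding",
    "network_summary",
    "functional_fingerprint",
    "place_in_receptor_space",
]

#: Default binarization threshold for likelihood z-maps.
Z_THRESHOLD = 3.1
DEFAULT_BINS = 20


@dataclass
class FunctionalMap:
    """A per-vertex activation z-map with optional homology weight."""

    z: np.ndarray
    label: str = ""
    threshold: float = Z_THRESHOLD
    homology: float | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError("threshold must be positive")
        if self.homology is not None and not (0 <= self.homology <= 1):
            raise ParameterError("homology weight must lie in [0, 1]")


@dataclass
class EmbeddingResult:
    """Per-bin Dice profile and scalar position along one gradient."""

    dice: np.ndarray  # (n_bins,)
    position: float  # bin-centroid units, in [1, n_bins]
    label: str = ""


def binarize(fmap: FunctionalMap) -> np.ndarray:
    """Boolean mask of vertices with z strictly above the threshold."""
    z = np.asarray(fmap.z, dtype=float)
    if not np.isfinite(z).all():
        raise DataError("z-map contains non-finite values")
    mask = z > fmap.threshold
    if not mask.any():
        raise DataError(
            f"no vertex exceeds z > {fmap.threshold}: embedding undefined")
    return mask


def _percentile_bins(gradient: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count percentile bin index (0-based) per vertex; ties broken
    by stable vertex order, bin sizes differ by at most one."""
    n = gradient.shape[0]
    if n_bins > n:
        raise ParameterError("more bins than vertices")
    order = np.argsort(gradient, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = (np.arange(n) * n_bins) // n
    return bin_of


def dice_embedding(mask: np.ndarray, gradient: np.ndarray,
                   n_bins: int = DEFAULT_BINS, *,
                   reduction: str = "weighted") -> EmbeddingResult:
    """Embed a binary activation mask along a vertex gradient map.

    Dice(mask, bin) = 2 |mask & bin| / (|mask| + |bin|) for each of
    ``n_bins`` equal-count percentile bins; the scalar position is the
    Dice-weighted bin centroid (``reduction="weighted"``, bins numbered
    1..n_bins) or the argmax bin (``reduction="argmax"``).
    """
    mask = np.asarray(mask, dtype=bool)
    g = np.asarray(gradient, dtype=float)
    if mask.shape != g.shape:
        raise ParameterError("mask and gradient must cover the same vertices")
    if not mask.any():
        raise DataError("empty mask")
    if not np.isfinite(g[mask]).all():
        raise DataError("gradient not finite on masked vertices")
    bin_of = _percentile_bins(g, n_bins)
    n_mask = int(mask.sum())
    dice = np.empty(n_bins)
    for b in range(n_bins):
        in_bin = bin_of == b
        inter = int((mask & in_bin).sum())
        dice[b] = 2.0 * inter / (n_mask + int(in_bin.sum()))
    total = dice.sum()
    if reduction == "weighted":
        position = float(((np.arange(n_bins) + 1) * dice).sum() / total)
    elif reduction == "argmax":
        position = float(np.argmax(dice) + 1)
    else:
        raise ParameterError(f"unknown reduction {reduction!r}")
    return EmbeddingResult(dice=dice, position=position)


def network_summary(vertex_values: np.ndarray, cortex, *,
                    exclude_limbic: bool = True) -> pd.DataFrame:
    """Mean and distribution of a vertex map within each cognitive network.

    Returns a DataFrame indexed by network name with columns ``mean``
    (vertex-area-weighted), ``n_vertices`` and ``values`` (the pooled
    per-vertex values, kept for raincloud-style rendering).  The limbic
    network is excluded by default (no receptor data there in the study
    design).  Weighting by vertex area makes the network means, combined
    with network surface areas, recover the global map mean exactly.
    """
    if cortex.network_labels is None:
        raise DataError("cortex carries no network labels")
    v = np.asarray(vertex_values, dtype=float)
    rows = {}
    for k, name in enumerate(NETWORK_NAMES):
        if exclude_limbic and name == LIMBIC_NETWORK:
            continue
        sel = (cortex.network_labels == k) & np.isfinite(v)
        vals = v[sel]
        w = cortex.vertex_areas[sel]
        rows[name] = {
            "mean": float(np.average(vals, weights=w)) if vals.size else np.nan,
            "n_vertices": int(vals.size),
            "values": vals,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def functional_fingerprint(mask: np.ndarray, receptor_vertex_maps: pd.DataFrame,
                           vertex_areas: np.ndarray) -> pd.Series:
    """Vertex-area-weighted mean receptor vector over activated vertices.

    ``receptor_vertex_maps`` is vertices x receptors (NaN where an area
    carries no receptor data); vertices without data are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    X = receptor_vertex_maps.to_numpy(dtype=float)
    w = np.asarray(vertex_areas, dtype=float)
    out = {}
    for j, rec in enumerate(receptor_vertex_maps.columns):
        sel = mask & np.isfinite(X[:, j])
        if not sel.any():
            raise DataError(f"no masked vertex carries data for receptor {rec!r}")
        out[rec] = float(np.average(X[sel, j], weights=w[sel]))
    return pd.Series(out, name="fingerprint")


def place_in_receptor_space(fmaps: list[FunctionalMap], gradient1: np.ndarray,
                            gradient2: np.ndarray, n_bins: int = DEFAULT_BINS
                            ) -> pd.DataFrame:
    """Locate functional maps in the 2-D receptor space.

    Each map's coordinate along a gradient is its Dice-embedding
    position rescaled linearly from bin units [1, n_bins] to that
    gradient's value range; homology weights pass through for rendering.
    """
    g1 = np.asarray(gradient1, dtype=float)
    g2 = np.asarray(gradient2, dtype=float)
    rows = {}
    for fm in fmaps:
        mask = binarize(fm)
        e1 = dice_embedding(mask, g1, n_bins)
        e2 = dice_embedding(mask, g2, n_bins)

        def rescale(pos, g):
            lo, hi = float(np.nanmin(g)), float(np.nanmax(g))
            return lo + (pos - 1) / (n_bins - 1) * (hi - lo)

        rows[fm.label] = {
            "position1": rescale(e1.position, g1),
            "position2": rescale(e2.position, g2),
            "bin1": e1.position,
            "bin2": e2.position,
            "homology": fm.homology,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
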