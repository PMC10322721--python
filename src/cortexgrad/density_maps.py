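"""Parcel-level map algebra for receptor density data.

The central container is :class:`ReceptorMatrix`, an areas x receptors
density table carrying a units flag (fmol per mg protein, as measured on
film, or fmol per neuron after normalization by neuron density).  The
module also provides overlap-weighted resampling between parcellations,
vertex-map parcel averaging and the per-neuron conversion.

Unit bookkeeping for the per-neuron conversion: receptor densities are
measured per mg of *protein*, neuron densities per g of *tissue*.  Taking
brain tissue to be 8% protein by weight, an area with raw density
``c`` fmol (mg protein)^-1 and ``d`` neurons g^-1 holds

    c * 0.08 * 1000 / d   fmol per neuron,

the factor 1000 converting mg protein to g tissue.  The conversion is a
per-area positive rescaling, so z-scored PCA gradients are unaffected by
the protein-fraction constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

#: Units flags understood by :class:`ReceptorMatrix`.
UNITS_RAW = "fmol/mg_protein"
UNITS_PER_NEURON = "fmol/neuron"

#: Protein mass fraction of brain tissue used for per-neuron conversion.
PROTEIN_FRACTION = 0.08
_MG_PER_G = 1000.0

#: The seven canonical cognitive networks, in their conventional order.
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience",
    "limbic",
    "frontoparietal",
    "default_mode",
)
LIMBIC_NETWORK = "limbic"


def canonical_receptors() -> list[str]:
    """The 14 canonical receptor names, in fingerprint order."""
    text = resources.files("cortexgrad.data").joinpath("receptors.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class ReceptorMatrix:
    """Areas x receptors density table with explicit units.

    Parameters
    ----------
    values
        DataFrame indexed by area id with one column per receptor.
        Densities must be non-negative (NaN marks missing areas).
    units
        ``"fmol/mg_protein"`` or ``"fmol/neuron"``.
    subjects
        Optional per-subject stack (list of DataFrames with the same
        shape as ``values``); ``values`` is conventionally their mean.
    """

    values: pd.DataFrame
    units: str
    subjects: list[pd.DataFrame] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.units not in (UNITS_RAW, UNITS_PER_NEURON):
            raise ParameterError(f"unknown units flag {self.units!r}")
        if self.values.index.has_duplicates:
            raise DataError("duplicate area ids in receptor matrix")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise DataError("negative receptor density encountered")

    @property
    def areas(self) -> list[str]:
        return [str(a) for a in self.values.index]

    @property
    def receptors(self) -> list[str]:
        return [str(r) for r in self.values.columns]

    def copy(self) -> "ReceptorMatrix":
        return ReceptorMatrix(self.values.copy(), self.units, self.subjects)


@dataclass
class ParcelOverlap:
    """Row-stochastic fractional overlap between two labelings.

    ``weights[s, t]`` is the fraction of source unit ``s``'s surface area
    lying inside target unit ``t``; valid rows sum to 1.  Source units
    with no assigned vertices are kept as flagged all-NaN rows rather
    than silently zeroed.
    """

    weights: pd.DataFrame
    empty_sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        ok = ~np.isnan(w).all(axis=1)
        if ok.any():
            sums = w[ok].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise DataError("overlap rows must sum to 1")


def parcel_average(vertex_map: np.ndarray, cortex) -> pd.Series:
    """Vertex-area-weighted mean of a vertex scalar map within each area.

    Non-finite vertex values are excluded (with a logged count); an area
    with no finite vertex is returned as NaN rather than fabricated.
    """
    values = np.asarray(vertex_map, dtype=float)
    if values.shape[0] != cortex.n_vertices:
        raise ParameterError("vertex map length does not match mesh")
    finite = np.isfinite(values)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("parcel_average: excluding %d non-finite vertices", n_bad)
    out = {}
    for aid, idx in cortex.area_vertices.items():
        sel = idx[finite[idx]]
        if sel.size == 0:
            out[aid] = np.nan
            continue
        w = cortex.vertex_areas[sel]
        out[aid] = float(np.average(values[sel], weights=w))
    return pd.Series(out, name="value").reindex(cortex.area_ids)


def compute_overlap(cortex, source_labels: np.ndarray, target_labels: np.ndarray,
                    source_ids=None, target_ids=None) -> ParcelOverlap:
    """Vertex-area-weighted fractional overlap between two labelings.

    Vertices labeled ``-1`` in either labeling are excluded from both
    margins.  ``overlap(s, t)`` = area of s intersect t / area of s.
    """
    src = np.asarray(source_labels)
    tgt = np.asarray(target_labels)
    if src.shape[0] != cortex.n_vertices or tgt.shape[0] != cortex.n_vertices:
        raise ParameterError("labelings must cover every vertex")
    s_ids = list(source_ids) if source_ids is not None else sorted(set(src[src != -1]))
    t_ids = list(target_ids) if target_ids is not None else sorted(set(tgt[tgt != -1]))
    s_pos = {s: i for i, s in enumerate(s_ids)}
    t_pos = {t: j for j, t in enumerate(t_ids)}
    w = np.zeros((len(s_ids), len(t_ids)))
    areas = cortex.vertex_areas
    keep = (src != -1) & (tgt != -1)
    s_idx = np.fromiter((s_pos[s] for s in src[keep]), dtype=int, count=int(keep.sum()))
    t_idx = np.fromiter((t_pos[t] for t in tgt[keep]), dtype=int, count=int(keep.sum()))
    np.add.at(w, (s_idx, t_idx), areas[keep])
    row = w.sum(axis=1)
    empty = [str(s_ids[i]) for i in np.nonzero(row == 0)[0]]
    with np.errstate(invalid="ignore"):
        frac = w / row[:, None]
    frac[row == 0] = np.nan
    df = pd.DataFrame(frac, index=[str(s) for s in s_ids], columns=[str(t) for t in t_ids])
    return ParcelOverlap(df, empty_sources=empty)


def overlap_resample(values: pd.Series, overlap: ParcelOverlap) -> pd.Series:
    """Resample a target-frame map onto the source frame.

    ``out[s] = sum_t overlap(s, t) * values[t]``; flagged empty source
    rows propagate as NaN.  The direction is explicit: to resample the
    other way, build the overlap with the roles swapped.
    """
    w = overlap.weights
    missing = set(w.columns) - set(map(str, values.index))
    if missing:
        raise DataError(f"map lacks values for target units: {sorted(missing)[:5]}")
    v = values.reindex(w.columns).to_numpy(dtype=float)
    out = w.to_numpy(dtype=float) @ v
    return pd.Series(out, index=w.index, name=values.name)


def per_neuron(raw: ReceptorMatrix, neuron_density: pd.Series,
               protein_fraction: float = PROTEIN_FRACTION) -> ReceptorMatrix:
    """Convert a raw (per mg protein) matrix to receptors per neuron.

    ``per_neuron[a, r] = raw[a, r] * protein_fraction * 1000 / neuron_density[a]``.
    """
    if raw.units != UNITS_RAW:
        raise ParameterError("per_neuron expects a matrix in fmol/mg_protein")
    dens = neuron_density.reindex(raw.values.index)
    bad = dens.index[~(dens > 0)]
    if len(bad):
        raise DataError(f"non-positive neuron density for areas: {list(map(str, bad[:5]))}")
    scale = protein_fraction * _MG_PER_G / dens.to_numpy(dtype=float)
    out = raw.values.mul(scale, axis=0)
    return ReceptorMatrix(out, UNITS_PER_NEURON)


def per_neuron_inverse(per_neuron_matrix: ReceptorMatrix, neuron_density: pd.Series,
                       protein_fraction: float = PROTEIN_FRACTION) -> ReceptorMatrix:
    """Exact inverse of :func:`per_neuron` (used by the synthetic generator)."""
    if per_neuron_matrix.units != UNITS_PER_NEURON:
        raise ParameterError("expects a matrix in fmol/neuron")
    dens = neuron_density.reindex(per_neuron_matrix.values.index).to_numpy(dtype=float)
    out = per_neuron_matrix.values.mul(dens / (protein_fraction * _MG_PER_G), axis=0)
    return ReceptorMatrix(out, UNITS_RAW)


def paint_to_vertices(values: pd.Series, cortex) -> np.ndarray:
    """Paint a per-area map onto vertices (piecewise constant)."""
    out = np.full(cortex.n_vertices, np.nan)
    v = values.reindex(cortex.area_ids)
    for aid, idx in cortex.area_vertices.items():
        out[idx] = v.loc[aid]
    return out


def network_table(cortex, exclusion_threshold: float = 0.5) -> tuple[ParcelOverlap, pd.Series]:
    """Fractional overlap of every area with the 7 cognitive networks.

    Returns the overlap table and a boolean per-area exclusion flag, set
    when the limbic fraction exceeds ``exclusion_threshold`` (limbic
    areas are excluded downstream for lack of usable data).
    """
    if cortex.network_labels is None:
        raise DataError("cortex carries no network labels")
    net_ids = list(range(len(NETWORK_NAMES)))
    ov = compute_overlap(cortex, cortex.parcel_labels, cortex.network_labels,
                         source_ids=list(range(cortex.n_areas)), target_ids=net_ids)
    ov.weights.index = cortex.area_ids
    ov.weights.columns = list(NETWORK_NAMES)
    limbic = ov.weights[LIMBIC_NETWORK].fillna(0.0)
    excluded = limbic > exclusion_threshold
    excluded.name = "limbic_excluded"
    return ov, excluded
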