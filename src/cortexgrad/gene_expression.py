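"""Microarray-to-parcel mapping of gene expression.

Implements the standard sequence for turning donor-structured cortical
microarray samples into an areas x genes expression matrix:

1. drop probes without a valid Entrez id;
2. assign samples to mesh vertices (drop samples > 2 mm from the mesh,
   resolve collisions to the nearest unoccupied vertex);
3. z-score probe intensities across probes, within each sample;
4. drop samples with exceptionally low inter-areal similarity
   (below median - 3 scaled-MAD of their donor's similarity);
5. drop probes without above-threshold (present-call) expression in at
   least 40% of sampled areas;
6. scaled-robust-sigmoid normalize each probe within donor;
7. per area and probe, average present-call samples in the area, or —
   if none — average the nearest present-call sample per vertex
   (nearest-significant-sample fallback, provenance-tracked);
8. pick one representative probe per gene (2 probes: higher across-area
   variance; >= 3 probes: highest mean correlation with the others).

"Significant expression" is modeled by the present/absent call matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSet",
    "AreaExpression",
    "filter_probes_entrez",
    "assign_samples",
    "zscore_within_samples",
    "filter_low_similarity_samples",
    "filter_probes_expression",
    "srs_normalize",
    "area_expression",
    "representative_probe",
    "run_gene_pipeline",
]

MAX_SAMPLE_DIST_MM = 2.0
PROBE_AREA_FRACTION = 0.40
SIMILARITY_MAD_FACTOR = 3.0
_MAD_SCALE = 1.4826  # scaled MAD: consistent with SD under normality


@dataclass
class SampleSet:
    """Donor-structured microarray-like samples.

    ``samples``: DataFrame indexed by sample id with columns donor, x,
    y, z (mm).  ``probes``: DataFrame indexed by probe id with columns
    gene and entrez_valid.  ``intensity`` and ``calls``: samples x
    probes matrices (log2-like intensities; boolean present/absent).
    """

    samples: pd.DataFrame
    probes: pd.DataFrame
    intensity: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.intensity.index.equals(self.samples.index)
                and self.calls.index.equals(self.samples.index)):
            raise DataError("intensity/call rows must match sample ids")
        if not (self.intensity.columns.equals(self.probes.index)
                and self.calls.columns.equals(self.probes.index)):
            raise DataError("intensity/call columns must match probe ids")

    def subset(self, sample_ids=None, probe_ids=None) -> "SampleSet":
        s = self.samples if sample_ids is None else self.samples.loc[sample_ids]
        p = self.probes if probe_ids is None else self.probes.loc[probe_ids]
        return SampleSet(
            samples=s,
            probes=p,
            intensity=self.intensity.loc[s.index, p.index],
            calls=self.calls.loc[s.index, p.index],
        )


@dataclass
class AreaExpression:
    """Areas x genes matrix with per-cell provenance and chosen probes.

    ``provenance`` holds ``"direct"`` (present-call samples inside the
    area), ``"nearest-fallback"`` (per-vertex nearest significant
    sample) or ``"missing"``.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    chosen_probes: dict = field(default_factory=dict)


def filter_probes_entrez(sset: SampleSet) -> SampleSet:
    """Remove probes lacking a valid Entrez id."""
    keep = sset.probes.index[sset.probes["entrez_valid"].astype(bool)]
    n_drop = sset.probes.shape[0] - len(keep)
    if len(keep) == 0:
        raise DataError("all probes removed by Entrez filter")
    if n_drop:
        logger.info("entrez filter: removed %d probes", n_drop)
    return sset.subset(probe_ids=keep)


def assign_samples(sset: SampleSet, cortex, max_dist: float = MAX_SAMPLE_DIST_MM
                   ) -> pd.DataFrame:
    """Assign samples to mesh vertices; drop samples > ``max_dist`` away.

    Samples are processed in stable (donor id, sample id) order; when
    two samples claim the same vertex the later one moves to its
    nearest unoccupied vertex.  Returns a DataFrame indexed by retained
    sample id with columns ``vertex``, ``area`` and ``dist``.
    """
    coords = sset.samples[["x", "y", "z"]].to_numpy(dtype=float)
    if coords.shape[0] > cortex.n_vertices:
        raise DataError("more samples than mesh vertices")
    tree = cKDTree(cortex.vertices)
    d0, _ = tree.query(coords)
    keep = d0 <= max_dist
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("assign_samples: dropped %d samples > %g mm from mesh",
                    n_drop, max_dist)
    order = sset.samples.loc[keep].sort_values("donor", kind="stable").index
    occupied: set[int] = set()
    rows = {}
    k_query = 8
    for sid in order:
        xyz = sset.samples.loc[sid, ["x", "y", "z"]].to_numpy(dtype=float)
        k = k_query
        while True:
            dists, idxs = tree.query(xyz, k=min(k, cortex.n_vertices))
            dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
            free = [(dd, vv) for dd, vv in zip(dists, idxs) if vv not in occupied]
            if free:
                dd, vv = free[0]
                break
            if k >= cortex.n_vertices:
                raise DataError("no unoccupied vertex available")
            k *= 4
        occupied.add(int(vv))
        rows[sid] = {"vertex": int(vv),
                     "area": cortex.area_ids[cortex.parcel_labels[int(vv)]],
                     "dist": float(dd)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.reindex([s for s in sset.samples.index if s in rows])


def zscore_within_samples(sset: SampleSet) -> SampleSet:
    """Standardize each sample's probe vector to mean 0, SD 1 (n-1)."""
    X = sset.intensity
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 probes to z-score within samples")
    sd = X.std(axis=1, ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0][:5])
        raise DataError(f"constant probe vector for sample(s): {bad}")
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    return SampleSet(sset.samples, sset.probes, Z, sset.calls)


def filter_low_similarity_samples(sset: SampleSet, *, mad_factor: float = SIMILARITY_MAD_FACTOR,
                                  enabled: bool = True) -> SampleSet:
    """Drop samples with exceptionally low within-donor similarity.

    A sample's similarity is the Pearson correlation of its probe vector
    with the mean vector of all other samples from the same donor; a
    sample is dropped when its similarity falls below
    median - ``mad_factor`` x scaled MAD of its donor's similarity
    distribution.  Donors with fewer than 5 samples are skipped.
    """
    if not enabled:
        return sset
    keep: list = []
    for donor, grp in sset.samples.groupby("donor", sort=False):
        ids = list(grp.index)
        if len(ids) < 5:
            logger.warning("similarity filter: donor %s has %d samples; skipped",
                           donor, len(ids))
            keep.extend(ids)
            continue
        X = sset.intensity.loc[ids].to_numpy(dtype=float)
        total = X.sum(axis=0)
        sims = np.empty(len(ids))
        for i in range(len(ids)):
            other_mean = (total - X[i]) / (len(ids) - 1)
            a = X[i] - X[i].mean()
            b = other_mean - other_mean.mean()
            den = np.linalg.norm(a) * np.linalg.norm(b)
            sims[i] = a @ b / den if den > 0 else 0.0
        med = np.median(sims)
        mad = _MAD_SCALE * np.median(np.abs(sims - med))
        cut = med - mad_factor * mad
        ok = sims >= cut
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("similarity filter: donor %s, removed %d samples", donor, n_drop)
        keep.extend([sid for sid, o in zip(ids, ok) if o])
    keep = [s for s in sset.samples.index if s in set(keep)]
    return sset.subset(sample_ids=keep)


def filter_probes_expression(sset: SampleSet, assignment: pd.DataFrame,
                             fraction: float = PROBE_AREA_FRACTION) -> SampleSet:
    """Keep probes with a present call in >= ``fraction`` of sampled areas.

    A probe is 'above threshold' in an area when at least one sample
    assigned to that area has a present call for it; the denominator is
    the number of areas containing at least one assigned sample.  The
    boundary is inclusive: exactly 40% of areas keeps the probe.
    """
    ids = [s for s in sset.samples.index if s in assignment.index]
    area_of = assignment.loc[ids, "area"]
    areas = sorted(set(area_of))
    if not areas:
        raise DataError("no assigned samples")
    calls = sset.calls.loc[ids]
    present_areas = pd.Series(0, index=sset.probes.index, dtype=int)
    for _, grp in calls.groupby(area_of.to_numpy()):
        present_areas += grp.any(axis=0).astype(int)
    frac = present_areas / len(areas)
    keep = sset.probes.index[frac >= fraction]
    logger.info("expression filter: kept %d of %d probes (>= %.0f%% of %d areas)",
                len(keep), sset.probes.shape[0], 100 * fraction, len(areas))
    return sset.subset(probe_ids=keep)


def srs_normalize(values) -> np.ndarray:
    """Scaled robust sigmoid: outlier-robust normalization to [0, 1].

    y = 1 / (1 + exp(-(x - median) / (IQR / 1.35))), then min-max
    rescaled to [0, 1].  Invariant under positive affine transforms of
    the input; monotone; requires >= 3 finite values and nonzero IQR.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if int(finite.sum()) < 3:
        raise DataError("srs_normalize needs at least 3 finite values")
    med = np.median(x[finite])
    q75, q25 = np.percentile(x[finite], [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise DataError("zero IQR: scaled robust sigmoid undefined")
    y = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    yf = y[finite]
    span = yf.max() - yf.min()
    return (y - yf.min()) / span


def area_expression(sset: SampleSet, assignment: pd.DataFrame, probe: str,
                    cortex) -> tuple[pd.Series, pd.Series]:
    """Per-area expression of one probe with provenance.

    Areas holding >= 1 present-call sample get the mean of those
    samples' values ('direct'); otherwise each of the area's vertices
    contributes its nearest present-call sample anywhere on the mesh
    (duplicates allowed) and the area gets their average
    ('nearest-fallback').  With no present-call sample anywhere the
    cells are missing.
    """
    ids = [s for s in sset.samples.index if s in assignment.index]
    vals = sset.intensity.loc[ids, probe]
    present = sset.calls.loc[ids, probe].astype(bool)
    area_of = assignment.loc[ids, "area"]
    sig_ids = [s for s in ids if present.loc[s]]

    values = pd.Series(np.nan, index=cortex.area_ids, dtype=float)
    prov = pd.Series("missing", index=cortex.area_ids, dtype=object)
    direct_areas = set()
    if sig_ids:
        sig_area = area_of.loc[sig_ids]
        for area, grp in vals.loc[sig_ids].groupby(sig_area.to_numpy()):
            values.loc[area] = float(grp.mean())
            prov.loc[area] = "direct"
            direct_areas.add(area)
        sig_pos = cortex.vertices[assignment.loc[sig_ids, "vertex"].to_numpy(dtype=int)]
        tree = cKDTree(sig_pos)
        sig_vals = vals.loc[sig_ids].to_numpy(dtype=float)
        for aid, vidx in cortex.area_vertices.items():
            if aid in direct_areas:
                continue
            _, nearest = tree.query(cortex.vertices[vidx])
            values.loc[aid] = float(sig_vals[np.atleast_1d(nearest)].mean())
            prov.loc[aid] = "nearest-fallback"
    return values, prov


def representative_probe(area_values: pd.DataFrame) -> str:
    """Choose the representative probe of a gene from its area profiles.

    ``area_values`` is areas x probes (1-4 columns).  One probe wins by
    default; two probes: the one with the higher across-area variance;
    three or more: the one with the highest mean Pearson correlation of
    its area profile with the other probes.  Ties break by probe id
    order; if correlations are undefined (constant profiles) the
    variance rule is used with a warning.
    """
    probes = list(area_values.columns)
    if not (1 <= len(probes) <= 4):
        raise ParameterError("genes own 1-4 probes")
    if len(probes) == 1:
        return probes[0]
    X = area_values.dropna()
    if len(probes) == 2:
        var = X.var(ddof=1)
        return str(var.idxmax())
    sd = X.std(ddof=1)
    if (sd <= 0).any():
        logger.warning("representative_probe: constant profile; falling back to variance rule")
        return str(X.var(ddof=1).idxmax())
    corr = X.corr()
    mean_corr = (corr.sum(axis=1) - 1.0) / (len(probes) - 1)
    best = mean_corr.max()
    winners = [p for p in probes if mean_corr.loc[p] == best]
    return winners[0]


def run_gene_pipeline(sset: SampleSet, cortex, *, max_dist: float = MAX_SAMPLE_DIST_MM,
                      probe_fraction: float = PROBE_AREA_FRACTION,
                      similarity_filter: bool = True) -> AreaExpression:
    """Run the full microarray-to-parcel pipeline in its fixed order."""
    logger.info("gene pipeline: %d samples, %d probes", *sset.intensity.shape)
    sset = filter_probes_entrez(sset)
    assignment = assign_samples(sset, cortex, max_dist)
    sset = sset.subset(sample_ids=list(assignment.index))
    sset = zscore_within_samples(sset)
    sset = filter_low_similarity_samples(sset, enabled=similarity_filter)
    assignment = assignment.loc[sset.samples.index]
    sset = filter_probes_expression(sset, assignment, probe_fraction)

    # scaled robust sigmoid within donor, per probe, across samples
    norm = sset.intensity.copy()
    for _, grp in sset.samples.groupby("donor", sort=False):
        block = norm.loc[grp.index]
        for probe in block.columns:
            norm.loc[grp.index, probe] = srs_normalize(block[probe].to_numpy())
    sset = SampleSet(sset.samples, sset.probes, norm, sset.calls)

    probe_values = {}
    probe_prov = {}
    for probe in sset.probes.index:
        v, pr = area_expression(sset, assignment, probe, cortex)
        probe_values[probe] = v
        probe_prov[probe] = pr
    probe_values = pd.DataFrame(probe_values)
    probe_prov = pd.DataFrame(probe_prov)

    chosen = {}
    gene_values = {}
    gene_prov = {}
    for gene, grp in sset.probes.groupby("gene", sort=False):
        probes = list(grp.index)
        best = representative_probe(probe_values[probes])
        chosen[gene] = best
        gene_values[gene] = probe_values[best]
        gene_prov[gene] = probe_prov[best]
    return AreaExpression(
        values=pd.DataFrame(gene_values),
        provenance=pd.DataFrame(gene_prov),
        chosen_probes=chosen,
    )
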