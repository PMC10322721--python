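"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of the real study data — a cortical
surface parcellated into contiguous areas, an areas x receptors density
matrix whose dominant gradient has all-positive loadings and whose second
gradient is driven by a single receptor (the serotonin 5-HT1A slot), a
neuron-density map spanning a factor of ~5, spatially autocorrelated
parcel maps, 7-network vertex labels, functional activation z-maps and
donor-structured microarray-like sample sets — so each analysis stage can
be tested by parameter recovery against the planted truth, with no
downloaded data.

All generators are pure functions of their seed and parameters; sub-stage
randomness is derived from the seed through :mod:`cortexgrad.seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from . import density_maps as dm
from .density_maps import ReceptorMatrix, UNITS_PER_NEURON
from .exceptions import DataError, NumericalError, ParameterError
from .seeds import stage_rng

__all__ = [
    "ToyCortex",
    "PlantedGroundTruth",
    "generate_toy_cortex",
    "make_ground_truth",
    "generate_receptor_matrix",
    "generate_smooth_map",
    "generate_sample_set",
    "generate_functional_map",
    "planted_gene_maps",
]

#: Minimum vertices required per requested area.
MIN_VERTICES_PER_AREA = 20


@dataclass(frozen=True)
class ToyCortex:
    """A closed toy cortical surface with parcel and network labels.

    Fields
    ------
    vertices : (V, 3) float, mm
    triangles : (T, 3) int vertex triples
    parcel_labels : (V,) int in [0, A), every vertex assigned
    network_labels : (V,) int in [0, 7) or -1 for unassigned
    vertex_areas : (V,) float, mm^2 (one third of adjacent triangle area)
    parcel_centroids : (A, 3) float, mm
    area_ids : area id strings, position = label value
    """

    vertices: np.ndarray
    triangles: np.ndarray
    parcel_labels: np.ndarray
    network_labels: np.ndarray | None
    vertex_areas: np.ndarray
    parcel_centroids: np.ndarray
    area_ids: tuple[str, ...]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def area_vertices(self) -> dict[str, np.ndarray]:
        """Mapping area id -> vertex index array (computed on demand)."""
        out = {}
        for k, aid in enumerate(self.area_ids):
            out[aid] = np.nonzero(self.parcel_labels == k)[0]
        return out

    def validate(self) -> None:
        counts = np.bincount(self.parcel_labels, minlength=self.n_areas)
        if (counts < 3).any():
            raise DataError("every area must own at least 3 vertices")
        lo = self.vertices.min(axis=0) - 1e-9
        hi = self.vertices.max(axis=0) + 1e-9
        if ((self.parcel_centroids < lo) | (self.parcel_centroids > hi)).any():
            raise DataError("centroid outside mesh bounding box")


@dataclass(frozen=True)
class PlantedGroundTruth:
    """Planted gradients and neuron density underlying a synthetic matrix.

    ``gradient_scores`` (A x K) and ``loadings`` (R x K) define the
    noiseless z-space matrix ``scores @ loadings.T``; component-1
    loadings are all strictly positive (a shared total-density gradient)
    and component 2 is dominated by one designated receptor, emulating
    the serotonin-driven secondary gradient.  ``neuron_density`` spans a
    max/min ratio of 5, as neuron counts do across cortex.
    """

    gradient_scores: np.ndarray
    loadings: np.ndarray
    noise_sd: float
    neuron_density: pd.Series
    seed: int
    dominant_receptor: int = 9  # index of the 5-HT1A slot in canonical order
    receptor_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if (self.loadings[:, 0] <= 0).any():
            raise DataError("component-1 loadings must all be strictly positive")
        if self.loadings.shape[1] >= 2:
            l2 = np.abs(self.loadings[:, 1])
            others = np.delete(l2, self.dominant_receptor)
            if others.size and l2[self.dominant_receptor] < 3 * others.max():
                raise DataError("component-2 must be dominated by the designated receptor")
        d = self.neuron_density.to_numpy(dtype=float)
        ratio = d.max() / d.min()
        if not (4.0 <= ratio <= 6.0):
            raise DataError(f"neuron density max/min ratio {ratio:.2f} not ~5")


# ---------------------------------------------------------------------------
# mesh construction


def _grid_mesh(n_side: int, extent: float) -> tuple[np.ndarray, np.ndarray]:
    """Flat triangulated square grid (fast alternative to the sphere)."""
    xs = np.linspace(0.0, extent, n_side)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n_side * n_side)])
    tris = []
    for i in range(n_side - 1):
        for j in range(n_side - 1):
            a = i * n_side + j
            b = a + 1
            c = a + n_side
            d = c + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return verts, np.asarray(tris, dtype=int)


def _vertex_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p0 = vertices[triangles[:, 0]]
    p1 = vertices[triangles[:, 1]]
    p2 = vertices[triangles[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    out = np.zeros(vertices.shape[0])
    for k in range(3):
        np.add.at(out, triangles[:, k], tri_area / 3.0)
    return out


def _edge_graph(vertices: np.ndarray, triangles: np.ndarray):
    edges = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    n = vertices.shape[0]
    g = coo_matrix((np.concatenate([lengths, lengths]),
                    (np.concatenate([edges[:, 0], edges[:, 1]]),
                     np.concatenate([edges[:, 1], edges[:, 0]]))), shape=(n, n))
    return g.tocsr()


def _farthest_point_seeds(vertices: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point sampling of k well-separated seed vertices."""
    seeds = [int(rng.integers(vertices.shape[0]))]
    d = np.linalg.norm(vertices - vertices[seeds[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(vertices - vertices[nxt], axis=1))
    return np.asarray(seeds, dtype=int)


def _voronoi_labels(graph, vertices: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Geodesic Voronoi labeling: each vertex joins its nearest seed, so
    parcels are connected patches."""
    dist = dijkstra(graph, directed=False, indices=seeds)
    return np.argmin(dist, axis=0).astype(int)


def generate_toy_cortex(n_areas: int, mesh_resolution: int, seed: int, *,
                        mesh: str = "sphere", radius: float = 30.0,
                        n_networks: int = 7) -> ToyCortex:
    """Build a parcellated toy cortex.

    Parameters
    ----------
    n_areas
        Number of parcels to grow (>= 8).
    mesh_resolution
        Icosphere subdivision level for ``mesh="sphere"`` (vertices =
        10 * 4**level + 2), or grid side length for ``mesh="grid"``.
    seed
        Master seed; parcel and network seed vertices derive from it.
    mesh
        ``"sphere"`` (closed surface, default) or ``"grid"`` (fast tests).
    radius
        Sphere radius in mm; a 30 mm sphere has an area comparable to a
        macaque hemisphere.
    """
    if n_areas < 8:
        raise ParameterError("n_areas must be >= 8")
    if mesh == "sphere":
        m = trimesh.creation.icosphere(subdivisions=int(mesh_resolution), radius=radius)
        vertices = np.asarray(m.vertices, dtype=float)
        triangles = np.asarray(m.faces, dtype=int)
    elif mesh == "grid":
        vertices, triangles = _grid_mesh(int(mesh_resolution), extent=2 * radius)
    else:
        raise ParameterError(f"unknown mesh kind {mesh!r}")
    if vertices.shape[0] < MIN_VERTICES_PER_AREA * n_areas:
        raise ParameterError(
            f"resolution yields {vertices.shape[0]} vertices; "
            f"{MIN_VERTICES_PER_AREA * n_areas} needed for {n_areas} areas")

    graph = _edge_graph(vertices, triangles)
    rng = stage_rng(seed, "toy-cortex")
    parcel_seeds = _farthest_point_seeds(vertices, n_areas, rng)
    labels = _voronoi_labels(graph, vertices, parcel_seeds)
    net_seeds = _farthest_point_seeds(vertices, n_networks, rng)
    networks = _voronoi_labels(graph, vertices, net_seeds)

    areas = _vertex_areas(vertices, triangles)
    centroids = np.vstack([vertices[labels == k].mean(axis=0) for k in range(n_areas)])
    cortex = ToyCortex(
        vertices=vertices,
        triangles=triangles,
        parcel_labels=labels,
        network_labels=networks,
        vertex_areas=areas,
        parcel_centroids=centroids,
        area_ids=tuple(f"A{k:03d}" for k in range(n_areas)),
    )
    cortex.validate()
    return cortex


# ---------------------------------------------------------------------------
# Gaussian random fields and planted gradients


def _grf_at_centroids(cortex: ToyCortex, correlation_length: float,
                      rng: np.random.Generator, n_fields: int = 1) -> np.ndarray:
    """Sample Gaussian random fields with squared-exponential covariance
    at the parcel centroids.  Returns (A, n_fields)."""
    if correlation_length <= 0:
        raise ParameterError("correlation_length must be positive")
    d = cdist(cortex.parcel_centroids, cortex.parcel_centroids)
    cov = np.exp(-0.5 * (d / correlation_length) ** 2)
    jitter = 1e-10
    for _ in range(8):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        raise NumericalError("covariance not positive definite after jitter")
    return chol @ rng.standard_normal((cov.shape[0], n_fields))


def generate_smooth_map(cortex: ToyCortex, correlation_length: float, seed: int) -> pd.Series:
    """A spatially autocorrelated per-area scalar map (unit-variance GRF)."""
    rng = stage_rng(seed, "smooth-map")
    vals = _grf_at_centroids(cortex, correlation_length, rng, 1)[:, 0]
    return pd.Series(vals, index=cortex.area_ids, name="value")


def make_ground_truth(cortex: ToyCortex, n_receptors: int = 14, n_components: int = 2,
                      noise_sd: float = 0.2, seed: int = 0, *,
                      component_scales: tuple[float, ...] | None = None,
                      dominant_receptor: int = 9,
                      density_range: tuple[float, float] = (2e7, 1e8),
                      density_gradient_coupling: float = 0.3) -> PlantedGroundTruth:
    """Plant smooth gradient scores, loadings and a neuron-density map.

    Component scores are smooth fields over the cortex (correlation
    length half the mesh radius for component 1, a third for component
    2), standardized and mutually orthogonalized, then scaled by
    ``component_scales`` (default (3.0, 1.2, 0.6, ...)) so the shared
    all-positive component dominates the variance, as in real receptor
    data.  Neuron density is an affine map onto ``density_range``
    (default 2e7-1e8 neurons/g, a 5-fold span) of a smooth field that
    anticorrelates with component 1 at strength
    ``density_gradient_coupling`` — early sensory cortex packs many
    neurons each expressing few receptors, so neuron density runs
    against the receptors-per-neuron gradient.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    A = cortex.n_areas
    if n_components > min(A, n_receptors):
        raise ParameterError("more planted components than matrix rank allows")
    rng = stage_rng(seed, "ground-truth")
    extent = np.ptp(cortex.vertices, axis=0).max() / 2
    if component_scales is None:
        component_scales = tuple(3.0 * (0.4 ** k) for k in range(n_components))
        if n_components >= 2:
            component_scales = (3.0, 1.2) + component_scales[2:]

    scores = np.empty((A, n_components))
    for k in range(n_components):
        ell = extent / (2 + k)
        f = _grf_at_centroids(cortex, ell, rng, 1)[:, 0]
        f = (f - f.mean()) / f.std(ddof=0)
        for j in range(k):  # orthogonalize against earlier components
            f = f - (f @ scores[:, j]) / (scores[:, j] @ scores[:, j]) * scores[:, j]
        f = (f - f.mean()) / f.std(ddof=0)
        scores[:, k] = f * component_scales[k]

    loadings = np.empty((n_receptors, n_components))
    l1 = np.abs(rng.normal(1.0, 0.15, n_receptors)) + 0.2
    loadings[:, 0] = l1 / np.linalg.norm(l1)
    if n_components >= 2:
        l2 = rng.normal(0.0, 0.05, n_receptors)
        l2 = np.clip(l2, -0.15, 0.15)
        l2[dominant_receptor] = 1.0
        loadings[:, 1] = l2 / np.linalg.norm(l2)
    for k in range(2, n_components):
        lk = rng.normal(0.0, 1.0, n_receptors)
        loadings[:, k] = lk / np.linalg.norm(lk)

    w = float(density_gradient_coupling)
    if not (0 <= w < 1):
        raise ParameterError("density_gradient_coupling must lie in [0, 1)")
    ind = _grf_at_centroids(cortex, extent / 2, rng, 1)[:, 0]
    ind = (ind - ind.mean()) / ind.std(ddof=0)
    s1_unit = scores[:, 0] / component_scales[0]
    dens_field = -w * s1_unit + np.sqrt(1 - w**2) * ind
    # rank-uniform squashed toward the center: most areas share a narrow
    # density band while a few extremes (the primary-sensory end) reach the
    # 5-fold cap, mirroring the clustered-with-outliers distribution of
    # cortical neuron counts
    u = (np.argsort(np.argsort(dens_field)) + 0.5) / A
    v = 0.5 + 16.0 * (u - 0.5) ** 5
    v = (v - v.min()) / (v.max() - v.min())
    lo, hi = density_range
    dens = lo + (hi - lo) * v
    neuron_density = pd.Series(dens, index=cortex.area_ids, name="neurons_per_g")

    names = dm.canonical_receptors()
    if n_receptors != len(names):
        names = [f"R{k:02d}" for k in range(n_receptors)]
    return PlantedGroundTruth(
        gradient_scores=scores,
        loadings=loadings,
        noise_sd=float(noise_sd),
        neuron_density=neuron_density,
        seed=int(seed),
        dominant_receptor=dominant_receptor,
        receptor_names=tuple(names),
    )


def generate_receptor_matrix(cortex: ToyCortex, truth: PlantedGroundTruth,
                             n_receptors: int = 14, *,
                             protein_fraction: float = dm.PROTEIN_FRACTION,
                             ) -> tuple[ReceptorMatrix, ReceptorMatrix]:
    """Synthesize the per-neuron and raw receptor density matrices.

    The z-space matrix is ``scores @ loadings.T`` plus i.i.d. Gaussian
    noise of SD ``truth.noise_sd``; it is back-transformed to per-neuron
    units by per-receptor location/scale pairs, then to raw per-mg-protein
    units by the exact inverse of the per-neuron normalization, so
    normalizing the raw output reproduces the per-neuron output to
    round-off.
    """
    if n_receptors != truth.loadings.shape[0]:
        raise ParameterError("n_receptors does not match planted loadings")
    rng = stage_rng(truth.seed, "receptor-matrix")
    z = truth.gradient_scores @ truth.loadings.T
    if truth.noise_sd > 0:
        z = z + rng.normal(0.0, truth.noise_sd, z.shape)
    # per-receptor location/scale: every column spans a severalfold range
    # along the planted gradient (as real per-neuron densities do) while
    # staying strictly positive; extreme z excursions are clipped just
    # inside the positivity bound
    mu = rng.uniform(5e-4, 3e-3, n_receptors)
    sigma = z.std(axis=0, ddof=0)
    sigma[sigma == 0] = 1.0
    sd = mu / (4.5 * sigma)
    z = np.clip(z, -4.4 * sigma[None, :], 4.4 * sigma[None, :])
    per = mu[None, :] + sd[None, :] * z
    if (per <= 0).any():
        raise NumericalError("synthetic per-neuron densities not all positive")
    names = list(truth.receptor_names) or [f"R{k:02d}" for k in range(n_receptors)]
    per_df = pd.DataFrame(per, index=cortex.area_ids, columns=names)
    per_matrix = ReceptorMatrix(per_df, UNITS_PER_NEURON)
    raw_matrix = dm.per_neuron_inverse(per_matrix, truth.neuron_density, protein_fraction)
    return per_matrix, raw_matrix


# ---------------------------------------------------------------------------
# functional activation maps


def generate_functional_map(cortex: ToyCortex, gradient_map: pd.Series,
                            target_percentile_band: tuple[float, float],
                            z_peak: float = 6.0, seed: int = 0, *,
                            background_sd: float = 0.8) -> np.ndarray:
    """A vertex z-map activating a percentile band of a gradient map.

    Vertices whose gradient percentile falls inside ``[lo, hi)`` receive
    z values near ``z_peak``; the rest get sub-threshold background
    noise.  The planted embedding position is the band midpoint.
    """
    lo, hi = target_percentile_band
    if not (0 <= lo < hi <= 100):
        raise ParameterError("percentile band must satisfy 0 <= lo < hi <= 100")
    rng = stage_rng(seed, "functional-map")
    g = dm.paint_to_vertices(gradient_map, cortex)
    order = np.argsort(g, kind="stable")
    pct = np.empty(cortex.n_vertices)
    pct[order] = (np.arange(cortex.n_vertices) + 0.5) / cortex.n_vertices * 100
    z = rng.normal(0.0, background_sd, cortex.n_vertices)
    in_band = (pct >= lo) & (pct < hi)
    z[in_band] = z_peak + rng.normal(0.0, 0.3, int(in_band.sum()))
    return z


# ---------------------------------------------------------------------------
# microarray-like sample sets


def planted_gene_maps(cortex: ToyCortex, n_genes: int, correlation_length: float,
                      seed: int) -> pd.DataFrame:
    """Smooth per-area expression maps (areas x genes), one GRF per gene."""
    rng = stage_rng(seed, "gene-maps")
    fields = _grf_at_centroids(cortex, correlation_length, rng, n_genes)
    cols = [f"G{k:03d}" for k in range(n_genes)]
    return pd.DataFrame(fields, index=cortex.area_ids, columns=cols)


def generate_sample_set(cortex: ToyCortex, n_donors: int, n_samples_per_donor: int,
                        n_probes: int, n_genes: int, planted: pd.DataFrame,
                        call_rate: float = 0.9, coord_noise_sd: float = 0.5,
                        seed: int = 0, *, donor_sd: float = 0.5,
                        probe_sd: float = 0.5, intensity_noise_sd: float = 0.1,
                        entrez_invalid_fraction: float = 0.0):
    """Donor-structured microarray-like samples over the toy cortex.

    Each sample sits at a mesh vertex jittered by 3-D Gaussian noise of
    SD ``coord_noise_sd`` (so some samples exceed the 2 mm mesh-distance
    filter when the jitter is large).  Probe intensity = planted area
    value of the probe's gene + donor offset + probe offset + noise;
    present/absent calls are Bernoulli(``call_rate``).
    """
    from .gene_expression import SampleSet

    if n_genes > n_probes:
        raise ParameterError("every gene needs at least one probe")
    if n_probes > 4 * n_genes:
        raise ParameterError("at most 4 probes per gene")
    if not (0 <= call_rate <= 1):
        raise ParameterError("call_rate must lie in [0, 1]")
    rng = stage_rng(seed, "sample-set")

    genes = list(planted.columns)
    if len(genes) != n_genes:
        raise ParameterError("planted map column count != n_genes")
    # each gene owns 1..4 probes, totals matching n_probes
    gene_of_probe = list(range(n_genes))
    extra = n_probes - n_genes
    counts = np.ones(n_genes, dtype=int)
    while extra > 0:
        g = int(rng.integers(n_genes))
        if counts[g] < 4:
            counts[g] += 1
            gene_of_probe.append(g)
            extra -= 1
    probe_ids = [f"P{k:03d}" for k in range(n_probes)]
    probes = pd.DataFrame({
        "gene": [genes[g] for g in gene_of_probe],
        "entrez_valid": rng.random(n_probes) >= entrez_invalid_fraction,
    }, index=pd.Index(probe_ids, name="probe_id"))

    n_samples = n_donors * n_samples_per_donor
    donor_ids = np.repeat([f"D{d:02d}" for d in range(n_donors)], n_samples_per_donor)
    home_vertex = rng.integers(cortex.n_vertices, size=n_samples)
    coords = cortex.vertices[home_vertex] + rng.normal(0.0, coord_noise_sd, (n_samples, 3))
    sample_ids = [f"S{k:04d}" for k in range(n_samples)]
    samples = pd.DataFrame({
        "donor": donor_ids,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    }, index=pd.Index(sample_ids, name="sample_id"))

    donor_offset = rng.normal(0.0, donor_sd, n_donors)
    probe_offset = rng.normal(0.0, probe_sd, n_probes)
    area_of_sample = cortex.parcel_labels[home_vertex]
    base = planted.to_numpy()[area_of_sample][:, gene_of_probe]  # (n_samples, n_probes)
    donor_idx = np.repeat(np.arange(n_donors), n_samples_per_donor)
    intensity = (base + donor_offset[donor_idx][:, None] + probe_offset[None, :]
                 + rng.normal(0.0, intensity_noise_sd, (n_samples, n_probes)))
    calls = rng.random((n_samples, n_probes)) < call_rate
    return SampleSet(
        samples=samples,
        probes=probes,
        intensity=pd.DataFrame(intensity, index=samples.index, columns=probes.index),
        calls=pd.DataFrame(calls, index=samples.index, columns=probes.index),
    )
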