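"""End-to-end orchestration of the receptor-gradient pipeline.

A :class:`RunConfig` (round-trippable through YAML) drives a fully
deterministic run: synthesize inputs, normalize to per-neuron units,
compute gradients and the dependence table, build surrogate ensembles
and a spatially corrected correlation report, summarize networks, embed
functional maps and run the gene pipeline.  Every stage writes delimited
tables under the output directory and the run ends with a JSON manifest
listing per-file SHA-256 hashes, seeds and stage status.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autoradiography as ar  # noqa: F401  (re-exported for scripts)
from . import density_maps as dm
from . import embedding as emb
from . import gene_expression as gx
from . import gradients as gr
from . import spatial_stats as ss
from . import synthetic_data as syn
from .exceptions import ParameterError
from .io import sha256_file, write_json, write_table
from .seeds import stage_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report_correlations"]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "cortexgrad_run"
    seed: int = 0
    n_areas: int = 60
    mesh_resolution: int = 4
    n_receptors: int = 14
    noise_sd: float = 0.2
    n_surrogates: int = 1000
    n_bins: int = 20
    z_threshold: float = 3.1
    limbic_exclusion: float = 0.5
    max_sample_dist: float = 2.0
    probe_fraction: float = 0.40
    protein_fraction: float = 0.08
    n_donors: int = 6
    n_samples_per_donor: int = 100
    n_probes: int = 40
    n_genes: int = 20
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        return int(self.stage_seeds.get(stage, stage_seed(self.seed, stage)))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def report_correlations(pairs: dict[str, tuple[pd.Series, pd.Series]],
                        D: pd.DataFrame, n_surrogates: int, seed: int,
                        m: int | None = None) -> pd.DataFrame:
    """Spatially corrected correlation report for declared map pairs.

    ``pairs`` maps a label to (map1, map2); the surrogate ensemble is
    built on map1 of each pair (restricted to jointly non-missing
    areas).  Bonferroni m defaults to the number of declared pairs.
    Reports r, a Fisher-z 95% CI, the spatial p and the adjusted p.
    """
    m = len(pairs) if m is None else int(m)
    rows = {}
    for label, (a, b) in pairs.items():
        joint = a.notna() & b.reindex(a.index).notna()
        a2 = a[joint]
        b2 = b.reindex(a.index)[joint]
        ens = ss.make_surrogates(a2, D, n_surr=n_surrogates,
                                 seed=stage_seed(seed, f"surr:{label}"))
        r, p = ss.corrected_correlation(a2, b2, ens)
        n = int(joint.sum())
        zr = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        half = 1.96 / np.sqrt(max(n - 3, 1))
        rows[label] = {
            "r": r,
            "ci_low": float(np.tanh(zr - half)),
            "ci_high": float(np.tanh(zr + half)),
            "p_spatial": p,
            "n": n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["p_bonferroni"] = ss.bonferroni(out["p_spatial"].to_numpy(), m=m)
    out.attrs["bonferroni_m"] = m
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def done(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = sha256_file(p)

    # --- synthesize inputs -------------------------------------------------
    cortex = syn.generate_toy_cortex(config.n_areas, config.mesh_resolution,
                                     config.seed_for("cortex"))
    truth = syn.make_ground_truth(cortex, config.n_receptors, 2,
                                  config.noise_sd, config.seed_for("truth"))
    per, raw = syn.generate_receptor_matrix(cortex, truth, config.n_receptors,
                                            protein_fraction=config.protein_fraction)
    p1 = write_table(raw.values, out / "receptors_raw.tsv",
                     comment=f"units: {raw.units}")
    p2 = write_table(truth.neuron_density.to_frame(), out / "neuron_density.tsv",
                     comment="units: neurons per g")
    done("simulate", p1, p2)

    # --- per-neuron normalization -----------------------------------------
    per_neuron = dm.per_neuron(raw, truth.neuron_density, config.protein_fraction)
    p = write_table(per_neuron.values, out / "receptors_per_neuron.tsv",
                    comment=f"units: {per_neuron.units}")
    done("normalize", p)

    # --- gradients ---------------------------------------------------------
    X = gr.zscore_columns(per_neuron)
    res = gr.pca(X)
    p1 = write_table(res.Z, out / "pc_scores.tsv", comment="PC scores Z = U S")
    p2 = write_table(res.V, out / "loadings.tsv", comment="receptor loadings V")
    p3 = write_table(pd.Series(res.variance_fractions,
                               index=res.Z.columns, name="variance_fraction").to_frame(),
                     out / "variance_fractions.tsv")
    done("gradients", p1, p2, p3)

    # --- gradient dependence ----------------------------------------------
    dep = gr.dependence_table(X, n_pcs=min(5, res.n_components))
    p = write_table(dep.g, out / "gradient_dependence.tsv",
                    comment="g = 1 - rho^2 per PC x receptor")
    done("dependence", p)

    # --- spatially corrected correlations ---------------------------------
    D = ss.distance_matrix(cortex)
    comparison = syn.generate_smooth_map(cortex, 15.0, config.seed_for("comparison-map"))
    pairs = {
        "PC1~total_density": (res.Z["PC1"], gr.total_density(per_neuron)),
        "PC1~neuron_density": (res.Z["PC1"], truth.neuron_density),
        "PC1~comparison_map": (res.Z["PC1"], comparison),
    }
    report = report_correlations(pairs, D, config.n_surrogates,
                                 config.seed_for("surrogates"))
    p = write_table(report, out / "correlations.tsv",
                    comment=f"Bonferroni m = {report.attrs['bonferroni_m']}; "
                            f"n_surrogates = {config.n_surrogates}")
    done("correlate", p)

    # --- networks ----------------------------------------------------------
    net, excluded = dm.network_table(cortex)
    pc1_vertex = dm.paint_to_vertices(res.Z["PC1"], cortex)
    summary = emb.network_summary(pc1_vertex, cortex)
    p1 = write_table(net.weights, out / "network_overlap.tsv")
    p2 = write_table(summary[["mean", "n_vertices"]], out / "network_summary.tsv")
    done("networks", p1, p2)

    # --- functional embedding ----------------------------------------------
    fmaps = []
    for label, band in [("planted_low", (0.0, 20.0)), ("planted_mid", (40.0, 60.0)),
                        ("planted_high", (80.0, 100.0))]:
        z = syn.generate_functional_map(cortex, res.Z["PC1"], band, 6.0,
                                        config.seed_for(f"fmap:{label}"))
        fmaps.append(emb.FunctionalMap(z, label=label, threshold=config.z_threshold))
    pc2_vertex = dm.paint_to_vertices(res.Z["PC2"], cortex)
    placement = emb.place_in_receptor_space(fmaps, pc1_vertex, pc2_vertex,
                                            n_bins=config.n_bins)
    p = write_table(placement, out / "functional_embedding.tsv")
    done("embed", p)

    # --- gene pipeline ------------------------------------------------------
    gene_maps = syn.planted_gene_maps(cortex, config.n_genes, 15.0,
                                      config.seed_for("gene-maps"))
    sset = syn.generate_sample_set(cortex, config.n_donors, config.n_samples_per_donor,
                                   config.n_probes, config.n_genes, gene_maps,
                                   seed=config.seed_for("samples"))
    expr = gx.run_gene_pipeline(sset, cortex, max_dist=config.max_sample_dist,
                                probe_fraction=config.probe_fraction)
    p1 = write_table(expr.values, out / "gene_expression.tsv",
                     comment="scaled-robust-sigmoid normalized, [0, 1]")
    p2 = write_table(expr.provenance, out / "gene_provenance.tsv")
    done("genes", p1, p2)

    config.to_yaml(out / "config.yaml")
    manifest["seed"] = config.seed
    write_json(manifest, out / "manifest.json")
    return manifest
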