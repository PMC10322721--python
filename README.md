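# cortexgrad

Cortical neurotransmitter-receptor gradient analysis: a tested Python
re-implementation of the pipeline that turns quantitative receptor
autoradiography into cortical gradients and relates them to anatomy,
cognitive networks and gene expression.

## Who this is for

Neuroanatomists and neuroinformaticians working with parcellated
receptor-density data (areas × receptors tables in fmol mg⁻¹ protein),
neuron-density maps, surface atlases and microarray samples. The
package covers the full chain:

1. **Densitometry** — convert film standards to binding-site
   concentrations with `C_b = R/(E·B·W_b·S_a)·(K_D+L)/L`, fit a
   monotone calibration curve, linearize 8-bit autoradiographs, extract
   laminar profiles and per-area means with CoV quality control.
2. **Map algebra** — vertex-area-weighted parcel averaging,
   overlap-weighted resampling between parcellations, and per-neuron
   normalization (`raw × 0.08 × 1000 / neuron_density`).
3. **Gradients** — z-score receptor columns, take the SVD
   `X = U S Vᵀ`, report PC scores `Z = U S`, loadings and variance
   fractions, and quantify how much each gradient relies on each
   receptor with the leave-one-receptor-out dependence statistic
   `g = 1 − ρ²`.
4. **Spatial statistics** — variogram-matched surrogate maps and
   autocorrelation-corrected correlation p-values with Bonferroni
   adjustment.
5. **Embedding** — binarize activation z-maps at z > 3.1 and embed
   them along gradients by Dice overlap with 20 percentile bins;
   per-network gradient summaries; functional receptor fingerprints.
6. **Gene expression** — the microarray-to-parcel pipeline (Entrez and
   expression filters, sample assignment, within-sample z-scoring,
   scaled-robust-sigmoid normalization, nearest-significant-sample
   fallback, representative-probe selection).

Real receptor and microarray datasets are large external downloads, so
the package also ships a first-class synthetic-data module
(`cortexgrad.synthetic_data`) that generates every input with planted
ground truth — a parcellated spherical cortex, a receptor matrix with a
dominant all-positive gradient and a second gradient driven by one
receptor, a 5-fold neuron-density map, smooth comparison maps,
functional z-maps and donor-structured microarray samples — and every
stage is validated by recovering what was planted.

## Worked example

```python
import numpy as np
from cortexgrad import synthetic_data as syn, gradients as gr

cortex = syn.generate_toy_cortex(n_areas=60, mesh_resolution=4, seed=1)
truth = syn.make_ground_truth(cortex, noise_sd=0.2, seed=3)
per_neuron, raw = syn.generate_receptor_matrix(cortex, truth)

X = gr.zscore_columns(per_neuron)
res = gr.pca(X)
print("variance fractions:", np.round(res.variance_fractions[:5], 3))
print("corr(PC1, planted gradient 1): %.3f"
      % np.corrcoef(res.Z["PC1"], truth.gradient_scores[:, 0])[0, 1])
print("corr(PC1, total density): %.4f"
      % np.corrcoef(res.Z["PC1"], gr.total_density(per_neuron))[0, 1])

dep = gr.dependence_table(X, n_pcs=2)
print("PC2 depends most on:", dep.g.loc["PC2"].idxmax(),
      "g = %.3f" % dep.g.loc["PC2"].max())
print("PC1 max dependence: %.3f" % dep.g.loc["PC1"].max())
```

prints

```
variance fractions: [0.895 0.054 0.008 0.007 0.007]
corr(PC1, planted gradient 1): 0.998
corr(PC1, total density): 0.9996
PC2 depends most on: 5-HT1A g = 0.306
PC1 max dependence: 0.002
```

Read: the first principal component carries ~90% of the variance and is
the planted shared gradient (recovered at r = 0.998); it tracks total
receptor density per neuron almost perfectly. Removing any single
receptor barely perturbs PC1 (max g = 0.002 — the principal gradient is
a consensus across receptors), while PC2 depends most on the 5-HT1A
receptor, exactly the receptor planted as the driver of the second
gradient.

A full end-to-end run (synthesis → normalization → gradients →
dependence → corrected correlations → networks → embedding → genes),
with every intermediate written as a TSV and a manifest of file hashes:

```bash
cortexgrad run-all --seed 7 --out runs/demo
```

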