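"""Microarray-to-parcel pipeline: filters, assignment, normalization,
area mapping and representative-probe selection."""

import numpy as np
import pandas as pd
import pytest

from cortexgrad import gene_expression as gx
from cortexgrad import synthetic_data as syn
from cortexgrad.exceptions import DataError, ParameterError
from conftest import make_sampleset


def tiny_sampleset(intensities, calls=None, donors=None, coords=None, genes=None):
    """Hand-built SampleSet for rule-level tests."""
    intensities = np.asarray(intensities, dtype=float)
    n_s, n_p = intensities.shape
    sids = [f"S{i}" for i in range(n_s)]
    pids = [f"P{j}" for j in range(n_p)]
    samples = pd.DataFrame({
        "donor": donors if donors is not None else ["D0"] * n_s,
        "x": coords[:, 0] if coords is not None else np.zeros(n_s),
        "y": coords[:, 1] if coords is not None else np.zeros(n_s),
        "z": coords[:, 2] if coords is not None else np.zeros(n_s),
    }, index=pd.Index(sids, name="sample_id"))
    probes = pd.DataFrame({
        "gene": genes if genes is not None else [f"G{j}" for j in range(n_p)],
        "entrez_valid": [True] * n_p,
    }, index=pd.Index(pids, name="probe_id"))
    calls = np.asarray(calls, dtype=bool) if calls is not None else np.ones((n_s, n_p), bool)
    return gx.SampleSet(samples, probes,
                        pd.DataFrame(intensities, index=sids, columns=pids),
                        pd.DataFrame(calls, index=sids, columns=pids))


class TestEntrezFilter:
    def test_all_valid_is_identity(self):
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(4, 6)))
        out = gx.filter_probes_entrez(s)
        assert list(out.probes.index) == list(s.probes.index)

    def test_counts(self):
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(4, 10)))
        s.probes.loc[["P1", "P4", "P7"], "entrez_valid"] = False
        out = gx.filter_probes_entrez(s)
        assert out.probes.shape[0] == 7
        assert out.intensity.shape[1] == 7

    def test_all_invalid_is_error(self):
        s = tiny_sampleset(np.zeros((3, 4)))
        s.probes["entrez_valid"] = False
        with pytest.raises(DataError):
            gx.filter_probes_entrez(s)


class TestAssignSamples:
    def test_distant_sample_dropped(self, cortex20):
        coords = cortex20.vertices[[0, 1]].copy()
        # push the second sample 2.5 mm off the mesh along its normal
        coords[1] = coords[1] * (1 + 2.5 / np.linalg.norm(coords[1]))
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(2, 4)), coords=coords)
        out = gx.assign_samples(s, cortex20)
        assert list(out.index) == ["S0"]

    def test_collision_moves_later_sample(self, cortex20):
        v = cortex20.vertices[10]
        coords = np.vstack([v + [0.01, 0, 0], v + [0.02, 0, 0]])
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(2, 4)), coords=coords)
        out = gx.assign_samples(s, cortex20)
        assert out.loc["S0", "vertex"] == 10
        assert out.loc["S1", "vertex"] != 10

    def test_zero_jitter_matches_bruteforce_nearest(self, cortex20):
        gm = syn.planted_gene_maps(cortex20, 5, 15.0, seed=5)
        sset = syn.generate_sample_set(cortex20, 2, 25, 10, 5, gm,
                                       coord_noise_sd=0.0, seed=5)
        out = gx.assign_samples(sset, cortex20)
        assert out["vertex"].is_unique
        assert len(out) == 50
        # uncollided samples sit exactly on their nearest vertex
        coords = sset.samples[["x", "y", "z"]].to_numpy()
        on_vertex = out["dist"] < 1e-9
        assert on_vertex.mean() > 0.8
        for sid in out.index[on_vertex]:
            xyz = sset.samples.loc[sid, ["x", "y", "z"]].to_numpy(float)
            d = np.linalg.norm(cortex20.vertices - xyz, axis=1)
            assert out.loc[sid, "vertex"] == int(np.argmin(d))


class TestZscoreWithinSamples:
    def test_symmetric_triple(self):
        s = tiny_sampleset([[1.0, 2.0, 3.0]])
        out = gx.zscore_within_samples(s)
        assert np.allclose(out.intensity.iloc[0], [-1, 0, 1])

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        s = tiny_sampleset(rng.normal(size=(6, 8)))
        out = gx.zscore_within_samples(s)
        assert np.allclose(out.intensity.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.intensity.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_sample_is_error(self):
        s = tiny_sampleset([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(DataError):
            gx.zscore_within_samples(s)


class TestSimilarityFilter:
    def test_identical_samples_all_kept(self):
        s = tiny_sampleset(np.tile([1.0, 2.0, 5.0, 3.0], (8, 1))
                           + np.random.default_rng(0).normal(0, 1e-6, (8, 4)))
        out = gx.filter_low_similarity_samples(s)
        assert out.samples.shape[0] == 8

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=20)
        X = base + rng.normal(0, 0.05, (50, 20))
        X[13] = rng.normal(size=20)  # incoherent sample
        s = tiny_sampleset(X)
        out = gx.filter_low_similarity_samples(s)
        assert "S13" not in out.samples.index
        assert out.samples.shape[0] >= 45

    def test_disabled_is_identity(self):
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(6, 4)))
        out = gx.filter_low_similarity_samples(s, enabled=False)
        assert out.samples.shape[0] == 6

    def test_small_donor_skipped_with_warning(self):
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(3, 4)))
        out = gx.filter_low_similarity_samples(s)
        assert out.samples.shape[0] == 3


class TestProbeExpressionFilter:
    def _set_with_area_calls(self, present_areas, n_areas=10):
        """One sample per area; probe P0 present exactly in the listed areas."""
        n_s = n_areas
        calls = np.zeros((n_s, 3), dtype=bool)
        calls[:, 1:] = True
        for a in present_areas:
            calls[a, 0] = True
        s = tiny_sampleset(np.random.default_rng(0).normal(size=(n_s, 3)), calls=calls)
        assignment = pd.DataFrame({
            "vertex": np.arange(n_s),
            "area": [f"A{a:03d}" for a in range(n_s)],
            "dist": 0.0,
        }, index=s.samples.index)
        return s, assignment

    def test_boundary_inclusive_at_40_percent(self):
        s, assign = self._set_with_area_calls([0, 1, 2, 3])
        out = gx.filter_probes_expression(s, assign, fraction=0.40)
        assert "P0" in out.probes.index

    def test_below_threshold_removed(self):
        s, assign = self._set_with_area_calls([0, 1, 2])
        out = gx.filter_probes_expression(s, assign, fraction=0.40)
        assert "P0" not in out.probes.index

    def test_matches_bruteforce_presence(self, cortex20):
        gm, sset = make_sampleset(cortex20, seed=7, call_rate=0.5)
        assign = gx.assign_samples(sset, cortex20)
        sset2 = sset.subset(sample_ids=list(assign.index))
        out = gx.filter_probes_expression(sset2, assign, fraction=0.40)
        areas = assign["area"]
        n_areas = areas.nunique()
        for p in sset2.probes.index:
            present = sset2.calls[p].groupby(areas.to_numpy()).any().sum()
            assert (p in out.probes.index) == (present / n_areas >= 0.40)


class TestSrsNormalize:
    def test_median_maps_to_half_before_rescale(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        raw_sigmoid = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
        assert raw_sigmoid[2] == pytest.approx(0.5)
        out = gx.srs_normalize(x)
        expect = (raw_sigmoid - raw_sigmoid.min()) / (raw_sigmoid.max() - raw_sigmoid.min())
        assert np.allclose(out, expect)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        assert np.allclose(gx.srs_normalize(x), gx.srs_normalize(3 * x + 7), atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        x = rng.normal(size=50)
        y = gx.srs_normalize(x)
        assert y.min() == 0.0 and y.max() == 1.0
        order = np.argsort(x)
        assert (np.diff(y[order]) >= 0).all()

    def test_zero_iqr_is_error(self):
        with pytest.raises(DataError):
            gx.srs_normalize([1.0, 1.0, 1.0, 1.0])


class TestAreaExpression:
    def test_direct_mean_of_present_samples(self, cortex20):
        v0 = cortex20.vertices[cortex20.parcel_labels == 0][:2]
        s = tiny_sampleset(np.array([[1.0, 9.0], [3.0, 9.0]]), coords=v0,
                           genes=["G0", "G1"])
        assign = gx.assign_samples(s, cortex20)
        vals, prov = gx.area_expression(s, assign, "P0", cortex20)
        a0 = cortex20.area_ids[0]
        assert vals.loc[a0] == pytest.approx(2.0)
        assert prov.loc[a0] == "direct"

    def test_fallback_uses_nearest_significant_sample(self, cortex20):
        v0 = cortex20.vertices[[0]]
        s = tiny_sampleset(np.array([[5.0, 1.0]]), coords=v0, genes=["G0", "G1"])
        assign = gx.assign_samples(s, cortex20)
        vals, prov = gx.area_expression(s, assign, "P0", cortex20)
        home = assign.loc["S0", "area"]
        assert prov.loc[home] == "direct"
        others = [a for a in cortex20.area_ids if a != home]
        assert (prov.loc[others] == "nearest-fallback").all()
        assert np.allclose(vals.loc[others], 5.0)

    def test_matches_per_vertex_nearest_oracle(self, cortex20):
        gm, sset = make_sampleset(cortex20, seed=13, call_rate=0.3)
        assign = gx.assign_samples(sset, cortex20)
        sset2 = sset.subset(sample_ids=list(assign.index))
        probe = sset2.probes.index[0]
        vals, prov = gx.area_expression(sset2, assign, probe, cortex20)
        sig = [s for s in assign.index if sset2.calls.loc[s, probe]]
        sig_pos = cortex20.vertices[assign.loc[sig, "vertex"].to_numpy(int)]
        for aid in cortex20.area_ids:
            if prov.loc[aid] != "nearest-fallback":
                continue
            verts = cortex20.vertices[cortex20.parcel_labels
                                      == cortex20.area_ids.index(aid)]
            picks = []
            for v in verts:
                d = np.linalg.norm(sig_pos - v, axis=1)
                picks.append(sset2.intensity.loc[sig[int(np.argmin(d))], probe])
            assert vals.loc[aid] == pytest.approx(np.mean(picks))


class TestRepresentativeProbe:
    def test_single_probe(self):
        df = pd.DataFrame({"P0": [1.0, 2.0, 3.0]})
        assert gx.representative_probe(df) == "P0"

    def test_two_probes_higher_variance_wins(self):
        df = pd.DataFrame({"P0": [0.0, 2.0, 4.0], "P1": [1.0, 1.5, 2.0]})
        assert gx.representative_probe(df) == "P0"

    def test_three_probes_correlation_rule(self, rng):
        base = rng.normal(size=30)
        df = pd.DataFrame({
            "P0": base + rng.normal(0, 0.01, 30),
            "P1": base + rng.normal(0, 0.01, 30),
            "P2": rng.normal(size=30),
        })
        assert gx.representative_probe(df) in ("P0", "P1")

    def test_too_many_probes_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)),
                          columns=[f"P{i}" for i in range(5)])
        with pytest.raises(ParameterError):
            gx.representative_probe(df)


class TestPipelineRecovery:
    def test_full_pipeline_recovers_planted_maps(self, cortex60):
        """End to end: recovered per-area expression correlates with the
        planted per-gene maps."""
        rs = []
        for seed in (11, 12, 13):
            gm = syn.planted_gene_maps(cortex60, 20, 15.0, seed=seed)
            sset = syn.generate_sample_set(cortex60, 6, 100, 40, 20, gm, seed=seed)
            expr = gx.run_gene_pipeline(sset, cortex60)
            for gene in gm.columns:
                v = expr.values[gene]
                ok = v.notna()
                rs.append(np.corrcoef(v[ok], gm.loc[ok[ok].index, gene])[0, 1])
        assert np.mean(rs) >= 0.8

    def test_provenance_complete(self, cortex20):
        gm, sset = make_sampleset(cortex20, seed=21)
        expr = gx.run_gene_pipeline(sset, cortex20)
        has_value = expr.values.notna()
        assert (expr.provenance.where(~has_value, None)
                .isin([None, "direct", "nearest-fallback"]).all().all())
        assert set(expr.provenance.to_numpy().ravel()) <= {"direct", "nearest-fallback", "missing"}

    def test_call_rate_one_never_falls_back(self, cortex20):
        gm, sset = make_sampleset(cortex20, seed=22, call_rate=1.0,
                                  coord_noise_sd=0.0)
        expr = gx.run_gene_pipeline(sset, cortex20)
        # every area on this small cortex holds at least one sample
        assert (expr.provenance == "direct").all().all()
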