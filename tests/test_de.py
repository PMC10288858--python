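"""DE engine: size factors, BH, SVA, NB-Wald fit, DEG calling, viz matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoscreen import de, pipeline
from mitoscreen.cohort import prepare_metadata
from mitoscreen.types import CountMatrix, DesignSpec


def _cm(arr, lengths=None):
    arr = np.asarray(arr)
    counts = pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=[f"s{j}" for j in range(arr.shape[1])]
    )
    ldf = None
    if lengths is not None:
        ldf = pd.DataFrame(np.asarray(lengths, dtype=float), index=counts.index, columns=counts.columns)
    return CountMatrix(counts=counts, lengths=ldf)


def brute_force_size_factors(arr):
    """Independent median-of-ratios: explicit loops, no vectorisation."""
    arr = np.asarray(arr, dtype=float)
    keep = [g for g in range(arr.shape[0]) if all(arr[g, s] > 0 for s in range(arr.shape[1]))]
    geo = [np.exp(np.mean([np.log(arr[g, s]) for s in range(arr.shape[1])])) for g in keep]
    return [float(np.median([arr[g, s] / geo[i] for i, g in enumerate(keep)])) for s in range(arr.shape[1])]


def brute_force_bh(ps):
    """Step-up BH by direct enumeration of the definition."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [min(ps[i] * m / (r + 1), 1.0) for r, i in enumerate(order)]
    for r in range(m - 2, -1, -1):
        adj[r] = min(adj[r], adj[r + 1])
    out = [None] * m
    for r, i in enumerate(order):
        out[i] = adj[r]
    return out


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm([[10, 10], [7, 7], [3, 3]])
        sf = de.size_factors(cm.counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        a = np.array([[10], [40], [6]])
        cm = _cm(np.hstack([a, 2 * a]))
        sf = de.size_factors(cm.counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            arr = rng.integers(0, 60, size=(50, 6))
            arr[0] = rng.integers(1, 60, size=6)  # ensure one all-positive gene
            got = de.size_factors(pd.DataFrame(arr)).to_numpy()
            assert np.allclose(got, brute_force_size_factors(arr))

    def test_all_sparse_matrix_rejected(self):
        with pytest.raises(ValueError, match="pre-filter"):
            de.size_factors(pd.DataFrame([[0, 1], [1, 0]]))

    def test_length_offsets_absorb_length_term(self):
        """With lengths proportional within genes, factors match plain ones."""
        rng = np.random.default_rng(6)
        arr = rng.integers(5, 100, size=(40, 4))
        cm_plain = _cm(arr)
        cm_len = _cm(arr, lengths=np.full(arr.shape, 1500.0))
        n_plain = de.normalization_matrix(cm_plain)
        n_len = de.normalization_matrix(cm_len)
        assert np.allclose(n_plain.to_numpy(), n_len.to_numpy())


class TestAdjustBH:
    def test_single_p(self):
        assert de.adjust_bh([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        got = de.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert de.adjust_bh([]).size == 0

    def test_nan_passthrough_excluded_from_family(self):
        got = de.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        assert got[0] == pytest.approx(0.02)  # m = 2, not 3
        assert got[2] == pytest.approx(0.02)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_brute_force_oracle(self, ps):
        got = de.adjust_bh(ps)
        assert np.allclose(got, brute_force_bh(ps))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(20):
            ps = rng.uniform(size=rng.integers(1, 200))
            got = de.adjust_bh(ps)
            expected = multipletests(ps, method="fdr_bh")[1]
            assert np.allclose(got, expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_and_dominates_p(self, ps):
        got = de.adjust_bh(ps)
        assert np.all(got >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(got[order]) >= -1e-12)


class TestCallDegs:
    def _frame(self, padj, lfc):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(padj))], "padj": padj, "log2fc": lfc})

    def test_strict_boundaries(self):
        res = de.call_degs(self._frame([0.05, 0.01, 0.01], [0.5, 0.1, 0.2]))
        assert list(res["is_deg"]) == [False, False, True]

    def test_missing_padj_never_deg(self):
        res = de.call_degs(self._frame([np.nan, 0.001], [2.0, -2.0]))
        assert list(res["is_deg"]) == [False, True]
        assert list(res["direction"]) == ["none", "down"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            padj = rng.uniform(0, 0.2, 50)
            lfc = rng.normal(0, 0.3, 50)
            res = de.call_degs(self._frame(padj, lfc))
            expected = [(pa < 0.05) and (abs(l) > 0.1) for pa, l in zip(padj, lfc)]
            assert list(res["is_deg"]) == expected


class TestEstimateSvs:
    def _design(self, n):
        rng = np.random.default_rng(1)
        cond = pd.Series(["AD", "control"] * (n // 2), index=[f"s{j}" for j in range(n)])
        covs = pd.DataFrame({"age": rng.uniform(65, 95, n)}, index=cond.index)
        return cond, covs

    def test_k_bounds_enforced(self):
        rng = np.random.default_rng(3)
        cm = _cm(rng.integers(1, 100, size=(100, 8)))
        cond, covs = self._design(8)
        with pytest.raises(ValueError, match="k must be"):
            de.estimate_svs(cm, DesignSpec(condition=cond, covariates=covs), k=7)

    def test_recovers_orthogonal_batch(self, null_sim):
        cm, meta, truth = null_sim["cm"], null_sim["meta"], null_sim["truth"]
        # regenerate with a strong batch effect
        from mitoscreen.synthdata import SimConfig, simulate_cohort

        cfg = SimConfig(seed=23, frac_deg=0.0, batch_sd=1.0, frac_braak3=0.0,
                        n_candidates=0, n_hubs=0, n_support=0)
        cm, meta, annot, truth = simulate_cohort(cfg)
        prep = prepare_metadata(meta)
        prep["sex"] = truth.true_sex.reindex(prep["sample_id"]).to_numpy()
        sub = prep[prep["sex"] == "male"]
        sub_cm = cm.subset_samples(sub["sample_id"].tolist())
        cond = pd.Series(sub["diagnosis"].to_numpy(), index=sub["sample_id"].to_numpy())
        covs = sub.set_index("sample_id")[["age", "pmi"]].astype(float)
        svs = de.estimate_svs(sub_cm, DesignSpec(condition=cond, covariates=covs), k=2)
        batch = (truth.batch_assignments.reindex(svs.index) == "DS1").astype(float)
        assert abs(np.corrcoef(svs["SV1"], batch)[0, 1]) > 0.9

    def test_sign_fix_invariant_to_residual_sign_flip(self):
        rng = np.random.default_rng(4)
        cm = _cm(rng.integers(1, 200, size=(60, 12)))
        cond, covs = self._design(12)
        d = DesignSpec(condition=cond, covariates=covs)
        svs1 = de.estimate_svs(cm, d, k=2)
        svs2 = de.estimate_svs(cm, d, k=2)
        pd.testing.assert_frame_equal(svs1, svs2)
        for c in svs1.columns:
            v = svs1[c].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0


class TestFitDe:
    def test_null_gene_flat_counts(self):
        rng = np.random.default_rng(9)
        col = rng.integers(20, 80, size=30)
        arr = np.tile(col[:, None], (1, 10))  # identical columns: unit size factors
        arr[0] = 42  # identical counts in both groups
        cm = _cm(arr)
        cond = pd.Series(["AD"] * 5 + ["control"] * 5, index=cm.sample_ids)
        res = de.fit_de(cm, DesignSpec(condition=cond))
        assert res.iloc[0]["log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert res.iloc[0]["pvalue"] > 0.9

    def test_matches_statsmodels_glm_per_gene(self):
        """Independent cross-check: statsmodels NB GLM with the same fixed
        dispersion and offsets reproduces coefficients and SEs."""
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 40
        arr = rng.negative_binomial(10, 0.3, size=(12, n)) + 1
        cm = _cm(arr)
        cond = pd.Series(["AD"] * (n // 2) + ["control"] * (n // 2), index=cm.sample_ids)
        res = de.fit_de(cm, DesignSpec(condition=cond))
        N = de.normalization_matrix(cm).to_numpy()
        X = DesignSpec(condition=cond).matrix().to_numpy()
        for i in range(12):
            alpha = res["dispersion"].iloc[i]
            fam = sm.families.NegativeBinomial(alpha=alpha) if alpha > 1e-6 else sm.families.Poisson()
            fit = sm.GLM(arr[i], X, family=fam, offset=np.log(N[i])).fit()
            assert fit.params[-1] / np.log(2) == pytest.approx(res["log2fc"].iloc[i], abs=1e-4)
            assert fit.bse[-1] / np.log(2) == pytest.approx(res["se"].iloc[i], rel=1e-3)

    def test_all_zero_gene_filtered(self):
        arr = np.vstack([np.zeros(8, dtype=int), np.full(8, 30)])
        cm = _cm(arr)
        cond = pd.Series(["AD"] * 4 + ["control"] * 4, index=cm.sample_ids)
        res = de.fit_de(cm, DesignSpec(condition=cond))
        assert np.isnan(res.iloc[0]["pvalue"]) and np.isnan(res.iloc[0]["padj"])
        assert not res.iloc[0]["is_deg"]

    def test_low_mean_genes_excluded_from_bh_family(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(20, 60, size=(20, 10))
        arr[3] = (rng.uniform(size=10) < 0.3).astype(int)  # mean << 1
        cm = _cm(arr)
        cond = pd.Series(["AD"] * 5 + ["control"] * 5, index=cm.sample_ids)
        res = de.fit_de(cm, DesignSpec(condition=cond))
        assert np.isnan(res.iloc[3]["padj"])
        assert np.isfinite(res.iloc[3]["pvalue"])

    def test_strata_independent(self, default_sim):
        """Permuting female samples never changes male results."""
        cm, meta, truth = default_sim["cm"], default_sim["meta"], default_sim["truth"]
        prep = prepare_metadata(meta)
        prep["sex"] = truth.true_sex.reindex(prep["sample_id"]).to_numpy()
        res1 = pipeline.run_de_stratum(cm, prep, "male", k_svs=1)
        rng = np.random.default_rng(0)
        females = prep.loc[prep["sex"] == "female", "sample_id"].tolist()
        perm = rng.permutation(females)
        counts = cm.counts.copy()
        counts[females] = counts[list(perm)].to_numpy()
        lengths = cm.lengths.copy()
        lengths[females] = lengths[list(perm)].to_numpy()
        cm2 = CountMatrix(counts=counts, lengths=lengths)
        res2 = pipeline.run_de_stratum(cm2, prep, "male", k_svs=1)
        pd.testing.assert_frame_equal(res1, res2)

    def test_pure_noise_sv_barely_moves_estimates(self, default_sim):
        cm, meta, truth = default_sim["cm"], default_sim["meta"], default_sim["truth"]
        prep = prepare_metadata(meta)
        prep["sex"] = truth.true_sex.reindex(prep["sample_id"]).to_numpy()
        sub = prep[(prep["sex"] == "male") & prep["diagnosis"].isin(["AD", "control"])]
        sub_cm = cm.subset_samples(sub["sample_id"].tolist())
        cond = pd.Series(sub["diagnosis"].to_numpy(), index=sub["sample_id"].to_numpy())
        covs = sub.set_index("sample_id")[["age", "pmi"]].astype(float)
        base = de.fit_de(sub_cm, DesignSpec(condition=cond, covariates=covs))
        rng = np.random.default_rng(12)
        noise = pd.DataFrame({"SVnoise": rng.normal(size=len(cond))}, index=cond.index)
        with_sv = de.fit_de(
            sub_cm, DesignSpec(condition=cond, covariates=covs, surrogate_variables=noise)
        )
        diff = (base["log2fc"] - with_sv["log2fc"]).abs().mean()
        assert diff < 0.02


class TestVizMatrix:
    def test_batch_variance_shrinks_after_adjustment(self):
        from mitoscreen.synthdata import SimConfig, simulate_cohort

        cfg = SimConfig(seed=31, frac_deg=0.0, batch_sd=1.0, frac_braak3=0.0,
                        n_candidates=0, n_hubs=0, n_support=0)
        cm, meta, annot, truth = simulate_cohort(cfg)
        prep = prepare_metadata(meta)
        prep["sex"] = truth.true_sex.reindex(prep["sample_id"]).to_numpy()
        sub = prep[prep["sex"] == "male"]
        sub_cm = cm.subset_samples(sub["sample_id"].tolist())
        cond = pd.Series(sub["diagnosis"].to_numpy(), index=sub["sample_id"].to_numpy())
        covs = sub.set_index("sample_id")[["age", "pmi"]].astype(float)
        d0 = DesignSpec(condition=cond, covariates=covs)
        svs = de.estimate_svs(sub_cm, d0, k=2)
        adj = de.adjusted_matrix_for_viz(
            sub_cm, DesignSpec(condition=cond, covariates=covs, surrogate_variables=svs)
        )
        batch = (truth.batch_assignments.reindex(adj.pca_before.index) == "DS1").to_numpy()

        def batch_r2(coords):
            d = coords.to_numpy()[:, :2]
            r2 = 0.0
            for j in range(2):
                r = np.corrcoef(d[:, j], batch.astype(float))[0, 1]
                r2 += r ** 2 * d[:, j].var()
            return r2 / d.var(axis=0).sum()

        assert batch_r2(adj.pca_after) < 0.5 * batch_r2(adj.pca_before)

    def test_output_type_not_accepted_by_fit_de(self):
        """The viz matrix is a distinct container; the DE fit only takes
        integral CountMatrix input."""
        rng = np.random.default_rng(13)
        cm = _cm(rng.integers(1, 50, size=(10, 6)))
        cond = pd.Series(["AD"] * 3 + ["control"] * 3, index=cm.sample_ids)
        adj = de.adjusted_matrix_for_viz(cm, DesignSpec(condition=cond))
        assert isinstance(adj, de.AdjustedExpression)
        with pytest.raises(AttributeError):
            de.fit_de(adj, DesignSpec(condition=cond))  # type: ignore[arg-type]
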