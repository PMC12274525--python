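"""Association layer: moderated tests, correlations, clustering."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pkdprog import association


def _random_matrix(n=30, p=25, seed=0, slope_effect=None):
    rng = np.random.default_rng(seed)
    slope = rng.normal(-2.5, 2.0, n)
    X = 20 + rng.normal(0, 1, (n, p)) * np.exp(rng.normal(0, 0.5, p))[None, :]
    if slope_effect is not None:
        X[:, 0] += slope_effect * slope
    idx = [f"s{i}" for i in range(n)]
    return (
        pd.DataFrame(X, index=idx, columns=[f"g{j}" for j in range(p)]),
        pd.Series(slope, index=idx),
    )


class TestModerated:
    def test_posterior_variance_formula(self):
        # s2=4, df=10, d0=4, s0_sq=1 -> (4*1 + 10*4)/14
        s2_post = (4 * 1.0 + 10 * 4.0) / (4 + 10)
        assert s2_post == pytest.approx(44 / 14)
        # and the estimator respects the same combination rule
        m, slope = _random_matrix(seed=1)
        res = association.moderated_association(m, slope)
        if np.isfinite(res.d0):
            expected = (res.d0 * res.s0_sq + res.table["df"] * res.table["s2"]) / (
                res.d0 + res.table["df"]
            )
            np.testing.assert_allclose(res.table["s2_post"], expected, rtol=1e-12)

    def test_shrinkage_between_s2_and_prior(self):
        m, slope = _random_matrix(seed=2)
        res = association.moderated_association(m, slope)
        lo = np.minimum(res.table["s2"], res.s0_sq)
        hi = np.maximum(res.table["s2"], res.s0_sq)
        assert ((res.table["s2_post"] >= lo - 1e-12) & (res.table["s2_post"] <= hi + 1e-12)).all()

    def test_null_yields_no_discoveries(self):
        hits = []
        for seed in range(5):
            m, slope = _random_matrix(n=60, p=100, seed=seed)
            res = association.moderated_association(m, slope)
            hits.append(int(res.table["significant"].sum()))
        assert np.mean(hits) < 2

    def test_strong_effect_detected(self):
        m, slope = _random_matrix(n=80, seed=3, slope_effect=0.5)
        res = association.moderated_association(m, slope)
        assert res.table.loc["g0", "significant"]
        assert res.table.loc["g0", "coef"] > 0

    def test_misaligned_samples_rejected(self):
        m, slope = _random_matrix()
        with pytest.raises(ValueError, match="misaligned"):
            association.moderated_association(m.iloc[:-2], slope)

    def test_zero_variance_protein_rejected(self):
        m, slope = _random_matrix()
        m["g0"] = 1.0
        with pytest.raises(ValueError, match="g0"):
            association.moderated_association(m, slope)

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check against the Bioconductor implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the limma cross-check")
        rng = np.random.default_rng(42)
        n, p = 24, 40
        slope = rng.normal(-2.5, 2.0, n)
        sds = np.exp(rng.normal(0, 0.6, p))
        X = 20 + rng.normal(0, 1, (n, p)) * sds + np.outer(slope, rng.normal(0, 0.1, p))
        m = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                         columns=[f"g{j}" for j in range(p)])
        res = association.moderated_association(m, pd.Series(slope, index=m.index))
        m.to_csv(tmp_path / "mat.tsv", sep="\t")
        np.savetxt(tmp_path / "slope.txt", slope)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("mat.tsv", row.names=1))
            sl <- scan("slope.txt", quiet=TRUE)
            fit <- eBayes(lmFit(t(m), design=cbind(Intercept=1, slope=sl)))
            out <- data.frame(t=fit$t[,"slope"], p=fit$p.value[,"slope"])
            write.csv(out, "r.csv")
        """)
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        r = pd.read_csv(tmp_path / "r.csv", index_col=0)
        np.testing.assert_allclose(res.table["t_mod"].values, r["t"].values,
                                   atol=1e-8)
        np.testing.assert_allclose(res.table["p"].values, r["p"].values, atol=1e-8)


class TestBH:
    def test_hand_computed_example(self):
        adj = association.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert association.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            association.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_capped_and_order_preserving(self, ps):
        adj = association.bh_adjust(ps)
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_discoveries_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        adj = association.bh_adjust(rng.uniform(0, 1, 200) ** 2)
        assert (adj < 0.01).sum() <= (adj < 0.05).sum() <= (adj < 0.1).sum()


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = association.pearson_with_pvalue(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, p, n = association.pearson_with_pvalue(x, y)
        rb = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(rb, abs=1e-12)
        from scipy import stats

        t = rb * np.sqrt((n - 2) / (1 - rb**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), abs=1e-12)

    def test_sign_flips_with_negation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        y = y + 0.5 * x
        r1, _, _ = association.pearson_with_pvalue(x, y)
        r2, _, _ = association.pearson_with_pvalue(x, -y)
        assert r2 == pytest.approx(-r1)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        _, _, n = association.pearson_with_pvalue(x, y)
        assert n == 3


class TestEGFRDependency:
    def test_construction(self):
        rng = np.random.default_rng(3)
        n = 100
        egfr = rng.uniform(20, 110, n)
        idx = [f"s{i}" for i in range(n)]
        m = pd.DataFrame(
            {
                "CST3": 20 - 0.03 * egfr + rng.normal(0, 0.3, n),
                "NULL1": rng.normal(15, 1, n),
            },
            index=idx,
        )
        res = association.egfr_dependency(m, pd.Series(egfr, index=idx),
                                          ["CST3", "NULL1"])
        assert len(res.table) == 2
        assert res.table.loc["CST3", "r"] < -0.5
        assert res.table.loc["CST3", "p"] < 1e-6
        assert res.table.loc["NULL1", "p"] > 0.001

    def test_empty_panel_rejected(self):
        m = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="empty"):
            association.egfr_dependency(m, pd.Series([1.0, 2.0, 3.0]), [])


class TestSignConcordance:
    def _table(self, seed=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"r": rng.uniform(-1, 1, 9), "p": rng.uniform(0, 0.04, 9)},
            index=[f"g{j}" for j in range(9)],
        )

    def test_identical_tables_fully_concordant(self):
        t = self._table()
        out = association.sign_concordance(t, t)
        assert len(out) == 9 and out["concordant"].all()

    def test_flipped_tables_discordant(self):
        t = self._table()
        flipped = t.assign(r=-t["r"])
        out = association.sign_concordance(t, flipped)
        assert not out["concordant"].any()

    def test_no_overlap_rejected(self):
        t = self._table()
        other = t.copy()
        other.index = [f"h{j}" for j in range(9)]
        with pytest.raises(ValueError, match="overlap"):
            association.sign_concordance(t, other)


class TestDetection:
    def test_detection_tracks_slope(self):
        rng = np.random.default_rng(5)
        n = 200
        slope = rng.normal(-2.5, 2.5, n)
        # marker abundant (hence detected) in fast progressors
        abundance = -0.8 * slope + rng.normal(0, 1, n)
        detected = abundance > np.quantile(abundance, 0.25)
        idx = [f"s{i}" for i in range(n)]
        mask = pd.DataFrame({"RARRES2": detected}, index=idx)
        r, p = association.detection_association(
            mask, pd.Series(slope, index=idx), "RARRES2"
        )
        assert r < 0 and p < 0.05

    def test_all_detected_rejected(self):
        mask = pd.DataFrame({"A": [True, True, True]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="contrast"):
            association.detection_association(
                mask, pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]), "A"
            )


def brute_force_average_linkage(dist):
    """Naive agglomerative average linkage on a dense distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    d = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                val = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        val, a, b = best
        heights.append(val)
        clusters[a] = clusters[a] + clusters[b]
        active.remove(b)
    return heights


class TestClustering:
    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(5, 12))
        m = pd.DataFrame(data.T, columns=[f"g{j}" for j in range(5)])
        res = association.hclust_corr(m, axis="proteins", k=2)
        corr = np.corrcoef(data)
        expected = brute_force_average_linkage(1 - corr)
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), sorted(expected),
                                   atol=1e-10)

    def test_identical_proteins_merge_first_at_zero(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=10)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=10), "d": rng.normal(size=10)}
        )
        res = association.hclust_corr(m, axis="proteins", k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_k_nonempty_clusters(self, processed_cohort):
        matrix = processed_cohort[0]
        res = association.hclust_corr(matrix.data.iloc[:, :30], axis="samples", k=3)
        assert res.assignment.nunique() == 3

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(20, 8))
        data[:, :4] += rng.normal(size=(20, 1)) * 2
        m = pd.DataFrame(data, columns=[f"g{j}" for j in range(8)])
        res1 = association.hclust_corr(m, axis="proteins", k=2)
        perm = rng.permutation(8)
        res2 = association.hclust_corr(m.iloc[:, perm], axis="proteins", k=2)
        a1 = res1.assignment
        a2 = res2.assignment.reindex(a1.index)
        # same partition up to label swap
        table = pd.crosstab(a1, a2)
        assert (table.values > 0).sum() == 2

    def test_constant_row_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0],
                          "c": [3.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            association.hclust_corr(m, axis="proteins", k=2)


class TestCompareClusters:
    def test_identical_distributions_nonsignificant(self):
        rng = np.random.default_rng(9)
        n = 150
        assign = pd.Series(rng.integers(1, 4, n), index=range(n))
        cov = pd.DataFrame({"age": rng.normal(45, 10, n)}, index=range(n))
        out = association.compare_clusters(assign, cov)
        assert (out["p_adj"] > 0.05).all()

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(10)
        assign = pd.Series([1] * 50 + [2] * 50 + [3] * 50)
        age = np.concatenate(
            [rng.normal(45, 5, 50), rng.normal(55, 5, 50), rng.normal(45, 5, 50)]
        )
        out = association.compare_clusters(assign, pd.DataFrame({"age": age}))
        sig = out[out["comparison"] == "cluster1_vs_cluster2"]
        assert (sig["p_adj"] < 0.05).all()

    def test_proportion_test_matches_chisq_oracle(self):
        from scipy import stats

        assign = pd.Series([1] * 40 + [2] * 60)
        sex = pd.Series(["f"] * 30 + ["m"] * 10 + ["f"] * 25 + ["m"] * 35)
        out = association.compare_clusters(
            assign, pd.DataFrame({"sex": sex.values}), categorical=["sex"]
        )
        p0 = 55 / 100  # cohort-wide fraction of the majority level "f"
        row = out[out["comparison"] == "cluster1_vs_cohort"].iloc[0]
        obs = np.array([30, 10])
        exp = np.array([40 * p0, 40 * (1 - p0)])
        stat = float(((obs - exp) ** 2 / exp).sum())
        assert row["statistic"] == pytest.approx(stat, abs=1e-12)
        assert row["p"] == pytest.approx(float(stats.chi2.sf(stat, 1)), abs=1e-12)
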