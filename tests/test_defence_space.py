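"""Defence matrix assembly, PCA, antiherbiome clustering, group contrasts."""

import logging

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from antiherbiome import assoc_models as am
from antiherbiome import defence_space as ds
from antiherbiome import synthetic_world as sw


def make_summary(n=30, seed=0, drop_palms_from=()):
    rng = np.random.default_rng(seed)
    idx = pd.Index(range(n), name="ecoregion_id")
    pres = rng.integers(0, 50, n)
    tot = pres + rng.integers(1, 50, n)
    lsp_pres = rng.integers(0, 5, n)
    lsp_abs = rng.integers(1, 5, n)
    df = pd.DataFrame(
        {
            "WD_mean": rng.uniform(0.3, 0.9, n),
            "LeafSize_mean": rng.uniform(5, 150, n),
            "StemSpines_presences": pres,
            "StemSpines_absences": tot - pres,
            "Latex_presences": rng.integers(0, 30, n),
            "Latex_absences": rng.integers(1, 30, n),
            "LeafSpines_present_species": lsp_pres,
            "LeafSpines_absent_species": lsp_abs,
        },
        index=idx,
    )
    for e in drop_palms_from:
        df.loc[e, ["LeafSpines_present_species", "LeafSpines_absent_species"]] = 0
    return df


class TestBuildDefenceMatrix:
    def test_proportions(self):
        df = make_summary(5)
        df.loc[0, ["StemSpines_presences", "StemSpines_absences"]] = (3, 2)
        dm = ds.build_defence_matrix(df)
        assert dm.values.loc[0, "StemSpines_prop"] == pytest.approx(0.6)

    def test_palm_free_filled_from_model_and_logged(self):
        df = make_summary(40, drop_palms_from=(1, 2))
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"pH": rng.standard_normal(40)},
                         index=pd.Index(range(40), name="ecoregion_id"))
        y = (df["LeafSpines_present_species"], df["LeafSpines_absent_species"])
        rows = X.index[(y[0] + y[1]) > 0]
        spine_model = am.fit_model((y[0].loc[rows], y[1].loc[rows]), X.loc[rows],
                                   ["pH"], family="binomial_counts", response_name="LeafSpines")
        dm = ds.build_defence_matrix(df, spine_model=spine_model, predictors=X)
        assert sorted(dm.filled) == [1, 2]
        assert dm.values.loc[1, "LeafSpines_prop"] == pytest.approx(
            float(spine_model.predict(X.loc[[1]])[0])
        )

    def test_unfillable_excluded(self):
        df = make_summary(10, drop_palms_from=(4,))
        dm = ds.build_defence_matrix(df)  # no model to fill with
        assert 4 in dm.excluded and 4 not in dm.values.index

    def test_constant_column_raises(self):
        df = make_summary(8)
        df["WD_mean"] = 0.5
        with pytest.raises(ValueError, match="WD"):
            ds.build_defence_matrix(df)

    def test_standardization_idempotent(self):
        df = make_summary(20)
        z1 = ds.standardize(ds.build_defence_matrix(df).values)
        z2 = ds.standardize(z1)
        pd.testing.assert_frame_equal(z1, z2, check_exact=False, atol=1e-12)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        dm = ds.build_defence_matrix(make_summary(50, seed=3))
        pca = ds.pca_axes(dm)
        C = np.corrcoef(dm.z.to_numpy(), rowvar=False)
        want = np.sort(np.linalg.eigvalsh(C))[::-1]
        n = len(dm.z)
        got = pca.var_frac * want.sum() * 0 + pca.var_frac  # fractions
        assert np.allclose(got, want / want.sum(), atol=1e-8)
        # loadings are eigenvectors of the correlation matrix (up to sign)
        _, vecs = np.linalg.eigh(C * (n - 1) / (n - 1))
        for j in range(5):
            col = pca.loadings.iloc[:, j].to_numpy()
            assert any(
                np.allclose(np.abs(col), np.abs(vecs[:, k]), atol=1e-6) for k in range(5)
            )

    def test_variance_fractions_sum_and_order(self):
        pca = ds.pca_axes(ds.build_defence_matrix(make_summary(60, seed=4)))
        assert pca.var_frac.sum() == pytest.approx(1.0)
        assert (np.diff(pca.var_frac) <= 1e-12).all()

    def test_dim1_sign_convention(self):
        pca = ds.pca_axes(ds.build_defence_matrix(make_summary(60, seed=5)))
        assert pca.loadings.loc["StemSpines_prop", "Dim1"] >= 0

    def test_duplicated_traits_symmetric_loadings(self):
        df = make_summary(80, seed=6)
        df["Latex_presences"] = df["StemSpines_presences"]
        df["Latex_absences"] = df["StemSpines_absences"]
        dm = ds.build_defence_matrix(df)
        pca = ds.pca_axes(dm)
        l1 = pca.loadings.loc["StemSpines_prop", "Dim1"]
        l2 = pca.loadings.loc["Latex_prop", "Dim1"]
        assert abs(abs(l1) - abs(l2)) < 1e-8

    def test_rank_deficient_raises(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(40)
        vals = pd.DataFrame(
            {c: base * (i + 1) for i, c in enumerate(ds.DEFENCE_COLUMNS)},
            index=pd.Index(range(40), name="ecoregion_id"),
        )
        dm = ds.DefenceMatrix(values=vals, z=ds.standardize(vals))
        with pytest.raises(ValueError, match="rank"):
            ds.pca_axes(dm)


class TestClustering:
    def blobs(self, seed=0, sep=4.0, n=30):
        vals, truth = sw.planted_defence_blobs(n_per_cluster=n, separation=sep, seed=seed)
        dm = ds.DefenceMatrix(values=vals, z=ds.standardize(vals))
        return dm, truth

    def test_three_blob_recovery_and_naming(self):
        dm, truth = self.blobs()
        cl = ds.cluster_antiherbiomes(ds.pca_axes(dm), dm.z)
        assert cl.k == 3
        assert (cl.labels == truth).all()  # names recovered, not just partition

    def test_row_order_invariance(self):
        dm, _ = self.blobs(seed=1)
        pca = ds.pca_axes(dm)
        cl1 = ds.cluster_antiherbiomes(pca, dm.z)
        perm = np.random.default_rng(0).permutation(len(dm.z))
        vals2 = dm.values.iloc[perm]
        dm2 = ds.DefenceMatrix(values=vals2, z=ds.standardize(vals2))
        cl2 = ds.cluster_antiherbiomes(ds.pca_axes(dm2), dm2.z)
        pd.testing.assert_series_equal(
            cl1.labels.sort_index(), cl2.labels.sort_index(), check_names=False
        )

    def test_single_blob_weak_structure_warning(self, caplog):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.standard_normal((60, 5)), columns=list(ds.DEFENCE_COLUMNS))
        dm = ds.DefenceMatrix(values=vals, z=ds.standardize(vals))
        with caplog.at_level(logging.WARNING):
            cl = ds.cluster_antiherbiomes(ds.pca_axes(dm), dm.z)
        assert "weak cluster structure" in caplog.text

    def test_k_max_bound(self):
        dm, _ = self.blobs(n=3)  # 9 points
        with pytest.raises(ValueError, match="k_max"):
            ds.cluster_antiherbiomes(ds.pca_axes(dm), dm.z, k_max=8)


class TestContrasts:
    def test_two_groups_matches_ranksum_equivalence(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.standard_normal(40))
        labels = pd.Series(["a"] * 20 + ["b"] * 20)
        out = ds.contrast_groups(values, labels)
        kw_p = out.global_tests["kw_p"].iloc[0]
        # KW with two groups is the square of the (tie-corrected) rank-sum z
        z = out.pairwise["z"].iloc[0]
        assert st.chi2.sf(z**2, 1) == pytest.approx(kw_p, abs=1e-10)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        values = pd.Series(np.concatenate([rng.standard_normal(25),
                                           rng.standard_normal(25) + 3.0]))
        labels = pd.Series(["a"] * 25 + ["b"] * 25)
        out = ds.contrast_groups(values, labels)
        assert out.global_tests["kw_p"].iloc[0] < 1e-6
        assert (out.pairwise["p_bh"] < 1e-4).all()

    def test_dunn_hand_check(self):
        values = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = pd.Series(["a", "a", "a", "b", "b", "b"])
        pw = ds.dunn_test(values, labels)
        N = 6
        se = np.sqrt(N * (N + 1) / 12 * (1 / 3 + 1 / 3))
        want = (2.0 - 5.0) / se  # mean ranks 2 and 5
        assert pw["z"].iloc[0] == pytest.approx(want)

    def test_small_group_excluded_and_flagged(self, caplog):
        values = pd.Series(np.arange(11.0))
        labels = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"])
        with caplog.at_level(logging.WARNING):
            out = ds.contrast_groups(values, labels)
        assert "c" in caplog.text
        assert set(out.pairwise[["group_a", "group_b"]].iloc[0]) == {"a", "b"}

    def test_identical_distributions_uniform_p(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            values = pd.Series(rng.standard_normal(30))
            labels = pd.Series(["a", "b", "c"] * 10)
            out = ds.contrast_groups(values, labels)
            ps.append(out.global_tests["kw_p"].iloc[0])
        # the KW chi-square approximation is slightly conservative at n = 30
        assert 0.005 <= np.mean(np.array(ps) < 0.05) <= 0.10
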