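import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import svrdeconv as sd
from tests.conftest import brute_force_anova


class TestAnovaRank:
    def test_two_group_example_matches_hand_arithmetic(self):
        # groups {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=pd.Index(["g"], name="feature_id"),
            columns=list("abcdef"),
        )
        ann = pd.DataFrame(
            {"cell_type": ["A"] * 3 + ["B"] * 3}, index=pd.Index(list("abcdef"))
        )
        table = sd.anova_rank(expr, ann)
        assert table.loc["g", "F_statistic"] == pytest.approx(13.5)
        assert table.loc["g", "p_value"] < 0.05
        assert bool(table.loc["g", "significant"])

    def test_matches_scipy_f_oneway(self, small_reference):
        expr, ann, _ = small_reference
        table = sd.anova_rank(expr, ann)
        labels = ann["cell_type"]
        for gene in expr.index[::37]:
            groups = [
                expr.loc[gene, labels.index[labels == ct]].to_numpy()
                for ct in labels.unique()
            ]
            F, p = stats.f_oneway(*groups)
            assert table.loc[gene, "F_statistic"] == pytest.approx(F, rel=1e-9)
            assert table.loc[gene, "p_value"] == pytest.approx(p, rel=1e-9, abs=1e-300)

    @given(st.integers(0, 2**31 - 1))
    def test_f_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        sizes = rng.integers(2, 6, size=k)
        groups = [rng.normal(rng.normal(0, 1), 1, size=n) for n in sizes]
        expr = pd.DataFrame(
            np.concatenate(groups)[None, :],
            index=pd.Index(["g"], name="feature_id"),
            columns=[f"s{i}" for i in range(sizes.sum())],
        )
        ann = pd.DataFrame(
            {"cell_type": np.repeat([f"t{j}" for j in range(k)], sizes)},
            index=pd.Index(expr.columns),
        )
        F_oracle, p_oracle = brute_force_anova(groups)
        table = sd.anova_rank(expr, ann)
        assert table.loc["g", "F_statistic"] == pytest.approx(F_oracle, rel=1e-9)
        assert table.loc["g", "p_value"] == pytest.approx(p_oracle, rel=1e-9, abs=1e-300)

    def test_constant_feature_gets_p_one(self, two_group_expr):
        expr, ann = two_group_expr
        expr = expr.copy()
        expr.loc["const"] = 7.0
        table = sd.anova_rank(expr, ann)
        assert table.loc["const", "p_value"] == 1.0
        assert not bool(table.loc["const", "significant"])
        assert len(table) == len(expr)  # no rows dropped

    def test_sorted_ascending_with_gapless_ranks(self, small_reference):
        expr, ann, _ = small_reference
        table = sd.anova_rank(expr, ann)
        assert (np.diff(table["p_value"].to_numpy()) >= 0).all()
        assert list(table["rank"]) == list(range(1, len(table) + 1))

    def test_single_replicate_type_rejected(self, two_group_expr):
        expr, ann = two_group_expr
        ann2 = ann.copy()
        ann2.loc["b3", "cell_type"] = "C"
        with pytest.raises(ValueError, match="< 2 replicates"):
            sd.anova_rank(expr, ann2)

    def test_unannotated_sample_rejected(self, two_group_expr):
        expr, ann = two_group_expr
        with pytest.raises(ValueError, match="unannotated"):
            sd.anova_rank(expr, ann.drop(index=["a2"]))


class TestConditionNumber:
    def test_identity_is_one(self):
        assert sd.condition_number(np.eye(3)) == 1.0

    def test_diagonal(self):
        assert sd.condition_number(np.diag([2.0, 1.0])) == pytest.approx(2.0)

    def test_singular_matrix_is_inf(self):
        assert sd.condition_number(np.ones((3, 3))) == np.inf

    @pytest.mark.parametrize("shape", [(10, 4), (50, 20), (200, 50)])
    def test_matches_independent_svd_oracle(self, shape):
        rng = np.random.default_rng(shape[0])
        A = rng.normal(size=shape)
        oracle = np.linalg.norm(A, 2) * np.linalg.norm(np.linalg.pinv(A), 2)
        assert sd.condition_number(A) == pytest.approx(oracle, rel=1e-9)

    def test_approx_mode_within_modest_factor_of_exact(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(60, 9))
        exact = sd.condition_number(A, mode="exact")
        approx = sd.condition_number(A, mode="approx")
        # 1-norm triangular estimate brackets the 2-norm value within sqrt(n)-ish factors
        assert exact / 10 <= approx <= exact * 10

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sd.condition_number(np.empty((0, 3)))


class TestScanOptimalG:
    def test_gstar_attains_grid_minimum(self, small_reference):
        expr, ann, _ = small_reference
        ranked = sd.anova_rank(expr, ann)
        scan = sd.scan_optimal_G(ranked, expr, step=50)
        assert scan.kappa_star <= scan.grid["kappa"].min() + 1e-12
        # oracle: evaluate every grid point independently and take the argmin
        for _, row in scan.grid.iterrows():
            top = ranked.index[: int(row["G"])]
            kappa = sd.condition_number(expr.loc[top].to_numpy())
            assert row["kappa"] == pytest.approx(kappa, rel=1e-12)

    def test_grid_is_step_multiples(self, small_reference):
        expr, ann, _ = small_reference
        ranked = sd.anova_rank(expr, ann)
        scan = sd.scan_optimal_G(ranked, expr, step=50)
        n_sig = int(ranked["significant"].sum())
        assert list(scan.grid["G"]) == list(range(50, n_sig + 1, 50))

    def test_fewer_significant_than_step_gives_single_point(self, small_reference):
        expr, ann, _ = small_reference
        ranked = sd.anova_rank(expr, ann)
        n_sig = int(ranked["significant"].sum())
        scan = sd.scan_optimal_G(ranked, expr, step=n_sig + 100)
        assert list(scan.grid["G"]) == [n_sig]
        assert scan.G_star == n_sig

    def test_first_g_wins_on_ties(self):
        grid = pd.DataFrame({"G": [500, 1000], "kappa": [2.0, 2.0]})
        scan = sd.ConditionScan(grid=grid, G_star=500)
        assert scan.G_star == 500


class TestSummaries:
    def test_median_is_sort_and_middle(self, two_group_expr):
        expr, ann = two_group_expr
        expr = expr.copy()
        expr.loc["probe"] = [1.0, 2.0, 9.0, 1.0, 3.0, 100.0]
        sig = sd.summarize_by_cell_type(expr, ann)
        assert sig.loc["probe", "A"] == 2.0  # median of {1, 2, 9}
        assert sig.loc["probe", "B"] == 3.0

    def test_even_count_median_is_mean_of_middle_pair(self):
        expr = pd.DataFrame(
            [[1.0, 3.0]], index=pd.Index(["g"], name="feature_id"), columns=["s1", "s2"]
        )
        ann = pd.DataFrame({"cell_type": ["T", "T"]}, index=pd.Index(["s1", "s2"]))
        sig = sd.summarize_by_cell_type(expr, ann)
        assert sig.loc["g", "T"] == 2.0

    def test_duplicating_every_replicate_leaves_medians_unchanged(self, small_reference):
        expr, ann, _ = small_reference
        base = sd.summarize_by_cell_type(expr, ann)
        # duplicating each sample doubles every within-type multiset,
        # which cannot move a median
        dup_expr = expr.copy()
        dup_expr.columns = [f"{c}_dup" for c in expr.columns]
        expr2 = pd.concat([expr, dup_expr], axis=1)
        ann2 = pd.concat(
            [ann, ann.set_axis([f"{c}_dup" for c in ann.index])]
        )
        dup = sd.summarize_by_cell_type(expr2, ann2)
        pd.testing.assert_frame_equal(base, dup)

    def test_columns_alphabetical_by_default(self, small_reference):
        expr, ann, _ = small_reference
        sig = sd.summarize_by_cell_type(expr, ann)
        assert list(sig.columns) == sorted(sig.columns)


class TestCollapseProbes:
    @pytest.fixture
    def probe_signature(self):
        sig = pd.DataFrame(
            {"T1": [5.0, 7.0, 1.0], "T2": [2.0, 3.0, 4.0]},
            index=pd.Index(["pA", "pB", "pC"], name="feature_id"),
        )
        source = pd.DataFrame(
            {
                "s1": [4.0, 6.0, 1.0],
                "s2": [5.0, 7.0, 2.0],
                "s3": [6.0, 8.0, 3.0],
            },
            index=sig.index,
        )
        return sig, source

    def test_highest_overall_median_probe_wins(self, probe_signature):
        sig, source = probe_signature
        pmap = pd.Series({"pA": "G1", "pB": "G1", "pC": "G2"})
        out = sd.collapse_probes(sig, source, pmap)
        # pB median 7.0 beats pA median 5.0 for gene G1
        assert out.loc["G1"].tolist() == sig.loc["pB"].tolist()
        assert out.loc["G2"].tolist() == sig.loc["pC"].tolist()

    def test_one_probe_per_gene_is_renaming(self, probe_signature):
        sig, source = probe_signature
        pmap = pd.Series({"pA": "GA", "pB": "GB", "pC": "GC"})
        out = sd.collapse_probes(sig, source, pmap)
        assert sorted(out.index) == ["GA", "GB", "GC"]
        np.testing.assert_allclose(
            out.loc[["GA", "GB", "GC"]].to_numpy(), sig.to_numpy()
        )

    def test_gene_count_equals_distinct_mapped_genes(self, probe_signature):
        sig, source = probe_signature
        pmap = pd.Series({"pA": "G1", "pB": "G1"})  # pC unmapped, dropped
        out = sd.collapse_probes(sig, source, pmap)
        assert len(out) == 1

    def test_tie_broken_by_lexicographic_probe_id(self, probe_signature):
        sig, source = probe_signature
        source = source.copy()
        source.loc["pB"] = source.loc["pA"]  # equal overall medians
        pmap = pd.Series({"pA": "G1", "pB": "G1"})
        out = sd.collapse_probes(sig, source, pmap)
        assert out.loc["G1"].tolist() == sig.loc["pA"].tolist()

    def test_empty_map_is_identity(self, probe_signature):
        sig, source = probe_signature
        out = sd.collapse_probes(sig, source, pd.Series(dtype=str))
        pd.testing.assert_frame_equal(out, sig)


class TestBuildSignature:
    def test_markers_peak_in_their_own_type(self, small_reference):
        expr, ann, markers = small_reference
        build = sd.build_signature(expr, ann)
        sig = build.signature
        in_sig = markers[markers["gene_id"].isin(sig.index)]
        assert len(in_sig) > 0
        argmax = sig.loc[in_sig["gene_id"]].idxmax(axis=1)
        assert (argmax.to_numpy() == in_sig["cell_type"].to_numpy()).all()

    def test_selected_kappa_not_above_any_grid_point(self, small_reference):
        expr, ann, _ = small_reference
        build = sd.build_signature(expr, ann)
        assert (build.scan.kappa_star <= build.scan.grid["kappa"] + 1e-12).all()

    def test_collapse_applied_when_map_given(self, small_reference):
        expr, ann, _ = small_reference
        pmap = pd.Series({g: f"GENE_{g[-4:]}" for g in expr.index})
        build = sd.build_signature(expr, ann, pmap)
        assert build.signature.index.str.startswith("GENE_").all()


class TestLdaEmbed:
    def test_two_identical_point_classes_collapse_and_separate(self):
        expr = pd.DataFrame(
            {
                "a1": [0.0, 0.0], "a2": [0.0, 0.0],
                "b1": [3.0, 1.0], "b2": [3.0, 1.0],
            },
            index=pd.Index(["f1", "f2"], name="feature_id"),
        )
        ann = pd.DataFrame(
            {"cell_type": ["A", "A", "B", "B"]}, index=pd.Index(expr.columns)
        )
        with pytest.warns(UserWarning, match="singular within-class"):
            coords = sd.lda_embed(expr, ann)
        assert coords.shape[1] == 1  # 2 classes -> 1 axis
        assert coords.loc["a1", "LD1"] == pytest.approx(coords.loc["a2", "LD1"])
        assert abs(coords.loc["a1", "LD1"] - coords.loc["b1", "LD1"]) > 1e-6

    def test_projection_collinear_with_closed_form_fisher_direction(self):
        rng = np.random.default_rng(8)
        a = rng.normal([0, 0], [1.0, 0.3], size=(40, 2))
        b = rng.normal([3, 1], [1.0, 0.3], size=(40, 2))
        X = np.vstack([a, b])
        expr = pd.DataFrame(
            X.T,
            index=pd.Index(["f1", "f2"], name="feature_id"),
            columns=[f"s{i}" for i in range(80)],
        )
        ann = pd.DataFrame(
            {"cell_type": ["A"] * 40 + ["B"] * 40}, index=pd.Index(expr.columns)
        )
        coords = sd.lda_embed(expr, ann)
        S_w = np.cov(a.T, ddof=1) * 39 + np.cov(b.T, ddof=1) * 39
        w = np.linalg.solve(S_w, a.mean(0) - b.mean(0))
        proj_oracle = (X - X.mean(0)) @ w
        r = np.corrcoef(coords["LD1"], proj_oracle)[0, 1]
        assert abs(r) > 1 - 1e-9

    def test_within_class_tighter_than_between_class(self, small_reference):
        expr, ann, _ = small_reference
        build = sd.build_signature(expr, ann)
        coords = sd.lda_embed(expr.loc[build.signature.index], ann, n_axes=3)
        labels = ann.loc[coords.index, "cell_type"].to_numpy()
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(coords.to_numpy()))
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert D[same & off_diag].mean() < D[~same].mean()

    def test_matches_sklearn_on_nonsingular_problem(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(m, 1.0, size=(30, 3)) for m in ([0, 0, 0], [4, 0, 1], [0, 4, 2])])
        expr = pd.DataFrame(
            X.T,
            index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
            columns=[f"s{i}" for i in range(90)],
        )
        ann = pd.DataFrame(
            {"cell_type": np.repeat(["A", "B", "C"], 30)}, index=pd.Index(expr.columns)
        )
        coords = sd.lda_embed(expr, ann, n_axes=2)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, ann["cell_type"])
        proj = ref.transform(X)
        for k in range(2):
            r = np.corrcoef(coords.iloc[:, k], proj[:, k])[0, 1]
            assert abs(r) > 0.999
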