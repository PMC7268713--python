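"""Extraction, retention, flagging, scoring, quantization, comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qmethod.factor import (
    Extraction,
    FlagSet,
    PipelineError,
    composite_reliability,
    correlate,
    distinguish_statements,
    eigenvalue_from_pct,
    factor_se,
    factor_weights,
    factor_zscores,
    flag_exemplars,
    loading_threshold,
    pca_extract,
    pct_from_eigenvalue,
    quantize_to_array,
    retain_factors,
    run_pipeline,
    scree_table,
    varimax,
)
from qmethod.grid import GridSpec
from qmethod.simulate import SimConfig, simulate_panel
from tests.conftest import panel_from_columns


class TestCorrelate:
    def test_identical_sorts_correlate_perfectly(self, fx):
        sorts = fx.factor_arrays[["factor_1", "factor_1"]].copy()
        sorts.columns = ["a", "b"]
        from qmethod.panel import QSortPanel

        R = correlate(QSortPanel(sorts, fx.grid))
        assert R.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_negation_correlates_minus_one(self, fx):
        col = fx.factor_arrays["factor_1"]
        sorts = pd.DataFrame({"a": col, "b": -col})
        from qmethod.panel import QSortPanel

        R = correlate(QSortPanel(sorts, fx.grid))
        assert R.loc["a", "b"] == pytest.approx(-1.0)

    def test_three_point_pearson_hand_value(self, tiny_grid):
        panel = panel_from_columns({"A": [-1, 0, 1], "B": [0, -1, 1]}, tiny_grid)
        R = correlate(panel)
        assert R.loc["A", "B"] == pytest.approx(0.5)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_symmetric_unit_diagonal(self, fx, method):
        sorts = fx.factor_arrays.copy()
        from qmethod.panel import QSortPanel

        R = correlate(QSortPanel(sorts, fx.grid), method).to_numpy()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0)

    def test_single_sort_rejected(self, fx):
        from qmethod.panel import QSortPanel

        panel = QSortPanel(fx.factor_arrays[["factor_1"]], fx.grid)
        with pytest.raises(PipelineError, match="two sorts"):
            correlate(panel)


class TestExtraction:
    def test_identity_spectrum(self):
        R = pd.DataFrame(np.eye(4))
        ext = pca_extract(R, 4)
        assert np.allclose(ext.eigenvalues, 1.0)

    def test_equicorrelation_closed_form(self):
        rho = 0.5
        R = pd.DataFrame(np.full((3, 3), rho) + (1 - rho) * np.eye(3))
        ext = pca_extract(R, 3)
        assert ext.eigenvalues == pytest.approx([2.0, 0.5, 0.5])

    def test_trace_conservation_on_panel(self, fx):
        cfg = SimConfig(grid=fx.grid, K=2, n_per_factor=[3, 3], noise_sd=1.0, seed=5)
        panel, _ = simulate_panel(cfg)
        ext = pca_extract(correlate(panel))
        assert ext.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_loading_column_norm_equals_eigenvalue(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        R = pd.DataFrame(np.corrcoef(X, rowvar=False))
        ext = pca_extract(R, 3)
        norms = (ext.loadings.to_numpy() ** 2).sum(axis=0)
        assert norms == pytest.approx(ext.eigenvalues[:3])

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        R = pd.DataFrame(np.corrcoef(X, rowvar=False))
        L = pca_extract(R, 4).loadings.to_numpy()
        for j in range(4):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_asymmetric_rejected(self):
        R = pd.DataFrame([[1.0, 0.9], [0.1, 1.0]])
        with pytest.raises(PipelineError, match="symmetric"):
            pca_extract(R, 1)


class TestEigenvaluePct:
    @pytest.mark.parametrize(
        "pct,n,expected", [(10, 110, 11.0), (0, 17, 0.0), (100, 42, 42.0)]
    )
    def test_formula(self, pct, n, expected):
        assert eigenvalue_from_pct(pct, n) == expected

    @given(st.floats(0, 100, allow_nan=False), st.integers(1, 500))
    def test_exact_inverse(self, pct, n):
        assert pct_from_eigenvalue(eigenvalue_from_pct(pct, n), n) == pytest.approx(pct, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            eigenvalue_from_pct(101, 10)


class TestScree:
    def test_arithmetic(self):
        t = scree_table([2.0, 1.0, 1.0], n_sorts=4)
        assert t["pct_variance"].tolist() == [50.0, 25.0, 25.0]
        assert t["cumulative_pct"].tolist() == [50.0, 75.0, 100.0]

    def test_single_eigenvalue(self):
        t = scree_table([1.0], n_sorts=1)
        assert len(t) == 1 and t["cumulative_pct"].iloc[0] == 100.0

    def test_cumulative_monotone(self, rng):
        ev = np.sort(rng.uniform(0, 5, 10))[::-1]
        t = scree_table(ev)
        assert (np.diff(t["cumulative_pct"]) >= -1e-12).all()

    def test_ascending_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            scree_table([1.0, 2.0])


class TestLoadingThreshold:
    def test_study_threshold_rounds_to_point_four(self):
        t = loading_threshold(42, 0.01)
        assert t == pytest.approx(2.58 / np.sqrt(42))
        assert round(t, 1) == 0.4

    def test_five_percent_level(self):
        assert loading_threshold(42, 0.05) == pytest.approx(0.3024, abs=5e-5)

    def test_hundred_statements(self):
        assert loading_threshold(100, 0.01) == pytest.approx(0.258)

    def test_unsupported_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            loading_threshold(42, 0.1)


def _extraction(eigenvalues, loadings):
    ev = np.asarray(eigenvalues, dtype=float)
    L = pd.DataFrame(np.asarray(loadings, dtype=float))
    return Extraction(ev, L, len(L))


class TestRetention:
    def test_both_rules_pass_gives_two(self):
        # two clean blocks of three loaders each, third eigenvalue below 1
        L = np.zeros((6, 2))
        L[:3, 0] = 0.8
        L[3:, 1] = 0.8
        ext = _extraction([3.2, 1.5, 0.8, 0.3, 0.1, 0.1], L)
        r = retain_factors(ext, threshold=0.4)
        assert r.k == 2

    def test_two_exemplar_rule_binds(self):
        # factor 2 carried by a single loader: eigenvalue passes, exemplars fail
        L = np.zeros((6, 2))
        L[:5, 0] = 0.8
        L[5, 1] = 0.9
        ext = _extraction([3.2, 1.1, 0.4, 0.2, 0.1, 0.0], L)
        r = retain_factors(ext, threshold=0.4)
        assert r.k == 1
        assert any("fewer than two" in line for line in r.rationale)

    def test_eigenvalue_rule_binds(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.8
        L[3:, 1] = 0.8
        ext = _extraction([3.2, 0.9, 0.5, 0.2, 0.1, 0.1], L)
        assert retain_factors(ext, threshold=0.4).k == 1

    def test_no_factor_passes_is_an_error(self):
        L = np.full((4, 2), 0.1)
        ext = _extraction([0.9, 0.8, 0.2, 0.1], L)
        with pytest.raises(PipelineError, match="inspect"):
            retain_factors(ext, threshold=0.4)

    def test_five_prototype_simulation_recovers_five(self, fx):
        cfg = SimConfig(grid=fx.grid, K=5, n_per_factor=[8] * 5, noise_sd=0.3, seed=17)
        panel, _ = simulate_panel(cfg)
        sol = run_pipeline(panel)
        assert sol.k == 5


class TestFlagging:
    def _rotated(self, rows):
        from qmethod.factor import RotatedLoadings

        L = pd.DataFrame(np.asarray(rows, dtype=float),
                         index=[f"p{i}" for i in range(len(rows))])
        L.columns = [f"F{j + 1}" for j in range(L.shape[1])]
        return RotatedLoadings(L, np.eye(L.shape[1]), False, True, 1, 0.0)

    def test_pure_loader_flagged(self):
        fs = flag_exemplars(self._rotated([[0.65, 0.10]]), 0.4)
        f = fs.flags[0]
        assert (f.factor, f.sign, f.status) == (0, 1, "flagged")

    def test_confounded_unflagged(self):
        fs = flag_exemplars(self._rotated([[0.45, 0.43]]), 0.4)
        assert fs.flags[0].status == "confounded"
        assert fs.flags[0].factor is None

    def test_negative_loader_flagged_with_sign(self):
        fs = flag_exemplars(self._rotated([[-0.50, 0.10]]), 0.4)
        f = fs.flags[0]
        assert (f.factor, f.sign) == (0, -1)

    def test_non_significant_unflagged(self):
        fs = flag_exemplars(self._rotated([[0.2, 0.3]]), 0.4)
        assert fs.flags[0].status == "non-significant"

    def test_pqmethod_rule_additionally_requires_dominance(self):
        # significant on F1 only, but squared loading below half communality
        rows = [[0.41, 0.39, 0.39]]
        pure = flag_exemplars(self._rotated(rows), 0.4, rule="pure")
        pq = flag_exemplars(self._rotated(rows), 0.4, rule="pqmethod")
        assert pure.flags[0].status == "flagged"
        assert pq.flags[0].status == "non-significant"

    @given(
        st.lists(
            st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=3),
            min_size=1,
            max_size=12,
        )
    )
    def test_flag_purity_property(self, rows):
        fs = flag_exemplars(self._rotated(rows), 0.4)
        for f, row in zip(fs.flags, rows):
            above = sum(abs(x) >= 0.4 for x in row)
            if f.status == "flagged":
                assert above == 1
            elif f.status == "confounded":
                assert above >= 2
            else:
                assert above == 0


class TestWeightsAndScores:
    @pytest.mark.parametrize(
        "f,w", [(0.0, 0.0), (0.5, 0.5 / 0.75), (-0.5, -0.5 / 0.75)]
    )
    def test_weight_formula(self, f, w):
        assert factor_weights(f) == pytest.approx(w)

    def test_extreme_loading_clamped(self):
        assert np.isfinite(factor_weights(1.0))
        assert factor_weights(1.0) == pytest.approx(factor_weights(0.999))

    def _flags(self, entries):
        from qmethod.factor import Flag

        return FlagSet(
            [Flag(pid, j, 1 if load >= 0 else -1, load, "flagged") for pid, j, load in entries],
            0.4,
            "pure",
        )

    def test_single_exemplar_reproduces_its_sort(self, fx):
        from qmethod.panel import QSortPanel

        sorts = fx.factor_arrays[["factor_1", "factor_2"]].copy()
        sorts.columns = ["a", "b"]
        panel = QSortPanel(sorts, fx.grid)
        flags = self._flags([("a", 0, 0.9)])
        scores = factor_zscores(panel, flags, 1)
        arr = quantize_to_array(scores.zscores["F1"], fx.grid)
        assert (arr.to_numpy() == fx.factor_arrays["factor_1"].to_numpy()).all()

    def test_duplicate_exemplars_change_nothing(self, fx):
        from qmethod.panel import QSortPanel

        sorts = fx.factor_arrays[["factor_1", "factor_1"]].copy()
        sorts.columns = ["a", "b"]
        panel = QSortPanel(sorts, fx.grid)
        one = factor_zscores(panel, self._flags([("a", 0, 0.7)]), 1)
        two = factor_zscores(panel, self._flags([("a", 0, 0.7), ("b", 0, 0.5)]), 1)
        assert np.allclose(one.zscores.to_numpy(), two.zscores.to_numpy())

    def test_weighted_sum_matches_brute_force(self, small_grid):
        cols = {
            "a": [2, 1, 1, 0, 0, 0, -1, -1, -2],
            "b": [0, 2, -1, 1, 0, -2, 1, 0, -1],
            "c": [-2, 0, 2, -1, 1, 0, 0, 1, -1],
        }
        panel = panel_from_columns(cols, small_grid)
        loads = {"a": 0.5, "b": 0.33333333, "c": 0.2}  # w ≈ 0.667, 0.375, 0.208
        flags = self._flags([(p, 0, f) for p, f in loads.items()])
        scores = factor_zscores(panel, flags, 1)
        raw = np.zeros(9)
        for p, f in loads.items():
            raw += (f / (1 - f**2)) * np.array(cols[p], dtype=float)
        expected = (raw - raw.mean()) / raw.std()
        assert np.allclose(scores.zscores["F1"].to_numpy(), expected)

    def test_zscores_standardized(self, fx):
        cfg = SimConfig(grid=fx.grid, K=3, n_per_factor=[6] * 3, noise_sd=0.8, seed=23)
        panel, _ = simulate_panel(cfg)
        sol = run_pipeline(panel)
        Z = sol.scores.zscores.to_numpy()
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-8)

    def test_factor_without_exemplars_is_an_error(self, fx):
        from qmethod.panel import QSortPanel

        sorts = fx.factor_arrays[["factor_1", "factor_2"]].copy()
        sorts.columns = ["a", "b"]
        panel = QSortPanel(sorts, fx.grid)
        with pytest.raises(PipelineError, match="no included exemplars"):
            factor_zscores(panel, self._flags([("a", 0, 0.9)]), 2)


class TestQuantize:
    def test_order_respecting_fill(self):
        grid = GridSpec({-1: 1, 0: 2, 1: 1})
        arr = quantize_to_array(np.array([0.9, 0.1, -0.2, -1.3]), grid)
        assert arr.tolist() == [1, 0, 0, -1]

    def test_extremes_get_extreme_ranks(self, fx, rng):
        z = pd.Series(rng.normal(size=42), index=range(1, 43))
        arr = quantize_to_array(z, fx.grid)
        assert arr.loc[z.idxmax()] == 5
        assert arr.loc[z.idxmin()] == -5

    def test_tie_broken_by_ascending_statement_id(self):
        grid = GridSpec({-1: 1, 0: 2, 1: 1})
        z = pd.Series({7: 0.5, 9: 0.5, 3: -0.1, 11: -0.9})
        arr = quantize_to_array(z, grid)
        assert arr.loc[7] == 1 and arr.loc[9] == 0

    @given(st.lists(st.floats(-3, 3, allow_nan=False, width=32), min_size=9, max_size=9))
    def test_always_conforms_to_grid(self, zs):
        from qmethod.grid import derive_grid

        grid = GridSpec({-2: 1, -1: 2, 0: 3, 1: 2, 2: 1})
        arr = quantize_to_array(np.array(zs), grid)
        assert derive_grid(arr).capacity == grid.capacity


class TestDistinguish:
    def test_reliability_arithmetic_for_19_exemplars(self):
        assert composite_reliability(19) == pytest.approx(0.80 * 19 / (1 + 18 * 0.80))
        assert composite_reliability(19) == pytest.approx(0.987, abs=5e-4)
        assert factor_se(19) == pytest.approx(0.114, abs=5e-4)

    def _scores(self, Z, counts):
        from qmethod.factor import FactorScores

        z = pd.DataFrame(
            np.asarray(Z, dtype=float),
            index=pd.Index(range(1, len(Z) + 1), name="statement_id"),
            columns=[f"F{j + 1}" for j in range(len(Z[0]))],
        )
        return FactorScores(z, counts, [{}] * len(counts))

    def test_identical_zvectors_all_consensus(self, rng):
        col = rng.normal(size=10)
        scores = self._scores(np.column_stack([col, col]), [5, 5])
        table = distinguish_statements(scores)
        assert table["consensus"].all()

    def test_large_p_and_unit_gap_distinguishes_everywhere(self):
        z1 = np.linspace(-1, 1, 10)
        scores = self._scores(np.column_stack([z1, z1 + 2.0]), [500, 500])
        table = distinguish_statements(scores)
        assert (table["distinguishes_F1"] == "**").all()
        assert (table["distinguishes_F2"] == "**").all()
        assert not table["consensus"].any()

    def test_zero_exemplars_rejected(self):
        with pytest.raises(ValueError):
            composite_reliability(0)


class TestPipeline:
    def test_noiseless_recovery_is_exact(self, fx):
        from qmethod.simulate import recovery_report

        cfg = SimConfig(grid=fx.grid, K=3, n_per_factor=[6] * 3, noise_sd=0.0, seed=2)
        panel, truth = simulate_panel(cfg)
        sol = run_pipeline(panel)
        assert sol.k == 3
        assert recovery_report(sol, truth)["exact_recovery"]

    def test_two_identical_sorts_fixed_k1(self, fx):
        from qmethod.factor import PipelineConfig
        from qmethod.panel import QSortPanel

        sorts = fx.factor_arrays[["factor_3", "factor_3"]].copy()
        sorts.columns = ["a", "b"]
        panel = QSortPanel(sorts, fx.grid)
        sol = run_pipeline(panel, PipelineConfig(retention=1, n_extract=1))
        assert sol.k == 1
        assert (sol.arrays["F1"].to_numpy() == fx.factor_arrays["factor_3"].to_numpy()).all()

    def test_solution_records_config_and_rationale(self, fx):
        cfg = SimConfig(grid=fx.grid, K=2, n_per_factor=[5, 5], noise_sd=0.5, seed=9)
        panel, _ = simulate_panel(cfg)
        sol = run_pipeline(panel)
        assert sol.config.corr_method == "pearson"
        assert sol.retention.rationale
        assert sol.threshold == pytest.approx(loading_threshold(42, 0.01))
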