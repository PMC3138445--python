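import itertools

import numpy as np
import pytest

import drugcombo as dc
from drugcombo.errors import RegressorCountError
from drugcombo.interactions import SubsetRegressionResult


def naive_best_subsets(X, y):
    """Independent oracle: per-size minimum-RSS subset by direct lstsq."""
    m, p = X.shape
    out = {}
    for size in range(1, p + 1):
        best = None
        for subset in itertools.combinations(range(p), size):
            A = np.column_stack([np.ones(m), X[:, subset]])
            beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ beta) ** 2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, subset)
        out[size] = best
    return out


@pytest.fixture(scope="module")
def toy_table(panel4, grid4):
    cancer, _ = dc.default_two_celltype_scenario()
    return dc.simulate_measurements(cancer, grid4, sigma=0.05, seed=21)


class TestInteractionDesign:
    def test_four_drug_design_has_15_columns(self, toy_table):
        X, y = dc.build_interaction_design(toy_table, "cancer-like")
        assert X.shape == (len(toy_table), 15)
        assert len(y) == len(toy_table)

    def test_zero_combination_gives_zero_regressor_row(self, toy_table):
        X, _ = dc.build_interaction_design(toy_table, "cancer-like")
        zero_rows = np.flatnonzero((toy_table.conc == 0).all(axis=1))
        assert np.all(X[zero_rows] == 0)

    def test_first_pairwise_column_is_product_of_first_two(self, toy_table):
        X, _ = dc.build_interaction_design(toy_table, "cancer-like")
        assert X[:, 4] == pytest.approx(X[:, 0] * X[:, 1])

    def test_pairwise_term_count(self, panel4):
        names = dc.term_names(panel4.drugs)
        assert len(names) == 15
        assert sum(n.count("*") == 1 for n in names) == 6
        assert sum(n.count("*") == 2 for n in names) == 4
        assert sum(n.count("*") == 3 for n in names) == 1

    def test_non_four_drug_panel_rejected(self, panel3, grid3, truth3):
        table = dc.simulate_measurements(truth3, grid3, sigma=0.0, seed=0)
        with pytest.raises(RegressorCountError):
            dc.build_interaction_design(table, "cancer-like")
        X, _ = dc.build_interaction_design(table, "cancer-like", allow_any_n=True)
        assert X.shape[1] == 2**3 - 1


class TestBestSubsetRegression:
    def test_matches_naive_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(40, 5))
        y = rng.uniform(0, 1, size=40)
        result = dc.best_subset_regression(X, y)
        oracle = naive_best_subsets(X, y)
        assert result.n_models_examined == 2**5 - 1
        for size in range(1, 6):
            assert result.subsets[size] == oracle[size][1]
            assert result.rss[size] == pytest.approx(oracle[size][0], abs=1e-9)

    def test_planted_three_term_model_recovered_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, size=(60, 8))
        planted = (1, 4, 6)
        y = 0.5 + 0.8 * X[:, 1] - 0.6 * X[:, 4] + 0.4 * X[:, 6]
        result = dc.best_subset_regression(X, y)
        assert result.subsets[3] == planted
        assert result.rss[3] < 1e-10

    def test_rss_nonincreasing_and_full_size_equals_ols(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, size=(50, 6))
        y = rng.uniform(0, 1, size=50)
        result = dc.best_subset_regression(X, y)
        rss = [result.rss[s] for s in sorted(result.rss)]
        assert np.all(np.diff(rss) <= 1e-12)
        A = np.column_stack([np.ones(50), X])
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        assert result.rss[6] == pytest.approx(float(np.sum((y - A @ beta) ** 2)))

    def test_recovered_coefficient_signs_match_planted_signs(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(80, 6))
        signs = {0: +1, 2: -1, 5: +1}
        y = 0.3 + 0.5 * X[:, 0] - 0.7 * X[:, 2] + 0.4 * X[:, 5]
        result = dc.best_subset_regression(X, y)
        terms = result.selected_terms(3)
        assert set(terms) == set(signs)
        for j, s in signs.items():
            assert np.sign(terms[j]) == s

    def test_scale_invariance_of_selection_and_signs(self, panel4, grid4):
        cancer, _ = dc.default_two_celltype_scenario()
        table = dc.simulate_measurements(cancer, grid4, sigma=0.02, seed=13)
        X1, y = dc.build_interaction_design(table, "cancer-like")
        # rescale one drug's concentrations (and its levels) by a constant
        factor = 7.3
        panel_s = dc.DrugPanel(
            drugs=panel4.drugs,
            levels=tuple(
                tuple(v * (factor if i == 2 else 1.0) for v in lv)
                for i, lv in enumerate(panel4.levels)
            ),
        )
        conc_s = table.conc.copy()
        conc_s[:, 2] *= factor
        table_s = dc.ResponseTable(
            panel=panel_s, conc=conc_s, responses={"cancer-like": y.copy()}
        )
        X2, _ = dc.build_interaction_design(table_s, "cancer-like")
        assert X2 == pytest.approx(X1)
        r1 = dc.best_subset_regression(X1[:400], y[:400])
        r2 = dc.best_subset_regression(X2[:400], y[:400])
        for s in r1.subsets:
            assert r1.subsets[s] == r2.subsets[s]


class TestModelSizeSelection:
    @staticmethod
    def result_from_rss(rss_seq):
        return SubsetRegressionResult(
            p=len(rss_seq),
            subsets={i + 1: tuple(range(i + 1)) for i in range(len(rss_seq))},
            rss={i + 1: float(v) for i, v in enumerate(rss_seq)},
            coefs={i + 1: np.zeros(i + 2) for i in range(len(rss_seq))},
            n_models_examined=2 ** len(rss_seq) - 1,
        )

    def test_flat_tail_selects_elbow(self):
        r = self.result_from_rss([100, 50, 25, 25, 25])
        assert dc.select_model_size(r, tau=0.01) == 3

    def test_hand_evaluated_sequence(self):
        r = self.result_from_rss([100, 50, 25, 24.9, 24.89])
        assert dc.select_model_size(r, tau=0.01) == 3

    def test_huge_tau_selects_single_term(self):
        r = self.result_from_rss([100, 50, 25, 12])
        assert dc.select_model_size(r, tau=0.9) == 1

    def test_perfect_fit_short_circuits(self):
        r = self.result_from_rss([10, 0.0, 0.0])
        assert dc.select_model_size(r) == 2


class TestClassification:
    def test_disjoint_and_identical_selected_sets(self):
        a = {0: 0.5, 3: -0.2}
        b = {1: 0.1, 4: 0.2}
        cls = dc.classify_interactions(a, b)
        assert cls.common == ()
        assert cls.a_only == (0, 3) and cls.b_only == (1, 4)
        assert cls.signs_a == {0: 1, 3: -1}
        same = dc.classify_interactions(a, dict(a))
        assert same.common == (0, 3) and same.a_only == () and same.b_only == ()
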