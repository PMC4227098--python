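import numpy as np
import pytest
from scipy.stats import kstest

from dsim.datamodel import GroupContrast, OmicsMatrix, WindowMap
from dsim.permutation import (
    PermutationError,
    PermutationPValueMatrix,
    draw_permutations,
    empirical_pvalue,
    meinshausen_adjust,
    permuted_pvalues,
)
from dsim.ridge import select_lambda


def _setup(rng, m=4, p=16, n=20, window=4):
    labels = np.r_[np.ones(n // 2, int), 2 * np.ones(n - n // 2, int)]
    con = GroupContrast(labels=labels)
    X = OmicsMatrix(
        rng.normal(size=(p, n)),
        [f"x{k}" for k in range(p)],
        [f"s{j}" for j in range(n)],
        "covariate",
    )
    windows = WindowMap(
        {f"y{i}": [f"x{k}" for k in range(i * window, (i + 1) * window)] for i in range(m)}
    )
    R = rng.normal(size=(m, n))
    return R, X, windows, con


class TestEmpiricalPvalue:
    def test_observed_smallest(self):
        assert empirical_pvalue([0.001, 0.5, 0.6, 0.7]) == pytest.approx(1 / 4)

    def test_observed_is_one(self):
        assert empirical_pvalue([1.0, 0.1, 0.2, 0.3, 0.4]) == 1.0

    def test_hand_count(self):
        assert empirical_pvalue([0.5, 0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.6)

    def test_lower_bound(self):
        row = np.r_[0.0, np.linspace(0.1, 0.9, 10)]
        assert empirical_pvalue(row) == pytest.approx(1 / 11)


class TestPermutedPvalues:
    def test_identity_permutation_duplicates_observed(self, rng, monkeypatch):
        R, X, windows, con = _setup(rng)
        monkeypatch.setattr(
            "dsim.permutation.draw_permutations",
            lambda n, B, seed: np.tile(np.arange(n), (B, 1)),
        )
        P = permuted_pvalues(R, X, windows, con, B=1, seed=0,
                             dep_probe_ids=[f"y{i}" for i in range(4)])
        np.testing.assert_array_equal(P.values[:, 1], P.values[:, 0])

    def test_deterministic_given_seed(self, rng):
        R, X, windows, con = _setup(rng)
        ids = [f"y{i}" for i in range(4)]
        P1 = permuted_pvalues(R, X, windows, con, B=5, seed=42, dep_probe_ids=ids)
        P2 = permuted_pvalues(R, X, windows, con, B=5, seed=42, dep_probe_ids=ids)
        np.testing.assert_array_equal(P1.values, P2.values)

    def test_longer_run_extends_same_permutations(self):
        a = draw_permutations(10, 3, seed=9)
        b = draw_permutations(10, 6, seed=9)
        np.testing.assert_array_equal(a, b[:3])

    def test_empty_window_row_of_ones(self, rng):
        R, X, windows, con = _setup(rng)
        windows.windows["y0"] = []
        P = permuted_pvalues(R, X, windows, con, B=3, seed=0,
                             dep_probe_ids=[f"y{i}" for i in range(4)])
        np.testing.assert_array_equal(P.values[0], np.ones(4))

    def test_null_pooled_pvalues_uniform(self, rng):
        R, X, windows, con = _setup(rng, m=20, p=60, n=24, window=3)
        P = permuted_pvalues(R, X, windows, con, B=200, seed=1,
                             dep_probe_ids=[f"y{i}" for i in range(20)])
        stat = kstest(P.permuted.ravel(), "uniform").statistic
        assert stat < 0.05

    def test_b_below_one_errors(self, rng):
        R, X, windows, con = _setup(rng)
        with pytest.raises(PermutationError):
            permuted_pvalues(R, X, windows, con, B=0, seed=0)

    def test_recompute_path_close_to_reuse_on_null(self, rng):
        # both permutation-null constructions must be valid; on pure noise
        # their p-value distributions agree coarsely
        R, X, windows, con = _setup(rng, m=2, n=16, p=8, window=4)
        ids = ["y0", "y1"]
        y_all = rng.normal(size=(2, 16))
        lam = np.empty(2)
        Xs = X.samples_view()
        widx = windows.indices(X.probe_ids)
        for i, pid in enumerate(ids):
            fit = select_lambda(y_all[i], Xs[:, widx[pid]])
            lam[i] = fit.lambda_star
            R[i] = fit.residuals
        P_slow = permuted_pvalues(R, X, windows, con, B=40, seed=3, dep_probe_ids=ids,
                                  recompute_residuals=True, y_all=y_all, lambda_stars=lam)
        P_fast = permuted_pvalues(R, X, windows, con, B=40, seed=3, dep_probe_ids=ids)
        np.testing.assert_array_equal(P_slow.values[:, 0], P_fast.values[:, 0])
        assert abs(P_slow.permuted.mean() - P_fast.permuted.mean()) < 0.25

    def test_requires_lambda_for_recompute(self, rng):
        R, X, windows, con = _setup(rng)
        with pytest.raises(PermutationError):
            permuted_pvalues(R, X, windows, con, B=2, seed=0, recompute_residuals=True)


def _pmat(obs, perm_cols, seed=0):
    values = np.column_stack([obs] + list(perm_cols))
    return PermutationPValueMatrix(
        values=values,
        probe_ids=[f"p{i}" for i in range(len(obs))],
        permutation_seed=seed,
        B=len(perm_cols),
    )


class TestMeinshausenAdjust:
    def test_hand_instance(self):
        P = _pmat(
            obs=[0.01, 0.50, 0.90],
            perm_cols=[[0.30, 0.60, 0.95], [0.20, 0.70, 0.80]],
        )
        res = meinshausen_adjust(P, confidence_alpha=0.5, level=0.05)
        # independently derived: V_b(0.01)=(0,0) -> Vbar=0; V_b(0.50)=(1,1)
        # -> Vbar=1; V_b(0.90)=(2,3) -> 1st order statistic = 2
        np.testing.assert_allclose(res.adjusted, [0.0, 0.5, 2 / 3])

    def test_all_observed_below_null(self):
        rng = np.random.default_rng(0)
        obs = np.full(5, 1e-6)
        perm = [rng.uniform(0.2, 1.0, size=5) for _ in range(10)]
        res = meinshausen_adjust(_pmat(obs, perm), confidence_alpha=0.05, level=0.05)
        np.testing.assert_array_equal(res.adjusted, np.zeros(5))
        assert res.selected.all()

    def test_pure_null_rarely_selects(self):
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            values = rng.uniform(size=(10, 41))
            P = PermutationPValueMatrix(
                values=values, probe_ids=[f"p{i}" for i in range(10)],
                permutation_seed=seed, B=40,
            )
            res = meinshausen_adjust(P, confidence_alpha=0.05, level=0.01)
            hits += res.selected.any()
        assert hits / reps <= 0.05 + 0.03

    def test_monotone_in_observed_rank(self, rng):
        values = rng.uniform(size=(30, 21))
        P = PermutationPValueMatrix(
            values=values, probe_ids=[f"p{i}" for i in range(30)],
            permutation_seed=0, B=20,
        )
        res = meinshausen_adjust(P)
        order = np.argsort(values[:, 0])
        assert np.all(np.diff(res.adjusted[order]) >= -1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.uniform(size=(12, 26))
        P1 = PermutationPValueMatrix(
            values=values, probe_ids=[f"p{i}" for i in range(12)],
            permutation_seed=0, B=25,
        )
        P2 = PermutationPValueMatrix(
            values=values**3, probe_ids=[f"p{i}" for i in range(12)],
            permutation_seed=0, B=25,
        )
        r1 = meinshausen_adjust(P1)
        r2 = meinshausen_adjust(P2)
        np.testing.assert_allclose(r1.adjusted, r2.adjusted)

    def test_tied_observed_share_larger_value(self):
        P = _pmat(
            obs=[0.5, 0.5, 0.1],
            perm_cols=[[0.2, 0.6, 0.9], [0.3, 0.4, 0.8], [0.25, 0.45, 0.7]],
        )
        res = meinshausen_adjust(P, confidence_alpha=0.34, level=0.05)
        assert res.adjusted[0] == res.adjusted[1]

    def test_selected_consistent_with_level(self, rng):
        values = rng.uniform(size=(15, 21))
        P = PermutationPValueMatrix(
            values=values, probe_ids=[f"p{i}" for i in range(15)],
            permutation_seed=0, B=20,
        )
        res = meinshausen_adjust(P, level=0.3)
        np.testing.assert_array_equal(res.selected, res.adjusted <= 0.3)

    def test_bad_alpha_rejected(self):
        P = _pmat([0.5], [[0.5]])
        with pytest.raises(PermutationError):
            meinshausen_adjust(P, confidence_alpha=1.5)


class TestPValueMatrixContainer:
    def test_shape_validation(self):
        with pytest.raises(PermutationError):
            PermutationPValueMatrix(np.zeros((2, 3)), ["a"], 0, 2)

    def test_range_validation(self):
        with pytest.raises(PermutationError):
            PermutationPValueMatrix(np.full((1, 3), 1.5), ["a"], 0, 2)

    def test_shared_permutations_required(self):
        with pytest.raises(PermutationError):
            PermutationPValueMatrix(
                np.zeros((1, 3)), ["a"], 0, 2, shared_permutations=False
            )
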