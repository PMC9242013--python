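import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrierkit import learn as L
from barrierkit.fixtures import generate_feature_table
from barrierkit.learn import (
    FittedModel,
    GuardedMatrix,
    LeakageError,
    ModelSpec,
    mae,
)


def ridge_spec(mode="direct", seed=0, alphas=(1e-6,)):
    return ModelSpec(family="Ridge", grid={"alpha": list(alphas)}, mode=mode, seed=seed)


@pytest.fixture(scope="module")
def table1000():
    table, truth = generate_feature_table(n=1000, n_features=20, seed=42)
    return table, truth


class TestSplit:
    def test_paper_split_sizes(self, table1000):
        table, _ = table1000
        train, test = L.split(table, 0.2, seed=0)
        assert len(train) == 800 and len(test) == 200

    def test_deterministic(self, table1000):
        table, _ = table1000
        assert L.split(table, 0.2, seed=3) == L.split(table, 0.2, seed=3)
        assert L.split(table, 0.2, seed=3) != L.split(table, 0.2, seed=4)

    def test_partition(self, table1000):
        table, _ = table1000
        train, test = L.split(table, 0.2, seed=1)
        assert set(train) | set(test) == set(table.frame.index)
        assert set(train) & set(test) == set()

    def test_literature_rows_excluded(self):
        table, _ = generate_feature_table(n=100, seed=0, n_literature=10)
        train, test = L.split(table, 0.2, seed=0)
        lit = set(table.rows_with_tag("literature"))
        assert lit.isdisjoint(train) and lit.isdisjoint(test)
        assert len(train) + len(test) == 90

    def test_too_few_train_rows(self):
        table, _ = generate_feature_table(n=6, seed=0)
        with pytest.raises(ValueError, match="5"):
            L.split(table, 0.5, seed=0)

    def test_fraction_bounds(self, table1000):
        with pytest.raises(ValueError):
            L.split(table1000[0], 1.0, seed=0)


class TestMAE:
    def test_perfect_prediction(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_two_point_arithmetic(self):
        m, se = mae([1.0, 3.0], [0.0, 0.0])
        assert m == pytest.approx(2.0)
        assert se == pytest.approx(1.0)  # SD({1,3})/sqrt(2) = sqrt(2)/sqrt(2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])

    @given(
        shift=st.floats(min_value=-100.0, max_value=100.0),
        data=st.lists(
            st.tuples(
                st.floats(min_value=-50, max_value=50),
                st.floats(min_value=-50, max_value=50),
            ),
            min_size=2,
            max_size=30,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, shift, data):
        pred = np.array([p for p, _ in data])
        truth = np.array([t for _, t in data])
        m0, se0 = mae(pred, truth)
        m1, se1 = mae(pred + shift, truth + shift)
        assert m1 == pytest.approx(m0, abs=1e-9)
        assert se1 == pytest.approx(se0, abs=1e-9)

    def test_half_normal_identity(self, rng):
        sigma = 2.0
        errs = np.abs(rng.normal(0, sigma, 10_000))
        m, se = mae(errs, np.zeros_like(errs))
        assert m == pytest.approx(sigma * np.sqrt(2 / np.pi), abs=3 * se)


class TestGuard:
    def test_blocks_forbidden_rows(self, rng):
        g = GuardedMatrix(rng.normal(size=(10, 3)), allowed_positions=range(8))
        g.rows([0, 5, 7])
        with pytest.raises(LeakageError):
            g.rows([8])

    def test_selection_cannot_touch_test_rows(self, table1000):
        table, _ = table1000
        x = table.frame.to_numpy()
        y = table.target.to_numpy()
        guarded = GuardedMatrix(x, allowed_positions=range(800))
        with pytest.raises(LeakageError):
            L.select_features(
                guarded, y, list(table.frame.columns),
                train_positions=list(range(700, 900)),  # includes test rows
                spec=ridge_spec(), max_features=1,
            )


class TestSelectFeatures:
    def test_planted_signal_selected_first(self):
        wins = 0
        for seed in range(50):
            table, _ = generate_feature_table(
                n=120, n_features=20, active=(3,), coefficients=(2.0,),
                sigma=0.5, seed=seed,
            )
            x = table.frame.drop(columns="barrier").to_numpy()
            y = table.target.to_numpy() - table.frame["barrier"].to_numpy()
            names = [c for c in table.frame.columns if c != "barrier"]
            got = L.select_features(
                x, y, names, list(range(120)), ridge_spec(seed=seed),
                k_folds=5, max_features=1,
            )
            wins += got == ["f03"]
        assert wins >= 40

    def test_infinite_tol_selects_one(self, table1000):
        table, _ = table1000
        x = table.frame.to_numpy()
        y = table.target.to_numpy()
        got = L.select_features(
            x, y, list(table.frame.columns), list(range(200)),
            ridge_spec(), tol=np.inf,
        )
        assert len(got) == 1


class TestTuneAndFit:
    def test_delta_with_perfect_baseline(self):
        # DFT barrier equals the SQM barrier: delta target is exactly zero
        table, truth = generate_feature_table(
            n=200, n_features=5, active=(0,), coefficients=(0.0,), sigma=0.0, seed=1
        )
        x = table.frame.to_numpy()
        y = table.target.to_numpy()
        base = table.frame["barrier"].to_numpy()
        names = list(table.frame.columns)
        model, cv = L.tune_and_fit(
            x, y, names[:2], names, list(range(150)),
            ridge_spec(mode="delta"), baseline=base,
        )
        pred = model.predict(x[150:, :2], baseline=base[150:])
        assert np.abs(pred - y[150:]).mean() < 1e-6

    def test_direct_and_delta_share_units(self):
        table, _ = generate_feature_table(n=200, n_features=5, active=(0,), seed=2)
        x = table.frame.to_numpy()
        y = table.target.to_numpy()
        base = table.frame["barrier"].to_numpy()
        names = list(table.frame.columns)
        out = {}
        for mode in ("direct", "delta"):
            model, _ = L.tune_and_fit(
                x, y, names, names, list(range(150)),
                ridge_spec(mode=mode), baseline=base,
            )
            out[mode] = model.predict(x[150:], baseline=base[150:])
        # both predict in original barrier units: same order of magnitude as y
        for mode, pred in out.items():
            assert np.corrcoef(pred, y[150:])[0, 1] > 0.9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ModelSpec(family="Ridge", grid={"alpha": []})

    def test_kernel_required(self):
        with pytest.raises(ValueError, match="kernel"):
            ModelSpec(family="SVR")


class TestEvaluate:
    def test_constant_predictor_mae_is_mad(self, rng):
        y = rng.normal(10, 2, 500)

        class Const:
            def predict(self, x):
                return np.full(len(x), y.mean())

        model = FittedModel(estimator=Const(), feature_names=["a"], column_positions=[0], mode="direct")
        block = L.evaluate(model, np.zeros((500, 1)), y)
        expected = np.abs(y - y.mean()).mean()
        assert block["mae"] == pytest.approx(expected, rel=1e-12)

    def test_outlier_flagging_rule(self):
        y = np.zeros(100)

        class Skewed:
            def predict(self, x):
                p = np.zeros(len(x))
                p[0] = 50.0  # one disproportionate error
                return p

        model = FittedModel(estimator=Skewed(), feature_names=["a"], column_positions=[0], mode="direct")
        block = L.evaluate(model, np.zeros((100, 1)), y, row_ids=[f"r{i}" for i in range(100)])
        assert block["outliers"] == ["r0"]


class TestPermutationImportance:
    def test_unused_feature_zero_importance(self, rng):
        class FirstColumnOnly:
            def predict(self, x):
                return x[:, 0]

        model = FittedModel(
            estimator=FirstColumnOnly(), feature_names=["used", "unused"],
            column_positions=[0, 1], mode="direct",
        )
        x = rng.normal(size=(200, 2))
        y = x[:, 0]
        imp = L.permutation_importance(model, x, y, n_repeats=3, seed=0)
        assert imp["unused"] == 0.0
        assert imp["used"] > 0.1

    def test_reproducible_under_seed(self, table1000):
        table, _ = table1000
        x = table.frame.to_numpy()
        y = table.target.to_numpy()
        names = list(table.frame.columns)
        model, _ = L.tune_and_fit(
            x, y, names, names, list(range(300)), ridge_spec(),
        )
        a = L.permutation_importance(model, x[300:500], y[300:500], n_repeats=4, seed=9)
        b = L.permutation_importance(model, x[300:500], y[300:500], n_repeats=4, seed=9)
        assert a == b


class TestPipeline:
    def test_report_reproducible(self):
        table, _ = generate_feature_table(n=200, n_features=8, active=(1, 3), coefficients=(2.0, 1.0), seed=5)
        spec = ridge_spec(mode="delta", alphas=(1e-3, 1e-1))
        r1 = L.run_pipeline(table, spec, split_seed=2, max_features=4)
        r2 = L.run_pipeline(table, spec, split_seed=2, max_features=4)
        assert r1.to_json() == r2.to_json()

    def test_literature_block_present_only_when_tagged(self):
        table, _ = generate_feature_table(n=150, n_features=5, seed=3)
        spec = ridge_spec()
        rep = L.run_pipeline(table, spec, split_seed=0, do_select=False)
        assert rep.literature is None
        table_lit, _ = generate_feature_table(n=150, n_features=5, seed=3, n_literature=20)
        rep_lit = L.run_pipeline(table_lit, spec, split_seed=0, do_select=False)
        assert rep_lit.literature is not None
        assert rep_lit.literature["n"] == 20
        assert "literature" in rep_lit.importances

    def test_delta_beats_direct_majority_krr(self):
        # smooth nonlinear correction on a spread-out baseline
        spec_kwargs = dict(
            family="KRR", kernel="RBF", grid={"alpha": [1e-3, 1e-2], "gamma": [0.05]},
        )
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            table, _ = generate_feature_table(
                n=250, n_features=8, active=(1, 4), coefficients=(2.5, 2.0), seed=seed
            )
            maes = {}
            for mode in ("direct", "delta"):
                spec = ModelSpec(mode=mode, seed=seed, **spec_kwargs)
                rep = L.run_pipeline(table, spec, split_seed=seed, do_select=False,
                                     n_importance_repeats=1)
                maes[mode] = rep.test["mae"]
            wins += maes["delta"] <= maes["direct"]
        assert wins >= 7

    def test_se_definition(self):
        table, _ = generate_feature_table(n=150, n_features=5, seed=3)
        rep = L.run_pipeline(table, ridge_spec(), split_seed=0, do_select=False)
        errs = np.array(list(rep.test["abs_errors"].values()))
        assert rep.test["se"] == pytest.approx(errs.std(ddof=1) / np.sqrt(len(errs)), rel=1e-9)


class TestDoubleCV:
    def test_six_reports_and_aggregate(self):
        table, _ = generate_feature_table(n=150, n_features=5, active=(1,), coefficients=(2.0,), seed=7)
        reports, agg = L.double_cv(
            table, ridge_spec(), n_extra_splits=5, base_seed=0,
            do_select=False, n_importance_repeats=1,
        )
        assert len(reports) == 6
        assert agg["mean_test_mae"] == pytest.approx(
            np.mean([r.test["mae"] for r in reports]), rel=1e-12
        )

    def test_split_variance_shrinks_with_n(self):
        sds = {}
        for n in (200, 800):
            maes = []
            for seed in range(6):
                table, _ = generate_feature_table(
                    n=n, n_features=5, active=(1,), coefficients=(2.0,), seed=seed
                )
                rep = L.run_pipeline(
                    table, ridge_spec(mode="delta"), split_seed=seed,
                    do_select=False, n_importance_repeats=1,
                )
                maes.append(rep.test["mae"])
            sds[n] = np.std(maes)
        assert sds[800] < sds[200]


class TestLearningCurve:
    def test_monotone_improvement_majority(self):
        better = 0
        for seed in range(50):
            table, _ = generate_feature_table(
                n=650, n_features=15, active=(1, 3, 5),
                coefficients=(3.0, 2.0, 2.0), seed=seed,
            )
            x = table.frame.drop(columns="barrier").to_numpy()
            y = table.target.to_numpy() - table.frame["barrier"].to_numpy()
            pts = L.learning_curve(
                x, y, ridge_spec(seed=seed, alphas=(1e-3,)), [25, 600],
                k_folds=3, seed=seed,
            )
            by_size = {p["size"]: p for p in pts}
            better += by_size[600]["cv_mae"] < by_size[25]["cv_mae"]
        assert better >= 40

    def test_train_below_cv_on_average(self):
        gaps = []
        for seed in range(20):
            table, _ = generate_feature_table(n=200, n_features=6, seed=seed)
            x = table.frame.to_numpy()
            y = table.target.to_numpy()
            pts = L.learning_curve(x, y, ridge_spec(seed=seed), [100], k_folds=3, seed=seed)
            gaps.append(pts[0]["cv_mae"] - pts[0]["train_mae"])
        assert np.mean(gaps) > 0

    def test_size_exceeds_rows_error(self):
        table, _ = generate_feature_table(n=50, n_features=4, seed=0)
        with pytest.raises(ValueError):
            L.learning_curve(
                table.frame.to_numpy(), table.target.to_numpy(),
                ridge_spec(), [51],
            )
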