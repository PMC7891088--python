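import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import minimize
from scipy.special import logsumexp

from paleorange import bioclim as bc
from paleorange import niche_model as nm
from paleorange import synthetic_data as syn
from paleorange.grids import LatLonGrid
from tests.conftest import log_linear_truth


def brute_force_ppm(presence_counts, background, stack, spec):
    """Independent optimizer on the same penalized point-process
    objective: un-split coefficients, numerically differentiated BFGS
    (the fitted path uses an analytic-gradient positive/negative split).
    Returns standardized-scale coefficients."""
    brows, bcols = background
    F_bg, _ = nm.expand_features(stack.values_at(brows, bcols), spec.classes)
    prow, pcol = np.nonzero(presence_counts)
    y = presence_counts[prow, pcol].astype(float)
    F_pr, _ = nm.expand_features(stack.values_at(prow, pcol), spec.classes)
    mu, sd = F_bg.mean(axis=0), F_bg.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Zb = (F_bg - mu) / sd
    Zp = (F_pr - mu) / sd
    s_pres = (y[:, None] * Zp).sum(axis=0)
    N = y.sum()

    def obj(w):
        return (
            -s_pres @ w
            + N * logsumexp(Zb @ w)
            + spec.beta * np.abs(w).sum()
        )

    res = minimize(obj, np.zeros(Zb.shape[1]), method="BFGS",
                   options={"maxiter": 5000, "gtol": 1e-10})
    return res.x, obj


def fit_standardized_coefs(model):
    return model.coef * np.where(model.bg_sd > 0, model.bg_sd, 1.0)


@pytest.fixture(scope="module")
def tiny_setup():
    """5x5 all-land grid with a clear aridity gradient."""
    grid = LatLonGrid(0, 5, -2.5, 2.5, 1.0)
    rng = np.random.default_rng(0)
    spec = syn.ScenarioSpec(noise_sd=1.0, pluvial_center_lat=1.0, pluvial_width=2.0)
    climate = syn.generate_climate(spec, grid, seed=8)
    stack = bc.build_bioclim_stack(climate)
    truth = log_linear_truth(stack, [0, 0, 2.0, 0])
    occ = syn.generate_occurrences(truth, 60, 0.0, seed=9, grid=grid)
    counts = nm.assign_presence_cells(occ, grid, stack.land_mask)
    background = nm.sample_background(stack.land_mask, 100_000, seed=10)
    return grid, stack, occ, counts, background


class TestSampleBackground:
    def test_clamped_to_all_cells_no_duplicates(self):
        mask = np.ones((50, 100), dtype=bool)  # 5,000 land cells
        rows, cols = nm.sample_background(mask, 100_000, seed=0)
        assert rows.size == 5000
        assert len({(r, c) for r, c in zip(rows, cols)}) == 5000

    def test_same_seed_same_sample(self):
        mask = np.ones((20, 20), dtype=bool)
        a = nm.sample_background(mask, 100, seed=5)
        b = nm.sample_background(mask, 100, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_inclusion_frequency_uniform(self):
        mask = np.ones((10, 10), dtype=bool)
        hits = np.zeros(100)
        reps = 400
        for s in range(reps):
            rows, cols = nm.sample_background(mask, 50, seed=s)
            hits[rows * 10 + cols] += 1
        # each cell included w.p. 1/2 per repeat
        se = np.sqrt(reps * 0.5 * 0.5)
        assert np.all(np.abs(hits - reps * 0.5) < 5 * se)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            nm.sample_background(np.zeros((3, 3), dtype=bool), 10, seed=0)


class TestAssignPresenceCells:
    def test_duplicates_kept_as_counts(self):
        grid = LatLonGrid(0, 4, 0, 4, 1.0)
        occ = syn.OccurrenceSet(
            [syn.OccurrenceRecord(0.5, 3.5, "a", 0.0)] * 2
        )
        counts = nm.assign_presence_cells(occ, grid)
        assert counts[0, 0] == 2
        assert counts.sum() == 2

    def test_sea_record_dropped_and_logged(self, caplog):
        grid = LatLonGrid(0, 2, 0, 2, 1.0)
        mask = np.array([[True, False], [True, True]])
        occ = syn.OccurrenceSet([syn.OccurrenceRecord(1.5, 1.5, "a", 0.0)])
        with caplog.at_level("WARNING"):
            counts = nm.assign_presence_cells(occ, grid, mask)
        assert counts.sum() == 0
        assert "off land" in caplog.text

    def test_empty_set(self):
        grid = LatLonGrid(0, 2, 0, 2, 1.0)
        assert nm.assign_presence_cells(syn.OccurrenceSet([]), grid).sum() == 0


class TestFitPpm:
    def test_uniform_presences_strong_penalty_shrinks_slopes(self, tiny_setup):
        grid, stack, _, _, background = tiny_setup
        occ = syn.generate_occurrences(
            np.ones(grid.shape), 400, 0.0, seed=3, grid=grid
        )
        counts = nm.assign_presence_cells(occ, grid, stack.land_mask)
        spec = nm.FeatureSpec(classes=("linear",), beta=50.0)
        model = nm.fit_ppm(counts, background, stack, spec)
        assert np.all(np.abs(fit_standardized_coefs(model)) < 1e-6)

    def test_matches_brute_force_oracle(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        spec = nm.FeatureSpec(classes=("linear",), beta=1e-6)
        model = nm.fit_ppm(counts, background, stack, spec)
        w_oracle, obj = brute_force_ppm(counts, background, stack, spec)
        w_fit = fit_standardized_coefs(model)
        np.testing.assert_allclose(w_fit, w_oracle, atol=1e-4)
        assert obj(w_fit) <= obj(w_oracle) + 1e-8

    def test_fitted_objective_beats_random_vectors(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        spec = nm.FeatureSpec(classes=("linear", "quadratic"), beta=2.0)
        model = nm.fit_ppm(counts, background, stack, spec)
        _, obj = brute_force_ppm(counts, background, stack, spec)
        fitted_val = obj(fit_standardized_coefs(model))
        rng = np.random.default_rng(0)
        for _ in range(1000):
            w = rng.normal(0, 1, size=len(model.coef))
            assert obj(w) >= fitted_val - 1e-8

    def test_parameter_recovery_sign(self, stack, small_grid, background):
        truth = log_linear_truth(stack, [0, 0, 1.0, 0])
        occ = syn.generate_occurrences(truth, 500, 0.0, seed=12, grid=small_grid)
        counts = nm.assign_presence_cells(occ, small_grid, stack.land_mask)
        spec = nm.FeatureSpec(classes=("linear",), beta=2.0)
        model = nm.fit_ppm(counts, background, stack, spec)
        w = fit_standardized_coefs(model)
        k = bc.VARIABLE_NAMES.index("aridity_index")
        assert w[k] > 0
        assert all(abs(w[j]) < abs(w[k]) for j in range(4) if j != k)

    def test_nonconvergence_raises_with_trace(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        spec = nm.FeatureSpec(classes=("linear", "quadratic", "product"), beta=0.001)
        with pytest.raises(nm.ConvergenceError) as err:
            nm.fit_ppm(counts, background, stack, spec, max_iter=1)
        assert err.value.trace is not None

    def test_input_validation(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        spec = nm.FeatureSpec()
        with pytest.raises(ValueError):
            nm.fit_ppm(np.zeros_like(counts), background, stack, spec)
        with pytest.raises(ValueError):
            nm.FeatureSpec(classes=(), beta=2.0)
        with pytest.raises(ValueError):
            nm.FeatureSpec(beta=0.0)


class TestPredictRaw:
    def test_background_sum_is_one(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        model = nm.fit_ppm(counts, background, stack, nm.FeatureSpec())
        smap = nm.predict_raw(model, stack)
        assert smap.at_cells(*background).sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_features_equal_raw(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        model = nm.fit_ppm(counts, background, stack, nm.FeatureSpec())
        # duplicate one cell's variable values into another cell
        layers = {n: getattr(stack, n).copy() for n in bc.VARIABLE_NAMES}
        for arr in layers.values():
            arr[0, 1] = arr[0, 0]
        twin = bc.BioclimStack(grid=stack.grid, land_mask=stack.land_mask, **layers)
        smap = nm.predict_raw(model, twin)
        assert smap.values[0, 1] == pytest.approx(smap.values[0, 0], rel=1e-12)

    def test_log_ratio_identity(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        model = nm.fit_ppm(counts, background, stack, nm.FeatureSpec())
        smap = nm.predict_raw(model, stack)
        X = stack.values_at(np.array([0, 2]), np.array([0, 3]))
        F, _ = nm.expand_features(X, model.spec.classes)
        expected = (F[0] - F[1]) @ model.coef
        got = np.log(smap.values[0, 0]) - np.log(smap.values[2, 3])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_unfitted_rejected(self, tiny_setup):
        _, stack, _, counts, background = tiny_setup
        model = nm.fit_ppm(counts, background, stack, nm.FeatureSpec())
        model.fitted = False
        with pytest.raises(nm.NotFittedError):
            nm.predict_raw(model, stack)


class TestCrossValidation:
    def test_perfectly_separable_auc_one(self):
        # only aridity varies; presence cells (top rows) and background
        # cells (bottom rows) have disjoint aridity ranges, so any fit
        # with a positive aridity slope ranks them perfectly
        grid = LatLonGrid(0, 10, -5, 5, 1.0)
        rng = np.random.default_rng(1)
        aridity = np.linspace(2.0, 0.1, grid.n_lat)[:, None] * np.ones(grid.shape)
        aridity += rng.uniform(0, 0.05, grid.shape)
        layers = {
            "gdd0": np.full(grid.shape, 5000.0),
            "temp_seasonality": np.full(grid.shape, 300.0),
            "aridity_index": aridity,
            "pet_seasonality": np.full(grid.shape, 20.0),
        }
        stack = bc.BioclimStack(
            grid=grid, land_mask=np.ones(grid.shape, dtype=bool), **layers
        )
        suit = np.zeros(grid.shape)
        suit[:3] = 1.0  # presences only in the three high-aridity rows
        occ = syn.generate_occurrences(suit, 80, 0.0, seed=2, grid=grid)
        background = np.nonzero(suit == 0.0)  # disjoint, lower aridity
        # beta large enough to bound the otherwise-divergent separable
        # likelihood, small enough to keep a positive aridity slope
        fspec = nm.FeatureSpec(classes=("linear",), beta=80.0)
        auc = nm.kfold_auc(occ, background, stack, fspec, k=4, seed=3)
        assert auc == 1.0

    def test_no_signal_auc_near_half(self, stack, small_grid, background):
        occ = syn.generate_occurrences(
            np.where(stack.land_mask, 1.0, np.nan), 200, 0.0, seed=6,
            grid=small_grid,
        )
        fspec = nm.FeatureSpec(classes=("linear",), beta=2.0)
        auc = nm.kfold_auc(occ, background, stack, fspec, k=5, seed=7)
        se = np.sqrt(1.0 / 12.0 * (1.0 / 40 + 1.0 / background[0].size))
        assert abs(auc - 0.5) < 3 * se + 0.02

    def test_strong_signal_auc_above_09(self, occurrences, stack, background):
        fspec = nm.FeatureSpec(classes=("linear",), beta=2.0)
        auc = nm.kfold_auc(occurrences, background, stack, fspec, k=10, seed=8)
        assert auc > 0.9

    def test_k_validation(self, occurrences, stack, background):
        with pytest.raises(ValueError):
            nm.kfold_auc(occurrences, background, stack, nm.FeatureSpec(), k=1)


class TestCheckerboard:
    def test_four_nonempty_folds(self, occurrences, stack, background):
        rows, cols = nm._occurrence_cells(occurrences, stack.grid, stack.land_mask)
        folds = nm.checkerboard_fold(rows, cols, aggregation=2)
        assert set(folds) == {0, 1, 2, 3}

    def test_hand_worked_partition(self):
        # aggregation 1: fine parity (r+c)%2, coarse parity (r//2+c//2)%2
        pts = [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (2, 2), (3, 1)]
        expected = [0, 1, 1, 0, 2, 2, 0, 2]
        got = nm.checkerboard_fold(
            np.array([p[0] for p in pts]), np.array([p[1] for p in pts]), 1
        )
        assert got.tolist() == expected

    def test_spatial_auc_not_above_random_on_average(
        self, stack, small_grid, background
    ):
        fspec = nm.FeatureSpec(classes=("linear",), beta=2.0)
        diffs = []
        for s in range(4):
            truth = log_linear_truth(stack, [0, 0, 6.0, 0])
            occ = syn.generate_occurrences(truth, 400, 0.0, seed=40 + s, grid=small_grid)
            kf = nm.kfold_auc(occ, background, stack, fspec, k=4, seed=s)
            cb = nm.checkerboard_cv_auc(
                occ, background, stack, fspec, aggregation=2, seed=s
            )
            diffs.append(cb - kf)
        assert np.mean(diffs) <= 0.005

    def test_aggregation_validation(self):
        with pytest.raises(ValueError):
            nm.checkerboard_fold(np.array([0]), np.array([0]), 0)


def threshold_oracle(suits, e):
    """Exhaustive scan over every observed candidate threshold."""
    suits = np.asarray(suits, dtype=float)
    best = suits.min()
    for cand in np.unique(suits):
        if np.mean(suits < cand) <= e and cand > best:
            best = cand
    return float(best)


class TestLowestPresenceThreshold:
    def test_decile_example(self):
        suits = np.arange(0.1, 1.05, 0.1)
        res = nm.lowest_presence_threshold(suits, 0.10)
        assert res.t == pytest.approx(0.2)
        assert res.realized_omission == pytest.approx(0.1)

    def test_zero_allowance_gives_minimum(self):
        suits = np.array([0.4, 0.2, 0.9])
        res = nm.lowest_presence_threshold(suits, 0.0)
        assert res.t == 0.2
        assert res.realized_omission == 0.0

    def test_tie_at_minimum(self):
        res = nm.lowest_presence_threshold([0.1, 0.1, 0.9], 0.10)
        assert res.t == 0.1
        assert res.realized_omission == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nm.lowest_presence_threshold([], 0.1)
        with pytest.raises(ValueError):
            nm.lowest_presence_threshold([0.5], 1.0)

    @given(
        suits=hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        e=hst.floats(min_value=0.0, max_value=0.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_property_matches_oracle_and_omission_bound(self, suits, e):
        res = nm.lowest_presence_threshold(suits, e)
        assert res.t == threshold_oracle(suits, e)
        assert res.realized_omission <= e


class TestBinarize:
    def _smap(self, values, grid):
        rows, cols = np.nonzero(np.isfinite(values))
        return nm.SuitabilityMap(grid=grid, values=values,
                                 background_rows=rows, background_cols=cols)

    def test_zero_threshold_all_suitable(self):
        grid = LatLonGrid(0, 3, 0, 3, 1.0)
        values = np.random.default_rng(0).uniform(0, 1, grid.shape)
        values[0, 0] = np.nan
        out = nm.binarize(self._smap(values, grid), 0.0)
        assert np.all(out[np.isfinite(out)] == 1.0)
        assert np.isnan(out[0, 0])

    def test_above_max_none_suitable(self):
        grid = LatLonGrid(0, 3, 0, 3, 1.0)
        values = np.random.default_rng(0).uniform(0, 1, grid.shape)
        out = nm.binarize(self._smap(values, grid), values.max() + 1)
        assert np.all(out == 0.0)

    def test_suitable_count_monotone_in_threshold(self):
        grid = LatLonGrid(0, 5, 0, 5, 1.0)
        values = np.random.default_rng(1).uniform(0, 1, grid.shape)
        smap = self._smap(values, grid)
        counts = [
            np.nansum(nm.binarize(smap, t)) for t in np.linspace(0, 1.1, 23)
        ]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))
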