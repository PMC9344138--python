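import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ecwsp import bayes, synthetic
from ecwsp.bayes import (
    ClassStats,
    PriorSpec,
    fit,
    log_conditional,
    log_density,
    majority_vote,
    posterior,
    precompute_cube,
    predict,
)
from ecwsp.errors import FitError
from ecwsp.io import SpectralDataset, WavelengthGrid


def _dataset_from_blocks(grid, blocks):
    """blocks: {class_label: (n_rows, p) array}; all rows tagged calibration."""
    rows, labels = [], []
    for k, block in blocks.items():
        rows.append(np.atleast_2d(block))
        labels += [k] * len(np.atleast_2d(block))
    X = np.vstack(rows)
    meta = pd.DataFrame(
        {
            "class_label": labels,
            "bottle_id": [f"B{i}" for i in range(len(X))],
            "sample_id": [f"S{i}" for i in range(len(X))],
            "replicate_id": 1,
            "set": "calibration",
        }
    )
    return SpectralDataset(grid, X, meta)


GRID3 = WavelengthGrid(400.0, 404.0, 2.0)


class TestFit:
    def test_zero_variance_hits_floor(self):
        ds = _dataset_from_blocks(GRID3, {1: np.full((3, 3), 0.50), 2: np.eye(3)})
        st = fit(ds, sd_floor=1e-6)
        assert st.mu[0, 0] == 0.50
        assert st.sigma[0, 0] == 1e-6

    def test_sample_standard_deviation_ddof1(self):
        ds = _dataset_from_blocks(
            GRID3, {1: np.array([[0.1] * 3, [0.2] * 3, [0.3] * 3]), 2: np.eye(3)}
        )
        st = fit(ds)
        assert st.mu[0, 0] == pytest.approx(0.2)
        assert st.sigma[0, 0] == pytest.approx(0.1)

    def test_class_with_single_spectrum_rejected(self):
        ds = _dataset_from_blocks(GRID3, {1: np.eye(3), 2: np.ones((1, 3))})
        with pytest.raises(FitError, match="class 2"):
            fit(ds)

    def test_recovers_generator_means(self):
        cfg = synthetic.recovery_config(5)
        ds, truth = synthetic.generate(cfg)
        ds.meta["set"] = "calibration"
        st = fit(ds)
        n_per_class = ds.n_spectra // 5
        for b, band in zip(truth, cfg.informative_bands):
            j = ds.grid.index(b)
            for ci in range(5):
                expected = sum(
                    p.amplitude * np.exp(-0.5 * ((b - p.center_nm) / p.width_nm) ** 2)
                    for p in cfg.shared_peaks
                ) + band.offsets[ci] * 1.0
                se = st.sigma[ci, j] / np.sqrt(n_per_class)
                assert abs(st.mu[ci, j] - expected) < 3 * se + 1e-3


class TestLogDensity:
    def test_standard_normal_mode(self):
        assert log_density(0.0, 0.0, 1.0) == pytest.approx(-0.9189385332046727)

    def test_one_sigma_off_mode(self):
        assert log_density(1.0, 0.0, 1.0) == pytest.approx(-1.4189385332046727)

    def test_matches_scipy_closed_form(self):
        assert log_density(0.0, 1.0, 0.1) == pytest.approx(
            sps.norm.logpdf(0.0, 1.0, 0.1), rel=1e-12
        )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            log_density(0.0, 0.0, 0.0)


@pytest.fixture
def handmade_stats():
    mu = np.array([[0.1, 0.5, 0.9], [0.2, 0.4, 0.6]])
    sigma = np.array([[0.05, 0.1, 0.2], [0.1, 0.1, 0.1]])
    return ClassStats(GRID3, np.array([1, 2]), mu, sigma, 1e-6)


class TestLogConditional:
    def test_single_wavelength_equals_log_density(self, handmade_stats):
        x = np.array([[0.15, 0.45, 0.8]])
        lc = log_conditional(x, handmade_stats, [402.0])
        for j in range(2):
            assert lc[0, j] == log_density(
                0.45, handmade_stats.mu[j, 1], handmade_stats.sigma[j, 1]
            )

    def test_additive_over_disjoint_subsets(self, handmade_stats):
        x = np.array([[0.15, 0.45, 0.8]])
        full = log_conditional(x, handmade_stats, [400.0, 402.0, 404.0])
        parts = log_conditional(x, handmade_stats, [400.0, 404.0]) + log_conditional(
            x, handmade_stats, [402.0]
        )
        np.testing.assert_allclose(full, parts, rtol=1e-13)

    def test_matches_explicit_product_of_densities(self, handmade_stats):
        x = np.array([0.15, 0.45, 0.8])
        lc = log_conditional(x, handmade_stats, [400.0, 402.0, 404.0])
        for j in range(2):
            product = np.prod(
                sps.norm.pdf(x, handmade_stats.mu[j], handmade_stats.sigma[j])
            )
            assert lc[0, j] == pytest.approx(np.log(product), rel=1e-10)


class TestPosterior:
    def test_symmetric_inputs_give_uniform(self):
        pri = PriorSpec.equal([1, 2, 3, 4, 5])
        post = posterior(np.zeros((1, 5)), pri)
        np.testing.assert_allclose(post, 0.2)

    def test_two_class_closed_form(self):
        # x=0 under N(0,1) vs N(1,1), equal priors: phi(0)/(phi(0)+phi(1))
        pri = PriorSpec.equal([1, 2])
        lc = np.array([[log_density(0.0, 0.0, 1.0), log_density(0.0, 1.0, 1.0)]])
        post = posterior(lc, pri)
        assert post[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-0.5)), rel=1e-12)
        assert post[0, 0] == pytest.approx(0.6224593, abs=1e-6)

    def test_rows_sum_to_one_for_extreme_inputs(self, rng):
        pri = PriorSpec.equal([1, 2, 3])
        lc = rng.uniform(-1e4, 1e2, size=(50, 3))
        post = posterior(lc, pri)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestPredict:
    def test_nearest_mean_under_equal_sigma(self):
        mu = np.array([[0.0] * 3, [1.0] * 3, [2.0] * 3])
        sigma = np.full((3, 3), 0.1)
        st = ClassStats(GRID3, np.array([1, 2, 3]), mu, sigma, 1e-6)
        pri = PriorSpec.equal([1, 2, 3])
        x = mu[2] + 0.01
        assert predict(x, st, pri)[0] == 3

    def test_ties_break_toward_smaller_label(self):
        mu = np.array([[0.5] * 3, [0.5] * 3])
        sigma = np.full((2, 3), 0.1)
        st = ClassStats(GRID3, np.array([2, 7]), mu, sigma, 1e-6)
        pri = PriorSpec.equal([2, 7])
        assert predict(np.full(3, 0.4), st, pri)[0] == 2

    def test_constant_shift_leaves_predictions_unchanged(self, handmade_stats, rng):
        X = rng.uniform(0, 1, size=(40, 3))
        pri = PriorSpec.equal([1, 2])
        lc = log_conditional(X, handmade_stats)
        base = np.asarray(handmade_stats.class_ids)[
            np.argmax(bayes.decision_scores(lc, pri), axis=1)
        ]
        shifted = np.asarray(handmade_stats.class_ids)[
            np.argmax(bayes.decision_scores(lc + 123.456, pri), axis=1)
        ]
        np.testing.assert_array_equal(base, shifted)

    def test_label_permutation_equivariance(self, small_dataset):
        ds, _ = small_dataset
        perm = {1: 3, 2: 1, 3: 2}
        st = fit(ds)
        pri = PriorSpec.for_stats(st, "proportional", ds.subset("calibration").class_labels)
        pred = predict(ds.subset("prediction").absorbance, st, pri)

        ds2 = SpectralDataset(ds.grid, ds.absorbance.copy(), ds.meta.copy())
        ds2.meta["class_label"] = ds2.meta["class_label"].map(perm)
        st2 = fit(ds2)
        pri2 = PriorSpec.for_stats(st2, "proportional", ds2.subset("calibration").class_labels)
        pred2 = predict(ds2.subset("prediction").absorbance, st2, pri2)
        np.testing.assert_array_equal(pred2, np.vectorize(perm.get)(pred))


class TestCube:
    def test_degenerate_cube_matches_direct_calls(self, handmade_stats):
        x = np.array([[0.3, 0.5, 0.7]])
        cube = precompute_cube(x, handmade_stats)
        for j in range(2):
            for i in range(3):
                assert cube.values[0, j, i] == log_density(
                    x[0, i], handmade_stats.mu[j, i], handmade_stats.sigma[j, i]
                )

    def test_subset_sum_bit_identical_to_direct(self, small_dataset, rng):
        ds, _ = small_dataset
        st = fit(ds)
        ev = ds.subset("prediction")
        cube = precompute_cube(ev.absorbance, st)
        wl = ds.grid.wavelengths
        for _ in range(10):
            size = rng.integers(1, 8)
            idx = np.sort(rng.choice(ds.grid.point_count, size=size, replace=False))
            direct = log_conditional(ev.absorbance, st, wl[idx])
            np.testing.assert_array_equal(cube.subset_log_conditional(idx), direct)

    def test_cube_predictions_equal_direct_predictions(self, small_dataset):
        ds, _ = small_dataset
        st = fit(ds)
        pri = PriorSpec.for_stats(st, "proportional", ds.subset("calibration").class_labels)
        ev = ds.subset("prediction")
        cube = precompute_cube(ev.absorbance, st)
        idx = np.arange(0, ds.grid.point_count, 3)
        direct = predict(ev.absorbance, st, pri, ds.grid.wavelengths[idx])
        via_cube = np.asarray(st.class_ids)[
            np.argmax(cube.subset_log_conditional(idx) + pri.log_values, axis=1)
        ]
        np.testing.assert_array_equal(direct, via_cube)

    def test_deterministic_recomputation(self, handmade_stats, rng):
        X = rng.uniform(0, 1, size=(5, 3))
        a = precompute_cube(X, handmade_stats)
        b = precompute_cube(X, handmade_stats)
        np.testing.assert_array_equal(a.values, b.values)


def test_majority_vote_smooths_replicates():
    labels = np.array([1, 1, 2, 3, 3, 3])
    samples = ["a", "a", "a", "b", "b", "b"]
    np.testing.assert_array_equal(majority_vote(labels, samples), [1, 1, 1, 3, 3, 3])


def test_priors_modes():
    pri = PriorSpec.proportional([1, 1, 1, 2])
    assert pri.values == (0.75, 0.25)
    eq = PriorSpec.equal([1, 2, 3])
    assert sum(eq.values) == 1.0
    with pytest.raises(Exception):
        PriorSpec((1, 2), (0.5, 0.6))
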