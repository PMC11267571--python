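import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from compraman import (
    FilterBank,
    GaussianClassModel,
    MultinomialClassModel,
    RamanSpectrumSet,
    bb_gaussian,
    bb_multinomial,
    estimate_gaussian_model,
    mlc_gaussian,
    mlc_multinomial,
    optimize_filters_swap,
)
from compraman.bb_filters import _filter_probabilities


def enumerate_filter_outcomes(n_filters, n_phot):
    """All count vectors over n_filters summing to n_phot."""
    for n in itertools.product(range(n_phot + 1), repeat=n_filters):
        if sum(n) == n_phot:
            yield np.asarray(n)


@pytest.fixture
def toy_two_class():
    s = np.array([[0.5, 0.3, 0.2], [0.1, 0.3, 0.6]])
    bank = FilterBank(B=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))
    return bank, MultinomialClassModel(s=s, N_phot=2)


class TestBBMultinomial:
    def test_identical_classes_give_half(self):
        s = np.array([[0.4, 0.6], [0.4, 0.6]])
        bank = FilterBank(B=np.array([[1.0, 0.0], [0.0, 1.0]]))
        model = MultinomialClassModel(s=s, N_phot=5)
        assert bb_multinomial(bank, model) == pytest.approx(0.5)

    def test_disjoint_single_filter_support_gives_zero(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0]])
        bank = FilterBank(B=np.array([[1.0, 0.0], [0.0, 1.0]]))
        model = MultinomialClassModel(s=s, N_phot=3)
        assert bb_multinomial(bank, model) == pytest.approx(0.0, abs=1e-15)

    def test_matches_exhaustive_enumeration(self, toy_two_class):
        bank, model = toy_two_class
        p = _filter_probabilities(bank, model)
        coeff = sum(
            np.sqrt(
                stats.multinomial.pmf(n, model.N_phot, p[0])
                * stats.multinomial.pmf(n, model.N_phot, p[1])
            )
            for n in enumerate_filter_outcomes(2, model.N_phot)
        )
        assert bb_multinomial(bank, model) == pytest.approx(0.5 * coeff, abs=1e-12)

    def test_nonincreasing_in_photon_budget(self, toy_two_class):
        bank, model = toy_two_class
        bounds = [
            bb_multinomial(bank, MultinomialClassModel(s=model.s, N_phot=n))
            for n in (1, 2, 5, 10, 50)
        ]
        assert np.all(np.diff(bounds) <= 1e-15)

    def test_zero_efficiency_class_is_hard_error(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0]])
        bank = FilterBank(B=np.array([[0.0, 1.0]]))
        with pytest.raises(ValueError, match="transmits nothing"):
            bb_multinomial(bank, MultinomialClassModel(s=s, N_phot=2))


class TestGaussianModelEstimation:
    def test_covariance_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        intens = rng.uniform(1, 10, size=(60, 6))
        labels = np.repeat(["a", "b"], 30)
        s = RamanSpectrumSet(
            intensities=intens, wavenumbers=np.arange(6.0), labels=labels
        )
        bank = FilterBank(B=(rng.uniform(size=(3, 6)) > 0.5).astype(float))
        model = estimate_gaussian_model(bank, s)
        outputs = intens @ bank.B.T
        for j, cls in enumerate(["a", "b"]):
            rows = outputs[labels == cls]
            mean = rows.sum(axis=0) / rows.shape[0]
            centered = rows - mean
            cov = centered.T @ centered / (rows.shape[0] - 1)
            np.testing.assert_allclose(model.means[j], mean, atol=1e-10)
            ridge = model.covariances[j] - cov
            assert np.allclose(ridge, np.eye(3) * ridge[0, 0], atol=1e-10)
            assert 0 < ridge[0, 0] < 1e-6 * np.trace(cov)

    def test_priors_reproduce_class_proportions(self):
        rng = np.random.default_rng(1)
        s = RamanSpectrumSet(
            intensities=rng.uniform(1, 5, size=(50, 4)),
            wavenumbers=np.arange(4.0),
            labels=np.repeat(["x", "y"], [30, 20]),
        )
        bank = FilterBank(B=np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]]))
        model = estimate_gaussian_model(bank, s)
        np.testing.assert_allclose(model.priors, [0.6, 0.4])
        assert model.priors.sum() == pytest.approx(1.0)

    def test_zero_variance_class_gets_ridge_identity(self):
        s = RamanSpectrumSet(
            intensities=np.tile([1.0, 2.0, 3.0], (5, 1)),
            wavenumbers=np.arange(3.0),
            labels=np.repeat("a", 5),
        )
        bank = FilterBank(B=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))
        model = estimate_gaussian_model(bank, s, ridge_rel=1e-8)
        np.testing.assert_allclose(model.means[0], [3.0, 5.0])
        assert np.allclose(model.covariances[0], 1e-8 * np.eye(2))


class TestBBGaussian:
    def test_identical_classes_give_half(self):
        cov = np.eye(2)
        model = GaussianClassModel(
            means=np.array([[1.0, 2.0], [1.0, 2.0]]),
            covariances=np.array([cov, cov]),
            priors=np.array([0.5, 0.5]),
        )
        assert bb_gaussian(model) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "m1,v1,m2,v2",
        [(0.0, 1.0, d, v) for d in (0.3, 1.0, 2.5) for v in (0.5, 1.0, 3.0)],
    )
    def test_one_dimensional_coefficient_matches_quadrature(self, m1, v1, m2, v2):
        model = GaussianClassModel(
            means=np.array([[m1], [m2]]),
            covariances=np.array([[[v1]], [[v2]]]),
            priors=np.array([0.5, 0.5]),
        )
        integrand = lambda x: np.sqrt(  # noqa: E731
            stats.norm.pdf(x, m1, np.sqrt(v1)) * stats.norm.pdf(x, m2, np.sqrt(v2))
        )
        coeff, _ = quad(integrand, -30, 30)
        assert bb_gaussian(model) == pytest.approx(0.5 * coeff, abs=1e-8)

    def test_bound_decreases_as_means_separate(self):
        cov = np.eye(2)
        bounds = []
        for d in np.linspace(0, 4, 9):
            model = GaussianClassModel(
                means=np.array([[0.0, 0.0], [d, 0.0]]),
                covariances=np.array([cov, cov]),
                priors=np.array([0.5, 0.5]),
            )
            bounds.append(bb_gaussian(model))
        assert np.all(np.diff(bounds) < 0)


class TestSwapOptimizer:
    def test_trace_nonincreasing_and_row_sums_invariant(self):
        rng = np.random.default_rng(0)
        s = rng.exponential(size=(3, 12)) ** 3
        s /= s.sum(axis=1, keepdims=True)
        model = MultinomialClassModel(s=s, N_phot=20)
        bank, trace = optimize_filters_swap(
            lambda F: bb_multinomial(F, model), n_filters=2, K=12, seed=1,
            patience=300, max_proposals=3000,
        )
        assert np.all(np.diff(trace) < 0)
        np.testing.assert_array_equal(bank.B.sum(axis=1), [4, 4])

    def test_finds_exhaustive_optimum_on_small_problem(self):
        # one perfectly discriminative channel; enumerate all banks with the
        # same per-filter element counts
        s = np.array([[0.7, 0.1, 0.1, 0.05, 0.05], [0.1, 0.7, 0.1, 0.05, 0.05]])
        model = MultinomialClassModel(s=s, N_phot=10)
        K, n_ones = 5, 2
        objective = lambda F: bb_multinomial(F, model)  # noqa: E731

        best = np.inf
        for rows in itertools.product(itertools.combinations(range(K), n_ones), repeat=2):
            B = np.zeros((2, K))
            for i, cols in enumerate(rows):
                B[i, list(cols)] = 1.0
            if np.any((s @ B.T).sum(axis=1) <= 0):
                continue
            best = min(best, objective(FilterBank(B=B)))

        bank, trace = optimize_filters_swap(
            objective, n_filters=2, K=K, frac_ones=n_ones / K, seed=3,
            patience=500, max_proposals=5000,
        )
        assert trace[-1] == pytest.approx(best, abs=1e-12)


class TestMLCMultinomial:
    def test_counts_on_exclusive_filter_pick_that_class(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0]])
        bank = FilterBank(B=np.array([[1.0, 0.0], [0.0, 1.0]]))
        model = MultinomialClassModel(s=s, N_phot=4)
        assert mlc_multinomial(np.array([0, 4]), bank, model) == 1
        assert mlc_multinomial(np.array([4, 0]), bank, model) == 0

    def test_identical_spectra_tie_breaks_to_first_class(self, toy_two_class):
        bank, _ = toy_two_class
        s = np.array([[0.5, 0.3, 0.2], [0.5, 0.3, 0.2]])
        model = MultinomialClassModel(s=s, N_phot=2)
        for n in enumerate_filter_outcomes(2, 2):
            assert mlc_multinomial(n, bank, model) == 0

    def test_decisions_match_bruteforce_and_error_below_bound(self, toy_two_class):
        bank, model = toy_two_class
        p = _filter_probabilities(bank, model)
        error = 0.0
        for n in enumerate_filter_outcomes(2, model.N_phot):
            likelihoods = [
                stats.multinomial.pmf(n, model.N_phot, p[j]) for j in range(2)
            ]
            expected = int(np.argmax(likelihoods))
            assert mlc_multinomial(n, bank, model) == expected
            for j in range(2):
                if expected != j:
                    error += 0.5 * likelihoods[j]
        assert error <= bb_multinomial(bank, model) + 1e-12


class TestMLCGaussian:
    @pytest.fixture
    def gauss_model(self):
        return GaussianClassModel(
            means=np.array([[1.0, 0.0], [0.0, 1.0]]),
            covariances=np.array([np.eye(2), np.eye(2)]),
            priors=np.array([0.5, 0.5]),
        )

    def test_spectrum_mapping_to_second_mean_picks_class_two(self, gauss_model):
        bank = FilterBank(B=np.array([[1.0, 0.0], [0.0, 1.0]]))
        spectrum = np.array([0.0, 1.0])  # filter outputs = m_2
        assert mlc_gaussian(spectrum, bank, gauss_model) == 1

    def test_equal_means_decided_by_covariance_term(self):
        # same means; class 1 has much larger variance, so a point at the
        # common mean is likelier under class 0's tighter density
        model = GaussianClassModel(
            means=np.array([[1.0], [1.0]]),
            covariances=np.array([[[0.1]], [[10.0]]]),
            priors=np.array([0.5, 0.5]),
        )
        bank = FilterBank(B=np.array([[1.0]]))
        assert mlc_gaussian(np.array([1.0]), bank, model) == 0
        d0 = stats.norm.pdf(1.0, 1.0, np.sqrt(0.1))
        d1 = stats.norm.pdf(1.0, 1.0, np.sqrt(10.0))
        assert d0 > d1  # density oracle agrees

    def test_monte_carlo_error_below_gaussian_bound(self, gauss_model):
        rng = np.random.default_rng(5)
        bank = FilterBank(B=np.array([[1.0, 0.0], [0.0, 1.0]]))
        n = 4000
        errors = 0
        for j in range(2):
            draws = rng.multivariate_normal(
                gauss_model.means[j], gauss_model.covariances[j], size=n
            )
            pred = mlc_gaussian(draws, bank, gauss_model)
            errors += int(np.sum(pred != j))
        err = errors / (2 * n)
        sigma = np.sqrt(err * (1 - err) / (2 * n))
        assert err <= bb_gaussian(gauss_model) + 3 * sigma
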