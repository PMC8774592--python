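"""kappa_phi measures, null asymptotics, and the serial-dependence test."""

import itertools

import numpy as np
import pytest

from ordentropy.core import MarginalCDF, OrdinalScale, OrdinalSeries
from ordentropy.dependence import (
    iid_cdf_covariances,
    kappa_asymptotics,
    kappa_ord,
    kappa_ord_star,
    kappa_phi,
    test_serial_dependence,
)
from ordentropy.egf import make_phi_a, make_phi_q, make_phi_shannon
from ordentropy.markov import bar1_model
from ordentropy.simulate import simulate

from conftest import SMOOTH_EGFS, random_cdf


def random_diag(rng, f):
    """A random admissible diagonal f_ii(h): between f_i^2-ish bounds."""
    lo = np.maximum(0.0, 2 * f - 1)
    hi = f
    return lo + rng.uniform(0, 1, size=f.shape) * (hi - lo)


class TestKappaMeasures:
    @pytest.mark.parametrize("egf", SMOOTH_EGFS, ids=lambda e: e.name)
    def test_independence_gives_zero(self, egf, rng):
        f = random_cdf(rng, 4)
        assert kappa_phi(f, f**2, egf) == pytest.approx(0.0, abs=1e-12)
        assert kappa_ord(f, f**2) == pytest.approx(0.0, abs=1e-12)
        assert kappa_ord_star(f, f**2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("egf", SMOOTH_EGFS, ids=lambda e: e.name)
    def test_perfect_agreement_gives_one(self, egf, rng):
        f = random_cdf(rng, 4)
        assert kappa_phi(f, f, egf) == pytest.approx(1.0, abs=1e-12)

    def test_binary_kappa_by_hand(self):
        # m = 1, f_0 = 0.5, f_00(1) = 0.35: (0.35 - 0.25) / 0.25
        assert kappa_ord([0.5], [0.35]) == pytest.approx(0.4)

    def test_constant_weights_reduce_to_kappa_ord(self, rng):
        """z(1-z) (a = 2) and a = 3 have constant curvature weights."""
        for _ in range(15):
            f = random_cdf(rng, int(rng.integers(1, 6)))
            fii = random_diag(rng, f)
            expected = kappa_ord(f, fii)
            for a in (2.0, 3.0):
                assert kappa_phi(f, fii, make_phi_a(a)) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_shannon_weights_reduce_to_kappa_star(self, rng):
        for _ in range(15):
            f = random_cdf(rng, int(rng.integers(1, 6)))
            fii = random_diag(rng, f)
            assert kappa_phi(f, fii, make_phi_shannon()) == pytest.approx(
                kappa_ord_star(f, fii), abs=1e-12
            )

    def test_kappa_star_boundary_workaround(self):
        """Boundary summands are zeroed but still averaged over all m."""
        f = np.array([0.0, 0.4, 0.7])
        fii = np.array([0.0, 0.3, 0.55])
        expected = (
            0.0
            + (0.3 - 0.16) / (0.4 * 0.6)
            + (0.55 - 0.49) / (0.7 * 0.3)
        ) / 3
        assert kappa_ord_star(f, fii) == pytest.approx(expected, abs=1e-12)

    def test_kappa_star_legacy_eps(self):
        f = np.array([0.0, 0.5])
        fii = np.array([0.0, 0.25])
        # the eps floor makes the boundary summand 0/eps = 0 here as well,
        # but a non-null diagonal at the boundary would blow up under eps
        assert kappa_ord_star(f, fii, legacy_eps=1e-6) == pytest.approx(0.0)

    def test_one_point_cdf_undefined(self):
        with pytest.raises(ValueError):
            kappa_ord([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            kappa_phi([0.0, 1.0], [0.0, 1.0], make_phi_a(2))

    def test_scale_reversal_invariance(self, rng):
        """kappa_phi is unchanged when the scale order is flipped."""
        for egf in SMOOTH_EGFS:
            f = random_cdf(rng, 4)
            fii = random_diag(rng, f)
            # reversal: f -> 1 - f[::-1]; diagonal f_ii -> 1 - 2 f + f_ii, flipped
            f_rev = 1 - f[::-1]
            fii_rev = (1 - 2 * f + fii)[::-1]
            assert kappa_phi(f, fii, egf) == pytest.approx(
                kappa_phi(f_rev, fii_rev, egf), abs=1e-10
            )


class TestKappaAsymptotics:
    @pytest.mark.parametrize("egf", SMOOTH_EGFS, ids=lambda e: e.name)
    def test_binary_scale_variance_is_one(self, egf, rng):
        """For m = 1 the weights cancel: sigma_kappa^2 = 1 for every EGF.

        At f_0 = 1/2 the q = 4 curvature weight vanishes and the
        constant-weight limit kicks in (with a warning), which preserves
        the cancellation.
        """
        import warnings as _warnings

        for f0 in (0.1, 0.3, 0.5, 0.77):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                asym = kappa_asymptotics(np.array([f0]), egf)
            assert asym.sigma2 == pytest.approx(1.0, abs=1e-12)

    def test_u_weights_normalized_and_nonnegative(self, rng):
        for egf in SMOOTH_EGFS:
            f = random_cdf(rng, 5)
            asym = kappa_asymptotics(f, egf)
            assert np.all(asym.u >= 0)
            assert float(asym.u @ (f * (1 - f))) == pytest.approx(1.0, abs=1e-12)

    def test_shannon_closed_form(self, rng):
        """General formula vs the closed form 1/m + (2/m^2) sum_{j<k} ..."""
        sh = make_phi_shannon()
        asym = kappa_asymptotics(np.array([1 / 3, 2 / 3]), sh)
        assert asym.sigma2 == pytest.approx(0.625, abs=1e-12)
        for _ in range(10):
            m = int(rng.integers(2, 6))
            f = random_cdf(rng, m)
            closed = 1 / m + (2 / m**2) * sum(
                (f[j] * (1 - f[k])) / (f[k] * (1 - f[j]))
                for j, k in itertools.combinations(range(m), 2)
            )
            assert kappa_asymptotics(f, sh).sigma2 == pytest.approx(closed, abs=1e-12)

    def test_iov_closed_form(self, rng):
        """For z(1-z): sigma^2 = sum (f_min - f_j f_k)^2 / (sum f_i(1-f_i))^2."""
        for _ in range(10):
            f = random_cdf(rng, 4)
            num = sum(
                (min(f[j], f[k]) - f[j] * f[k]) ** 2
                for j in range(4)
                for k in range(4)
            )
            closed = num / (f * (1 - f)).sum() ** 2
            assert kappa_asymptotics(f, make_phi_a(2)).sigma2 == pytest.approx(
                closed, abs=1e-12
            )


def enumeration_moments(pmf, n, h):
    """Exact small-n moments of (f_hat_0, f_hat_00(h)) on a binary scale.

    Enumerates all (m+1)^n sequences of i.i.d. draws with the given pmf and
    accumulates the exact covariances of the marginal ECDF component and
    the lag-h bivariate diagonal (denominator n - h).  Independent oracle
    for the asymptotic covariance blocks.
    """
    k = len(pmf)
    cov = np.zeros((2, 2))
    mean = np.zeros(2)
    stats = []
    for seq in itertools.product(range(k), repeat=n):
        p = float(np.prod([pmf[c] for c in seq]))
        a = np.array([c == 0 for c in seq], dtype=float)  # 1{X_t <= s_0}, m=1
        fhat = a.mean()
        fhh = (a[h:] * a[:-h]).sum() / (n - h)
        stats.append((p, fhat, fhh))
    for p, x, y in stats:
        mean += p * np.array([x, y])
    for p, x, y in stats:
        v = np.array([x, y]) - mean
        cov += p * np.outer(v, v)
    return cov


class TestIidCdfCovariances:
    def test_matrix_is_symmetric_psd(self, rng):
        for _ in range(10):
            sigma = iid_cdf_covariances(random_cdf(rng, 4))
            assert np.allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10

    @pytest.mark.parametrize("f0", [0.3, 0.5, 0.7])
    def test_blocks_against_small_n_enumeration(self, f0):
        """Exact enumeration at n = 6, m = 1 pins down all three blocks.

        The exact finite-n covariances are
          n Cov(fh, fh)      = c
          n Cov(fh, fhh)     = 2 f c                      (exact at any n)
          n Cov(fhh, fhh)    = n [(n-h)(fmin^2 - f^4) + 2(n-2h) f^2 c] / (n-h)^2
        whose n -> infinity limit is the asymptotic block (fmin + 3 f^2) c.
        """
        n, h = 6, 1
        f = np.array([f0])
        c = f0 - f0**2
        cov = enumeration_moments([f0, 1 - f0], n, h)
        assert n * cov[0, 0] == pytest.approx(c, abs=1e-12)
        assert n * cov[0, 1] == pytest.approx(2 * f0 * c, abs=1e-12)
        exact_biv = n * ((n - h) * (f0**2 - f0**4) + 2 * (n - 2 * h) * f0**2 * c) / (
            n - h
        ) ** 2
        assert n * cov[1, 1] == pytest.approx(exact_biv, abs=1e-12)
        # the asymptotic matrix is the n -> infinity limit of those formulas
        sigma = iid_cdf_covariances(f)
        assert sigma[0, 0] == pytest.approx(c)
        assert sigma[0, 1] == pytest.approx(2 * f0 * c)
        assert sigma[1, 1] == pytest.approx((f0 + 3 * f0**2) * c)

    def test_delta_method_identity(self, rng):
        """g Sigma(h) g' = sigma_kappa^2 with g = (-2 f_j u_j, u_j)."""
        egfs = [make_phi_a(a) for a in (1.5, 2.0, 2.5)] + [
            make_phi_q(4),
            make_phi_shannon(),
        ]
        for _ in range(100):
            m = int(rng.integers(1, 6))
            f = random_cdf(rng, m)
            sigma = iid_cdf_covariances(f)
            for egf in egfs:
                asym = kappa_asymptotics(f, egf)
                g = np.concatenate([-2 * f * asym.u, asym.u])
                assert float(g @ sigma @ g) == pytest.approx(asym.sigma2, abs=1e-10)


class TestSerialDependenceTest:
    def test_critical_pair_centered_at_null_bias(self, rng):
        series = simulate(bar1_model(4, 0.3, 0.0), 300, seed=5)
        res = test_serial_dependence(series, make_phi_a(2.5), lags=range(1, 6))
        assert res.lo < -1 / res.n < res.hi
        assert abs((res.lo + res.hi) / 2 - (-1 / res.n)) < 1e-12
        # reject flag consistent with the critical pair
        expected = (res.kappa_hat < res.lo) | (res.kappa_hat > res.hi)
        assert np.array_equal(res.reject, expected)

    def test_detects_strong_dependence(self):
        series = simulate(bar1_model(4, 0.5, 0.6), 500, seed=17)
        res = test_serial_dependence(series, make_phi_a(2.5), lags=[1, 2])
        assert res.reject[0]
        assert res.kappa_hat[0] > 0
        assert res.p_values[0] < 1e-4

    def test_negative_dependence_detected_with_sign(self):
        series = simulate(bar1_model(4, 0.5, -0.5), 500, seed=23)
        res = test_serial_dependence(series, make_phi_a(2.5), lags=[1])
        assert res.kappa_hat[0] < 0
        assert res.reject[0]

    def test_short_series_and_bad_lags_rejected(self):
        series = simulate(bar1_model(2, 0.5, 0.0), 10, seed=1)
        with pytest.raises(ValueError):
            test_serial_dependence(series, make_phi_a(2), lags=[9])
        with pytest.raises(ValueError):
            test_serial_dependence(series, make_phi_a(2), lags=[0])

    def test_degenerate_sample_rejected(self):
        series = OrdinalSeries(np.zeros(50, dtype=int), OrdinalScale.integer(3))
        with pytest.raises(ValueError):
            test_serial_dependence(series, make_phi_a(2), lags=[1])
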