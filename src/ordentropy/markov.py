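"""Exact theory for finite-state ordinal Markov chains.

A stationary ergodic Markov chain on the rank counts {0, ..., m} determines
every population quantity in this package in closed form: the stationary
marginal CDF, the lagged bivariate CDFs f_ij(h) via matrix powers, the
dependence sequences kappa_phi(h) / vartheta_phi(h), and the infinite-sum
factors that inflate the bias and SE of the dispersion estimator.  Two
data-generating processes are shipped:

* :func:`bar1_model` — the first-order binomial autoregressive (BAR(1))
  chain, I_t = alpha o I_{t-1} + beta o (m - I_{t-1}) with binomial
  thinning, which has Bin(m, p) stationary marginal and rank-count
  autocorrelation rho^h;
* :func:`oitp_model` — a one-inflated truncated-Poisson chain, where the
  conditional law of I_t mixes a point mass at state 1 (weight omega) with
  a Poisson(lambda0 + lambda1 * I_{t-1}) distribution truncated to
  {0, ..., m}; with its default parameters this is the published fit to
  the daily Shanghai air-quality level series.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import stats

from .core import LaggedBivariateCDF, MarginalCDF, OrdinalScale
from .egf import EGF, weights

__all__ = [
    "MarkovOrdinalModel",
    "TheoreticalDependence",
    "stationary_distribution",
    "theoretical_kappa_sequence",
    "bar1_model",
    "iid_model",
    "oitp_model",
    "model_from_name",
]


@dataclass(frozen=True)
class MarkovOrdinalModel:
    """A homogeneous Markov chain on an ordinal scale.

    ``P[k, j] = P(I_t = j | I_{t-1} = k)``.  The stationary distribution is
    computed lazily and cached; construction only validates stochasticity.
    """

    P: np.ndarray
    scale: OrdinalScale

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        k = self.scale.m + 1
        if P.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}; got {P.shape}")
        if P.min() < -1e-12:
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def m(self) -> int:
        return self.scale.m

    @cached_property
    def stationary(self) -> np.ndarray:
        return stationary_distribution(self)

    @cached_property
    def marginal_cdf(self) -> MarginalCDF:
        return MarginalCDF(np.cumsum(self.stationary)[: self.m], self.scale)

    def lagged_bivariate(self, h: int) -> LaggedBivariateCDF:
        """Exact f_ij(h) = sum_{k<=j} sum_{l<=i} pi_k (P^h)[k, l]."""
        h = int(h)
        if h < 1:
            raise ValueError("lag must be a positive integer")
        Ph = np.linalg.matrix_power(self.P, h)
        joint = self.stationary[:, None] * Ph  # joint[k, l] = P(I_{t-h}=k, I_t=l)
        cum = joint.cumsum(axis=0).cumsum(axis=1)
        return LaggedBivariateCDF(
            h=h, fij=cum[: self.m, : self.m].T, marginal=self.marginal_cdf
        )


def stationary_distribution(model: MarkovOrdinalModel) -> np.ndarray:
    """Unique stationary vector of an irreducible aperiodic chain.

    Ergodicity is checked by requiring some power of P up to 2(m + 1) to be
    strictly positive; pi then solves pi P = pi, sum pi = 1 via least
    squares on the overdetermined linear system.
    """
    P = model.P
    k = P.shape[0]
    Q = np.eye(k)
    for _ in range(2 * k):
        Q = Q @ P
        if np.all(Q > 0):
            break
    else:
        raise ValueError(
            "chain is not ergodic (no power of P up to 2(m+1) is strictly "
            "positive); stationary distribution not unique"
        )
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class TheoreticalDependence:
    """Model-implied dependence sequences and Theorem-style factors.

    ``bias_factor`` = 1 + 2 sum_h kappa_phi(h) multiplies the i.i.d. bias;
    ``var_factor`` = 1 + 2 sum_h vartheta_phi(h) multiplies the i.i.d.
    variance, so the SE is inflated by ``se_factor`` = sqrt(var_factor).
    """

    kappa: np.ndarray
    theta: np.ndarray
    bias_factor: float
    var_factor: float
    truncation_lag: int
    tol: float

    @property
    def se_factor(self) -> float:
        return float(np.sqrt(self.var_factor))


def theoretical_kappa_sequence(
    model: MarkovOrdinalModel,
    egf: EGF,
    *,
    tol: float = 1e-10,
    max_lag: int = 10_000,
) -> TheoreticalDependence:
    """Exact kappa_phi(h) and vartheta_phi(h) sequences for a Markov model.

    Lags are accumulated until both per-lag increments fall below ``tol``
    in absolute value (geometric mixing makes the tails negligible), with a
    hard cap at ``max_lag``.
    """
    egf.require_smoothness(2, "theoretical dependence sequences")
    f = model.marginal_cdf.f
    w = weights(egf, f)
    if not w.finite.all():
        raise ValueError(
            "stationary CDF has boundary components with divergent weights; "
            "theoretical sequences undefined for this EGF"
        )
    d, hw = w.d, w.h
    cov0 = np.minimum.outer(f, f) - np.outer(f, f)
    sigma2_iid = float(d @ cov0 @ d)
    kden = float((hw * f * (1 - f)).sum())
    if sigma2_iid <= 0 or kden == 0:
        raise ValueError("degenerate stationary CDF: dependence sequences undefined")

    Ph = np.eye(model.m + 1)
    kappas: list[float] = []
    thetas: list[float] = []
    pi = model.stationary
    for _ in range(max_lag):
        Ph = Ph @ model.P
        joint = pi[:, None] * Ph
        cum = joint.cumsum(axis=0).cumsum(axis=1)
        fij = cum[: model.m, : model.m].T
        dev = fij - np.outer(f, f)
        th = float(d @ dev @ d) / sigma2_iid
        kap = float((hw * (np.diag(fij) - f**2)).sum()) / kden
        kappas.append(kap)
        thetas.append(th)
        if abs(th) < tol and abs(kap) < tol:
            break
    kappa = np.asarray(kappas)
    theta = np.asarray(thetas)
    return TheoreticalDependence(
        kappa=kappa,
        theta=theta,
        bias_factor=float(1 + 2 * kappa.sum()),
        var_factor=float(1 + 2 * theta.sum()),
        truncation_lag=len(kappas),
        tol=tol,
    )


# ---------------------------------------------------------------------------
# Shipped data-generating processes


def bar1_model(m: int, p: float, rho: float) -> MarkovOrdinalModel:
    """A BAR(1) chain: Bin(m, p) marginal, lag-h rank-count ACF rho^h.

    The transition from state k convolves Bin(k, alpha) with Bin(m - k,
    beta), where alpha = p(1 - rho) + rho and beta = p(1 - rho) are the
    thinning probabilities.  rho may be negative only down to
    max(-(1-p)/p, -p/(1-p)), the attainability bound that keeps both
    thinning probabilities in [0, 1]; rho = 0 gives i.i.d. rows.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    lower = max(-(1 - p) / p, -p / (1 - p))
    if not lower <= rho < 1:
        raise ValueError(
            f"BAR(1) dependence rho={rho} outside the attainable range "
            f"[{lower:.4g}, 1) for p={p}"
        )
    alpha = p * (1 - rho) + rho
    beta = p * (1 - rho)
    j = np.arange(m + 1)
    P = np.empty((m + 1, m + 1))
    for k in range(m + 1):
        a_pmf = stats.binom.pmf(np.arange(k + 1), k, alpha)
        b_pmf = stats.binom.pmf(np.arange(m - k + 1), m - k, beta)
        P[k] = np.convolve(a_pmf, b_pmf)
    P /= P.sum(axis=1, keepdims=True)
    return MarkovOrdinalModel(P, OrdinalScale.integer(m))


def iid_model(m: int, p: float) -> MarkovOrdinalModel:
    """Serially independent Bin(m, p) rank counts (BAR(1) with rho = 0)."""
    return bar1_model(m, p, 0.0)


def oitp_model(
    lambda0: float = 0.3489,
    lambda1: float = 0.7594,
    omega: float = 0.3463,
    m: int = 5,
) -> MarkovOrdinalModel:
    """One-inflated truncated-Poisson autoregressive chain on {0, ..., m}.

    Row k mixes a point mass at state 1 (weight omega) with a Poisson
    distribution of mean lambda0 + lambda1 * k truncated to {0, ..., m}.
    The defaults are the published fit to the daily Shanghai air-quality
    level series (six categories from "excellent" to "severely polluted").
    """
    if not 0 <= omega < 1:
        raise ValueError("one-inflation omega must lie in [0, 1)")
    if m < 1:
        raise ValueError("need at least two states")
    states = np.arange(m + 1)
    P = np.empty((m + 1, m + 1))
    for k in range(m + 1):
        lam = lambda0 + lambda1 * k
        if lam <= 0:
            raise ValueError(f"non-positive Poisson mean {lam} at state {k}")
        pmf = stats.poisson.pmf(states, lam)
        pmf = pmf / pmf.sum()
        P[k] = (1 - omega) * pmf
        P[k, 1] += omega
    return MarkovOrdinalModel(P, OrdinalScale.integer(m))


def model_from_name(spec: str) -> MarkovOrdinalModel:
    """Parse a model spec string.

    Forms: ``"iid:m=4,p=0.3"``, ``"bar1:m=4,p=0.3,rho=0.4"``,
    ``"oitp:defaults"`` or ``"oitp:lambda0=...,lambda1=...,omega=...,m=..."``.
    """
    name, _, rest = spec.strip().partition(":")
    params: dict[str, float] = {}
    if rest and rest != "defaults":
        for item in rest.split(","):
            key, _, val = item.partition("=")
            params[key.strip()] = float(val)
    if name == "iid":
        return iid_model(int(params["m"]), params["p"])
    if name == "bar1":
        return bar1_model(int(params["m"]), params["p"], params["rho"])
    if name == "oitp":
        kwargs = {k: params[k] for k in ("lambda0", "lambda1", "omega") if k in params}
        if "m" in params:
            kwargs["m"] = int(params["m"])
        return oitp_model(**kwargs)
    raise ValueError(f"unknown model spec {spec!r} (expected iid/bar1/oitp)")
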