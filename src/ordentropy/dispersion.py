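"""Cumulative paired entropy dispersion measures and their asymptotics.

The normalized cumulative paired phi-entropy of a marginal CDF f is

    CPE_phi(f) = (1 / (2 m phi(1/2))) * sum_{i<m} [phi(f_i) + phi(1 - f_i)],

which is 0 exactly at one-point distributions and 1 exactly at the extreme
two-point (polarized) distribution.  Classical ordinal dispersion indices
are special cases: Leik's ordinal variation (q = 1), the OV_q family, the
index of ordinal variation IOV (a = 2 or 3, q = 2) and the cumulative
paired Shannon entropy (a -> 1).

For stationary short-memory ordinal time series the plug-in estimator
CPE_phi(f_hat) is asymptotically normal.  Writing d_k and h_kk for the
gradient and Hessian-diagonal weights of CPE_phi at f,

    sqrt(n) (CPE_phi(f_hat) - CPE_phi(f))  ->  N(0, sigma_phi^2),
    sigma_phi^2     = sigma_iid^2 * (1 + 2 sum_h vartheta_phi(h)),
    sigma_iid^2     = sum_{i,j} d_i d_j (f_min(i,j) - f_i f_j),
    vartheta_phi(h) = sum_{i,j} d_i d_j (f_ij(h) - f_i f_j) / sigma_iid^2,

and the estimator has negative bias

    E CPE_phi(f_hat) - CPE_phi(f)
        ~ (1 / 2n) sum_i h_ii f_i (1 - f_i) * (1 + 2 sum_h kappa_phi(h)),

where kappa_phi(h) is the matched serial-dependence measure implemented in
:mod:`ordentropy.dependence`.  Serial dependence thus inflates both the
standard error (through vartheta) and the bias (through kappa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LaggedBivariateCDF, MarginalCDF, OrdinalSeries, ecdf, lagged_ecdf
from .egf import EGF, Weights, make_phi_a, make_phi_shannon, weights

__all__ = [
    "cpe",
    "lov",
    "ov_q",
    "iov",
    "cpe_shannon",
    "cpe_a",
    "DispersionAsymptotics",
    "DispersionResult",
    "dispersion_asymptotics",
    "estimate_dispersion",
]

_DEGENERATE_TOL = 1e-12


def cpe(f: MarginalCDF | np.ndarray, egf: EGF) -> float:
    """The normalized cumulative paired phi-entropy CPE_phi(f) in [0, 1]."""
    fv = np.asarray(getattr(f, "f", f), dtype=float)
    m = fv.shape[0]
    vals = egf.value(fv) + egf.value(1.0 - fv)
    return float(vals.sum() / (2 * m * egf.half_value))


def cpe_rows(F: np.ndarray, egf: EGF) -> np.ndarray:
    """Row-wise CPE_phi for a (R, m) matrix of CDF vectors (Monte-Carlo helper)."""
    F = np.asarray(F, dtype=float)
    m = F.shape[-1]
    return (egf.value(F) + egf.value(1.0 - F)).sum(axis=-1) / (2 * m * egf.half_value)


def lov(f: MarginalCDF | np.ndarray) -> float:
    """Leik's ordinal variation: 1 - (1/m) sum |2 f_i - 1|."""
    fv = np.asarray(getattr(f, "f", f), dtype=float)
    return float(1.0 - np.abs(2 * fv - 1).mean())


def ov_q(f: MarginalCDF | np.ndarray, q: float) -> float:
    """The ordinal variation OV_q = 1 - ((1/m) sum |2 f_i - 1|^q)^(1/q), q >= 1.

    Related to the entropy family by OV_q = 1 - (1 - CPE_{phi_q}(f))^(1/q).
    """
    if q < 1:
        raise ValueError("OV_q needs q >= 1")
    fv = np.asarray(getattr(f, "f", f), dtype=float)
    return float(1.0 - (np.abs(2 * fv - 1) ** q).mean() ** (1.0 / q))


def iov(f: MarginalCDF | np.ndarray) -> float:
    """The index of ordinal variation, (4/m) sum f_i (1 - f_i)."""
    fv = np.asarray(getattr(f, "f", f), dtype=float)
    return float(4.0 * (fv * (1 - fv)).mean())


def cpe_shannon(f: MarginalCDF | np.ndarray) -> float:
    """The cumulative paired Shannon entropy (a -> 1 member of the family)."""
    return cpe(f, make_phi_shannon())


def cpe_a(f: MarginalCDF | np.ndarray, a: float) -> float:
    """CPE under the a-entropy EGF; a = 2 and a = 3 both give the IOV."""
    return cpe(f, make_phi_a(a))


# ---------------------------------------------------------------------------
# Asymptotics


@dataclass(frozen=True)
class DispersionAsymptotics:
    """Asymptotic variance and bias ingredients of the CPE_phi estimator.

    ``sigma2`` is the variance of sqrt(n)-scaled estimation error;
    ``bias_iid`` the n-free bias factor (1/2) sum h_ii f_i (1 - f_i), so the
    first-order bias is ``bias_iid * dependence_factor_bias / n``.  The
    variance dependence factor 1 + 2 sum_h vartheta(h) acts on the variance
    scale; ``se_factor`` is its square root, the multiplier for the SE.
    For i.i.d. input both factors are exactly 1 and the lag sequences empty.
    """

    sigma2_iid: float
    theta: np.ndarray
    dependence_factor_var: float
    sigma2: float
    bias_iid: float
    kappa_seq: np.ndarray
    dependence_factor_bias: float
    truncation_lag: int
    tol: float
    degenerate: bool = False
    excluded: np.ndarray | None = None

    @property
    def se_factor(self) -> float:
        """SE inflation sqrt(1 + 2 sum_h vartheta(h))."""
        return float(np.sqrt(self.dependence_factor_var))

    def bias(self, n: int) -> float:
        return self.bias_iid * self.dependence_factor_bias / n

    def se(self, n: int) -> float:
        return float(np.sqrt(self.sigma2 / n))


@dataclass(frozen=True)
class DispersionResult:
    """A CPE_phi point estimate with asymptotic uncertainty."""

    estimate: float
    bias: float
    bias_corrected: float
    se: float
    ci: tuple[float, float]
    level: float
    n: int
    egf_name: str
    dependence_mode: str
    asymptotics: DispersionAsymptotics
    degenerate: bool = False


def _theta_terms(f: np.ndarray, d: np.ndarray, mask: np.ndarray):
    """Precompute the i.i.d. quadratic form sum d_i d_j (f_min - f_i f_j)."""
    dm = np.where(mask, d, 0.0)
    cov = np.minimum.outer(f, f) - np.outer(f, f)
    return float(dm @ cov @ dm), dm


def dispersion_asymptotics(
    f: MarginalCDF | np.ndarray,
    egf: EGF,
    dependence=None,
    *,
    tol: float = 1e-10,
    max_lag: int = 10_000,
) -> DispersionAsymptotics:
    """Asymptotic SE/bias ingredients of CPE_phi(f_hat) at a marginal CDF.

    Parameters
    ----------
    f
        The marginal CDF at which the gradient d and Hessian diagonal h are
        evaluated (the true CDF in theory, the sample CDF as plug-in).
    egf
        A twice-differentiable EGF (variance alone needs one derivative).
    dependence
        ``None`` for i.i.d.; a sequence of :class:`LaggedBivariateCDF`
        (e.g. empirical plug-ins up to a chosen lag H); or a Markov model
        from :mod:`ordentropy.markov`, whose exact lagged bivariate CDFs
        are summed until the per-lag increments fall below ``tol``.
    tol, max_lag
        Truncation rule for the infinite dependence sums.

    Categories whose weights diverge at boundary CDF components are excluded
    from all sums with a warning (the affected terms carry zero information
    but would otherwise poison the arithmetic).
    """
    fcdf = f if isinstance(f, MarginalCDF) else MarginalCDF(np.asarray(f, float))
    fv = fcdf.f
    egf.require_smoothness(1, "dispersion asymptotics")
    w: Weights = weights(egf, fv)
    mask = w.finite
    if not mask.all():
        warnings.warn(
            "boundary CDF components with divergent weights excluded from "
            "asymptotic sums",
            RuntimeWarning,
            stacklevel=2,
        )
    degenerate = bool(np.all(np.abs(np.where(mask, w.d, 0.0)) < _DEGENERATE_TOL))
    sigma2_iid, dm = _theta_terms(fv, w.d, mask)
    hm = np.where(mask, w.h, 0.0)
    bias_iid = 0.5 * float((hm * fv * (1 - fv)).sum())

    theta_list: list[float] = []
    kappa_list: list[float] = []
    kden = float((hm * fv * (1 - fv)).sum())  # denominator of kappa_phi

    def add_lag(biv: LaggedBivariateCDF) -> tuple[float, float]:
        dev = biv.fij - np.outer(fv, fv)
        th = float(dm @ dev @ dm) / sigma2_iid if sigma2_iid > 0 else 0.0
        kap = (
            float((hm * (biv.diagonal - fv**2)).sum()) / kden if kden != 0 else 0.0
        )
        theta_list.append(th)
        kappa_list.append(kap)
        return th, kap

    if dependence is None:
        pass
    elif hasattr(dependence, "lagged_bivariate"):
        # model route: the dependence factors are ratios of model quantities,
        # so they are evaluated entirely at the model's stationary CDF (the
        # i.i.d. ingredients above may still use a plugged-in sample CDF)
        from .markov import theoretical_kappa_sequence

        dep = theoretical_kappa_sequence(dependence, egf, tol=tol, max_lag=max_lag)
        theta_list = list(dep.theta)
        kappa_list = list(dep.kappa)
    else:
        for biv in dependence:
            add_lag(biv)

    theta = np.asarray(theta_list)
    kappa = np.asarray(kappa_list)
    factor_var = float(1.0 + 2.0 * theta.sum())
    factor_bias = float(1.0 + 2.0 * kappa.sum())
    return DispersionAsymptotics(
        sigma2_iid=sigma2_iid,
        theta=theta,
        dependence_factor_var=factor_var,
        sigma2=sigma2_iid * factor_var,
        bias_iid=bias_iid,
        kappa_seq=kappa,
        dependence_factor_bias=factor_bias,
        truncation_lag=len(theta_list),
        tol=tol,
        degenerate=degenerate,
        excluded=~mask if not mask.all() else None,
    )


def estimate_dispersion(
    series: OrdinalSeries,
    egf: EGF,
    *,
    level: float = 0.95,
    dependence: str | object = "iid",
    tol: float = 1e-10,
) -> DispersionResult:
    """Estimate CPE_phi from data with bias correction and a normal CI.

    ``dependence`` selects how the serial-dependence factors of the SE and
    bias are obtained:

    * ``"iid"`` — no adjustment (both factors 1);
    * ``"plugin:H"`` — empirical lagged CDFs at lags 1..H plugged into the
      dependence sums (H is the user's explicit truncation choice);
    * a Markov model — model-implied factors from its exact lagged
      bivariate CDFs, with weights still evaluated at the sample CDF.

    For a degenerate two-point sample CDF the gradient vanishes, the limit
    is chi-square rather than normal, and the CI is withheld (NaN bounds,
    ``degenerate`` flag set).
    """
    if series.n < 2:
        raise ValueError("need at least two observations")
    egf.require_smoothness(2, "bias-corrected dispersion estimation")
    fhat = ecdf(series)
    est = cpe(fhat, egf)

    mode = dependence if isinstance(dependence, str) else "model"
    if dependence == "iid":
        dep_arg = None
    elif isinstance(dependence, str) and dependence.startswith("plugin:"):
        H = int(dependence.split(":", 1)[1])
        if not 1 <= H <= series.n - 1:
            raise ValueError(f"plug-in truncation lag H must be in 1..{series.n - 1}")
        dep_arg = [lagged_ecdf(series, h) for h in range(1, H + 1)]
    elif isinstance(dependence, str):
        raise ValueError(f"unknown dependence mode {dependence!r}")
    else:
        dep_arg = dependence  # a Markov model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        asym = dispersion_asymptotics(fhat, egf, dep_arg, tol=tol)
    bias = asym.bias(series.n)
    corrected = est - bias
    se = asym.se(series.n)
    if asym.degenerate:
        ci = (float("nan"), float("nan"))
    else:
        z = stats.norm.ppf(0.5 + level / 2)
        ci = (corrected - z * se, corrected + z * se)
    return DispersionResult(
        estimate=est,
        bias=bias,
        bias_corrected=corrected,
        se=se,
        ci=ci,
        level=level,
        n=series.n,
        egf_name=egf.name,
        dependence_mode=mode,
        asymptotics=asym,
        degenerate=asym.degenerate,
    )
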