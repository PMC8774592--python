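"""Entropy generating functions (EGFs) and their derivative weights.

An EGF is a concave function ``phi`` on [0, 1] with ``phi(0) = phi(1) = 0``.
Every such function induces a normalized cumulative paired entropy

    CPE_phi(f) = (1 / (2 m phi(1/2))) * sum_i [phi(f_i) + phi(1 - f_i)]

over the marginal CDF ``f`` of an ordinal random variable, and, through its
second derivative, a weighted kappa-type measure of serial dependence.  The
module ships the two parametric families used in practice:

* the *a*-entropies  ``phi_a(z) = (z - z^a) / (a - 1)``  (a > 0, a != 1),
  with the cumulative paired Shannon entropy ``-z ln z`` as the limit a -> 1;
* the *q*-entropies  ``phi_q(z) = 1 - |2z - 1|^q``  (q >= 1), which generate
  the ordinal-variation family OV_q (q = 1: Leik's measure, q = 2: IOV).

Derivatives are closed-form, with the conventions ``0 ln 0 = 0`` and
``0^0 = 1`` applied explicitly; nothing downstream differentiates numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "EGF",
    "Weights",
    "make_phi_a",
    "make_phi_shannon",
    "make_phi_q",
    "weights",
    "egf_from_name",
]


@dataclass(frozen=True)
class EGF:
    """An entropy generating function with closed-form derivatives.

    Attributes
    ----------
    name
        Human-readable label, e.g. ``"a-entropy:a=2.5"``.
    value, first_deriv, second_deriv
        Vectorized callables on [0, 1] (derivatives on the open interval,
        plus the boundary where they exist; divergent boundary values are
        returned as ``inf`` rather than raising).
    half_value
        ``phi(1/2)``, the normalization constant of the induced dispersion
        measure; strictly positive for any non-trivial EGF.
    smoothness_order
        How many derivatives exist everywhere they are needed by the
        asymptotic theory: 2 permits variance *and* bias expansions, 1 only
        the variance, 0 neither.
    symmetric
        Whether ``phi(z) = phi(1 - z)``.
    family_params
        The generating parameter (``{"a": ...}`` or ``{"q": ...}``), empty
        for the Shannon case.
    """

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    first_deriv: Callable[[np.ndarray], np.ndarray]
    second_deriv: Callable[[np.ndarray], np.ndarray]
    half_value: float
    smoothness_order: int
    symmetric: bool = False
    family_params: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EGF({self.name!r})"

    def require_smoothness(self, order: int, context: str) -> None:
        """Raise if the EGF lacks the derivatives the caller needs.

        Non-smooth generators (q < 2, a < 1) yield valid dispersion values
        but no normal asymptotics, so the asymptotic code paths refuse them.
        """
        if self.smoothness_order < order:
            raise ValueError(
                f"{context} requires an EGF that is {order}x differentiable; "
                f"{self.name} has smoothness order {self.smoothness_order}. "
                "Non-smooth generators admit no normal approximation "
                "(consider a >= 1 / q >= 2, or a bootstrap)."
            )


@dataclass(frozen=True)
class Weights:
    """Gradient and Hessian-diagonal weights of CPE_phi at a CDF f.

    ``d[k] = (phi'(f_k) - phi'(1 - f_k)) / (2 m phi(1/2))`` and
    ``h[k] = (phi''(f_k) + phi''(1 - f_k)) / (2 m phi(1/2))``; ``h`` is
    non-positive by concavity.  Entries are ``+-inf`` where a boundary
    value f_k in {0, 1} meets a derivative that diverges there; consumers
    decide how to treat those (see the kappa-star workaround).
    """

    d: np.ndarray
    h: np.ndarray
    scale_size: int

    @property
    def finite(self) -> np.ndarray:
        """Boolean mask of categories with finite d and h entries."""
        return np.isfinite(self.d) & np.isfinite(self.h)


def _asarray(z) -> np.ndarray:
    return np.asarray(z, dtype=float)


def make_phi_a(a: float) -> EGF:
    """The a-entropy EGF ``phi_a(z) = (z - z^a) / (a - 1)``, a > 0, a != 1.

    a = 2 and a = 3 both induce the index of ordinal variation; the limit
    a -> 1 is the Shannon case (request it via :func:`make_phi_shannon`).
    ``phi_a`` is twice differentiable on [0, 1] only for a >= 2; for
    1 < a < 2 the second derivative diverges at z = 0, and for a < 1
    already the first derivative does, so such EGFs are barred from the
    asymptotic machinery via ``smoothness_order``.
    """
    a = float(a)
    if a <= 0 or a == 1:
        raise ValueError(
            "a-entropy needs a > 0 and a != 1 (use make_phi_shannon() for the "
            "a -> 1 limit)"
        )

    def value(z):
        z = _asarray(z)
        with np.errstate(invalid="ignore"):
            return (z - z**a) / (a - 1)

    def first_deriv(z):
        z = _asarray(z)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (1 - a * z ** (a - 1)) / (a - 1)
        if a < 1:
            out = np.where(z == 0, np.inf, out)
        return out

    def second_deriv(z):
        z = _asarray(z)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -a * z ** (a - 2)
        if a < 2:
            out = np.where(z == 0, -np.inf, out)
        return out

    # phi_a is twice differentiable on (0, 1) for every a > 1; for a < 2 the
    # second derivative diverges at z = 0 (and already the first for a < 1),
    # which the weight machinery flags per component.  a < 1 is barred from
    # the asymptotic paths outright: its boundary blow-up is so strong that
    # the normal approximation is useless in practice.
    order = 2 if a > 1 else 0
    return EGF(
        name=f"a-entropy:a={a:g}",
        value=value,
        first_deriv=first_deriv,
        second_deriv=second_deriv,
        half_value=(0.5 - 0.5**a) / (a - 1),
        smoothness_order=order,
        symmetric=(a == 2),  # z(1 - z) is the one symmetric member
        family_params={"a": a},
    )


def make_phi_shannon() -> EGF:
    """The Shannon EGF ``phi(z) = -z ln z`` (convention 0 ln 0 = 0).

    The a -> 1 limit of the a-entropies; induces the cumulative paired
    Shannon entropy.  Both derivatives diverge at the boundary, so weight
    entries at f_k in {0, 1} come out infinite and are flagged downstream.
    """

    def value(z):
        z = _asarray(z)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -z * np.log(z)
        return np.where(z == 0, 0.0, out)

    def first_deriv(z):
        z = _asarray(z)
        with np.errstate(divide="ignore"):
            return -1.0 - np.log(z)

    def second_deriv(z):
        z = _asarray(z)
        with np.errstate(divide="ignore"):
            out = -1.0 / z
        return np.where(z == 0, -np.inf, out)

    return EGF(
        name="shannon",
        value=value,
        first_deriv=first_deriv,
        second_deriv=second_deriv,
        half_value=0.5 * np.log(2.0),
        smoothness_order=2,  # twice differentiable on (0, 1); boundary flagged
        symmetric=False,
        family_params={},
    )


def make_phi_q(q: float, *, allow_nonsmooth: bool = False) -> EGF:
    """The q-entropy EGF ``phi_q(z) = 1 - |2z - 1|^q``, q >= 2.

    Generates the ordinal-variation family OV_q.  For q >= 2 the function is
    twice differentiable everywhere (with 0^0 = 1 at z = 1/2); for
    1 <= q < 2 it is not, which is known to break the normal asymptotics, so
    those values are admitted only with ``allow_nonsmooth=True`` and tagged
    with a reduced ``smoothness_order``.  q = 1 (Leik) is not differentiable
    at z = 1/2 at all.
    """
    q = float(q)
    if q < 1:
        raise ValueError("q-entropy needs q >= 1")
    if q < 2 and not allow_nonsmooth:
        raise ValueError(
            "q in [1, 2) lacks the smoothness required by the asymptotic "
            "theory; pass allow_nonsmooth=True to build it for plain "
            "dispersion values only"
        )

    def _pow(u, expo):
        # |2z-1|^expo with the 0^0 = 1 convention
        with np.errstate(divide="ignore", invalid="ignore"):
            out = u**expo
        if expo == 0:
            out = np.ones_like(u)
        elif expo < 0:
            out = np.where(u == 0, np.inf, out)
        return out

    def value(z):
        z = _asarray(z)
        return 1.0 - np.abs(2 * z - 1) ** q

    def first_deriv(z):
        z = _asarray(z)
        u = np.abs(2 * z - 1)
        return -2 * q * (2 * z - 1) * _pow(u, q - 2)

    def second_deriv(z):
        z = _asarray(z)
        u = np.abs(2 * z - 1)
        return -4 * q * (q - 1) * _pow(u, q - 2)

    if q >= 2:
        order = 2
    elif q > 1:
        order = 1
    else:
        order = 0
    return EGF(
        name=f"q-entropy:q={q:g}",
        value=value,
        first_deriv=first_deriv,
        second_deriv=second_deriv,
        half_value=1.0,
        smoothness_order=order,
        symmetric=True,
        family_params={"q": q},
    )


def weights(egf: EGF, f: np.ndarray, *, scale_size: int | None = None) -> Weights:
    """Gradient/Hessian weights d_k, h_kk of CPE_phi evaluated at a CDF.

    Parameters
    ----------
    egf
        An EGF with at least first derivatives (second derivatives are
        evaluated too and are ``nan``-free only for smoothness order 2).
    f
        The marginal CDF vector (f_0, ..., f_{m-1}); a ``MarginalCDF`` from
        :mod:`ordentropy.core` is accepted via its array interface.
    scale_size
        m; inferred as ``len(f)`` when omitted.

    Boundary components f_k in {0, 1} combined with boundary-divergent
    derivatives produce infinite entries; a warning is emitted and the
    ``finite`` mask on the result identifies them.
    """
    fv = np.asarray(getattr(f, "f", f), dtype=float)
    m = int(scale_size) if scale_size is not None else fv.shape[0]
    pref = 1.0 / (2 * m * egf.half_value)
    with np.errstate(invalid="ignore"):
        d = pref * (egf.first_deriv(fv) - egf.first_deriv(1 - fv))
        h = pref * (egf.second_deriv(fv) + egf.second_deriv(1 - fv))
    # inf - inf at a boundary point -> nan; normalize to signed infinities
    d = np.where(np.isnan(d) & ((fv == 0) | (fv == 1)), np.inf, d)
    h = np.where(np.isnan(h) & ((fv == 0) | (fv == 1)), -np.inf, h)
    if not (np.isfinite(d).all() and np.isfinite(h).all()):
        warnings.warn(
            f"EGF {egf.name}: divergent derivative weights at boundary CDF "
            "components; affected categories flagged infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    return Weights(d=d, h=h, scale_size=m)


def egf_from_name(spec: str) -> EGF:
    """Parse an EGF specification string.

    Accepted forms: ``"shannon"``, ``"a-entropy:a=2.5"``, ``"q-entropy:q=4"``.
    """
    spec = spec.strip()
    if spec == "shannon":
        return make_phi_shannon()
    if ":" in spec:
        family, _, param = spec.partition(":")
        key, _, val = param.partition("=")
        try:
            x = float(val)
        except ValueError as exc:
            raise ValueError(f"cannot parse EGF parameter in {spec!r}") from exc
        if family == "a-entropy" and key == "a":
            return make_phi_a(x)
        if family == "q-entropy" and key == "q":
            return make_phi_q(x)
    raise ValueError(
        f"unknown EGF spec {spec!r}; expected 'shannon', 'a-entropy:a=<a>' "
        "or 'q-entropy:q=<q>'"
    )
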