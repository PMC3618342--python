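"""Closed-form fractional-order impedance models.

This module evaluates the model family built from three ingredients:

* the constant phase element (CPE), ``Z = 1 / (C_alpha (j w)^alpha)``;
* the Cole dispersion, ``Z = Rinf + (R0 - Rinf) / (1 + (j w tau)^alpha)``;
* a generalized dispersion in which the constant-exponent Cole factor is
  replaced by a non-constant scaling carrying a partial Maclaurin sum in
  the bounded log-frequency variable ``v = (j pi/2) / L`` with
  ``L = Ln(j w tau)`` (``|v| <= 1``, equal to 1 at ``w tau = 1`` and
  vanishing toward both band edges)::

      F(w) = exp( alpha L + beta (v + ln p)
                  + gamma v^2 + delta v^3 + eps v^4 + zeta v^5 )

  The ``beta`` coefficient encodes remnant memory: ``beta = 0`` (with all
  higher coefficients zero) collapses ``F`` to the Cole factor
  ``(j w tau)^alpha`` exactly, for every admissible ``p``.  Non-zero
  coefficients bend the impedance locus away from the Cole circular arc,
  most strongly around the characteristic frequency ``1 / (2 pi tau)``.

Circuits are series combinations of a high-frequency resistance ``r_inf``
and reduced elements (a resistance increment ``dR`` in parallel with a
(generalized) CPE), each contributing ``dR / (1 + F(w))``.

Conventions: ``e^{+j w t}`` drive so capacitive impedances have negative
imaginary part; all equations take angular frequency ``w = 2 pi f``; grids
and files carry ``f`` in Hz.  Complex powers and logarithms are principal
branch throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DomainError,
    InvalidParameterError,
    InvalidSpecError,
    NoSolutionError,
)

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "CPEParams",
    "MaclaurinCoeffs",
    "ElementParams",
    "Element",
    "ModelSpec",
    "CANONICAL_KINDS",
    "eval_cpe",
    "eval_cole",
    "gcpe_scaling",
    "solve_p",
    "element_impedance",
    "eval_gc1",
    "eval_ggc1",
    "eval_serial",
    "dc_limit",
]

ElementKind = Literal["cole", "gencole", "ggc"]

#: canonical label -> ordered element kinds
CANONICAL_KINDS: dict[str, tuple[ElementKind, ...]] = {
    "C1": ("cole",),
    "C2": ("cole", "cole"),
    "C3": ("cole", "cole", "cole"),
    "GC1": ("gencole",),
    "GC2": ("gencole", "gencole"),
    "GC1C1": ("gencole", "cole"),
    "C1GC1": ("cole", "gencole"),
    "GGC1": ("ggc",),
}

#: default frequency (Hz) at which the numerical DC limit is reported
DC_LIMIT_FREQUENCY_HZ = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered, strictly positive measurement frequencies in Hz."""

    f: np.ndarray

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if f.ndim != 1 or f.size == 0:
            raise InvalidParameterError("frequency grid must be a non-empty 1-d array")
        if not np.all(np.isfinite(f)):
            raise InvalidParameterError("frequency grid contains non-finite entries")
        if np.any(f <= 0.0):
            raise InvalidParameterError(
                "frequencies must be strictly positive (w > 0); "
                "use dc_limit() for the DC limit"
            )
        if np.any(np.diff(f) <= 0.0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        object.__setattr__(self, "f", f)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency 2*pi*f, rad/s (derived, never stored)."""
        return 2.0 * np.pi * self.f

    def __len__(self) -> int:
        return self.f.size


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Paired frequencies and complex impedances, optionally replicated.

    Stored long-form: ``f[i]`` (Hz), ``z[i]`` (ohm) and an integer
    ``replicate[i]`` label.  Within each replicate, frequencies must be
    strictly positive and strictly increasing.
    """

    f: np.ndarray
    z: np.ndarray
    replicate: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=complex))
        rep = (
            np.zeros(f.size, dtype=int)
            if self.replicate is None
            else np.atleast_1d(np.asarray(self.replicate, dtype=int))
        )
        if not (f.shape == z.shape == rep.shape):
            raise InvalidParameterError("f, z and replicate must have equal length")
        if not np.all(np.isfinite(f)) or np.any(f <= 0.0):
            raise InvalidParameterError("spectrum frequencies must be finite and > 0")
        if not np.all(np.isfinite(z)):
            raise InvalidParameterError("spectrum impedances must be finite")
        for r in np.unique(rep):
            fr = f[rep == r]
            if np.any(np.diff(fr) <= 0.0):
                raise InvalidParameterError(
                    f"frequencies of replicate {r} must be strictly increasing"
                )
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "replicate", rep)

    @property
    def n_replicates(self) -> int:
        return int(np.unique(self.replicate).size)

    @property
    def frequencies(self) -> np.ndarray:
        """Distinct frequencies, ascending."""
        return np.unique(self.f)

    def mean(self) -> "ImpedanceSpectrum":
        """Per-frequency mean over replicates, as a single-replicate spectrum."""
        fu = self.frequencies
        zm = np.empty(fu.size, dtype=complex)
        for i, fi in enumerate(fu):
            zm[i] = self.z[self.f == fi].mean()
        return ImpedanceSpectrum(f=fu, z=zm)

    def __len__(self) -> int:
        return self.f.size


@dataclass(frozen=True)
class CPEParams:
    """Constant phase element parameters.

    ``c_alpha`` is the capacitance of order ``alpha`` (F s^(alpha-1)
    equivalent).  ``alpha`` in [0, 1]: 0 is a pure resistance, 1 an ideal
    capacitor.  The generalized CPE additionally carries ``beta``, ``tau``
    and ``p``.
    """

    c_alpha: float
    alpha: float
    beta: float = 0.0
    tau: float = 1.0
    p: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.c_alpha) and self.c_alpha > 0.0):
            raise InvalidParameterError(f"c_alpha must be > 0, got {self.c_alpha}")
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidParameterError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (np.isfinite(self.tau) and self.tau > 0.0):
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not (np.isfinite(self.p) and self.p >= 0.0):
            raise InvalidParameterError(f"p must be >= 0, got {self.p}")


@dataclass(frozen=True)
class MaclaurinCoeffs:
    """Higher remnant-memory coefficients of the extended element (GGC)."""

    gamma: float = 0.0
    delta: float = 0.0
    epsilon: float = 0.0
    zeta: float = 0.0

    def __post_init__(self):
        for name in ("gamma", "delta", "epsilon", "zeta"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.gamma, self.delta, self.epsilon, self.zeta)


@dataclass(frozen=True)
class ElementParams:
    """Parameters of one reduced (generalized) Cole element.

    ``dr`` (ohm) is the resistance increment; ``alpha`` in (0, 1]; ``tau``
    (s) > 0; ``p`` >= 0 a dimensionless scaling constant; ``beta`` the
    remnant-memory coefficient (any sign).  ``maclaurin`` holds the higher
    coefficients and marks the element as Maclaurin-extended.
    """

    dr: float
    alpha: float
    tau: float
    p: float = 1.0
    beta: float = 0.0
    maclaurin: Optional[MaclaurinCoeffs] = None

    def __post_init__(self):
        if not (np.isfinite(self.dr) and self.dr >= 0.0):
            raise InvalidParameterError(f"dr must be >= 0, got {self.dr}")
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidParameterError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (np.isfinite(self.tau) and self.tau > 0.0):
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not (np.isfinite(self.p) and self.p >= 0.0):
            raise InvalidParameterError(f"p must be >= 0, got {self.p}")
        if not np.isfinite(self.beta):
            raise InvalidParameterError("beta must be finite")


@dataclass(frozen=True)
class Element:
    kind: ElementKind
    params: ElementParams

    def __post_init__(self):
        if self.kind not in ("cole", "gencole", "ggc"):
            raise InvalidSpecError(f"unknown element kind {self.kind!r}")
        if self.kind == "ggc" and self.params.maclaurin is None:
            raise InvalidSpecError("ggc element requires maclaurin coefficients")
        if self.kind != "ggc" and self.params.maclaurin is not None:
            raise InvalidSpecError(
                "maclaurin coefficients imply a ggc element; "
                f"got kind {self.kind!r}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Series resistance plus an ordered list of reduced elements."""

    name: str
    r_inf: float
    elements: tuple[Element, ...]

    def __post_init__(self):
        if not (np.isfinite(self.r_inf) and self.r_inf >= 0.0):
            raise InvalidParameterError(f"r_inf must be >= 0, got {self.r_inf}")
        elements = tuple(self.elements)
        if len(elements) == 0:
            raise InvalidSpecError("model must contain at least one element")
        if self.name not in CANONICAL_KINDS:
            raise InvalidSpecError(
                f"unknown model label {self.name!r}; "
                f"valid: {sorted(CANONICAL_KINDS)}"
            )
        kinds = tuple(e.kind for e in elements)
        if kinds != CANONICAL_KINDS[self.name]:
            raise InvalidSpecError(
                f"label {self.name!r} requires element kinds "
                f"{CANONICAL_KINDS[self.name]}, got {kinds}"
            )
        object.__setattr__(self, "elements", elements)

    @property
    def r0_classic(self) -> float:
        """DC resistance r_inf + sum(dR).

        Exact for all-classic models; generalized elements have different
        asymptotics for beta != 0, so use :func:`dc_limit` for those.
        """
        return self.r_inf + sum(e.params.dr for e in self.elements)


# ---------------------------------------------------------------------------
# scaling factors
# ---------------------------------------------------------------------------


def _log_jwt(omega: np.ndarray, tau: float) -> np.ndarray:
    """Principal complex logarithm of (j w tau) for w > 0: ln(w tau) + j pi/2."""
    omega = np.asarray(omega, dtype=float)
    with np.errstate(over="ignore"):
        wt = omega * tau
    if np.any(~np.isfinite(wt)) or np.any(wt <= 0.0):
        raise DomainError("omega * tau must be finite and > 0")
    return np.log(wt) + 0.5j * np.pi


def _scaling_exponent(
    omega: np.ndarray,
    alpha: float,
    beta: float,
    tau: float,
    p: float,
    maclaurin: Optional[MaclaurinCoeffs] = None,
) -> np.ndarray:
    """Complex exponent A(w) such that the scaling factor is exp(A)."""
    L = _log_jwt(omega, tau)
    a = alpha * L
    if beta != 0.0:
        if p <= 0.0:
            raise DomainError(
                "p must be > 0 when beta != 0 (ln p enters the scaling)"
            )
        v = (0.5j * np.pi) / L
        a = a + beta * (v + np.log(p))
    if maclaurin is not None:
        v = (0.5j * np.pi) / L
        g, d, e, z = maclaurin.as_tuple()
        v2 = v * v
        a = a + v2 * (g + d * v + e * v2 + z * v2 * v)
    return a


def gcpe_scaling(
    omega,
    alpha: float,
    beta: float,
    tau: float,
    p: float,
    maclaurin: Optional[MaclaurinCoeffs] = None,
) -> np.ndarray:
    """Generalized frequency-scaling factor replacing the Cole ``(j w tau)^alpha``.

    ``F = exp(alpha L + beta (v + ln p) + gamma v^2 + ... + zeta v^5)``
    with ``L = Ln(j w tau)`` principal branch and ``v = (j pi/2)/L``.  For
    ``beta = 0`` (and no Maclaurin coefficients) this is exactly
    ``(j w tau)^alpha``, independent of ``p``: the memoryless Cole case
    with linear (constant-exponent) scaling.
    """
    a = _scaling_exponent(np.asarray(omega, dtype=float), alpha, beta, tau, p, maclaurin)
    with np.errstate(over="ignore", under="ignore"):
        return np.exp(a)


def solve_p(alpha: float, beta: float, tau: float) -> float:
    """Self-consistent non-negative scaling constant p for (alpha, beta, tau).

    Solves ``p = exp(-(beta/alpha) * ln(p tau)^2)`` for the root continuous
    with the memoryless limit (p -> 1 as beta -> 0).  For ``beta = 0`` the
    relation degenerates to the linear-scaling case and returns p = 1
    without any log correction.  The returned root satisfies the relation
    with residual below 1e-10; if no sign change is found in the bracket
    (0, 10] a :class:`NoSolutionError` is raised carrying the bracket and
    the smallest residual seen.

    This is a consistency diagnostic: evaluation and fitting treat p as a
    stored model constant and never call this implicitly.
    """
    if not (0.0 < alpha <= 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")
    if not (np.isfinite(tau) and tau > 0.0):
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    if not np.isfinite(beta):
        raise InvalidParameterError("beta must be finite")
    if beta == 0.0:
        return 1.0

    c = beta / alpha
    lt = np.log(tau)

    def g(x: float) -> float:  # x = ln p
        return x + c * (x + lt) ** 2

    # scan outward from x = 0 (p = 1) for the nearest sign-change bracket
    p_lo, p_hi = 1e-12, 10.0
    xs = np.linspace(np.log(p_lo), np.log(p_hi), 20001)
    vals = np.array([g(x) for x in xs])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0 and not np.any(vals == 0.0):
        best = float(np.min(np.abs(vals)))
        raise NoSolutionError(
            f"no non-negative root of the p relation for alpha={alpha}, "
            f"beta={beta}, tau={tau}",
            bracket=(p_lo, p_hi),
            residual=best,
        )
    # pick the bracket whose midpoint is nearest x = 0 (continuity with p=1)
    i = sign_change[np.argmin(np.abs(0.5 * (xs[sign_change] + xs[sign_change + 1])))]
    x_root = brentq(g, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16)
    p_root = float(np.exp(x_root))
    residual = abs(p_root - np.exp(-c * np.log(p_root * tau) ** 2))
    if residual > 1e-10:
        raise NoSolutionError(
            "root refinement failed", bracket=(p_lo, p_hi), residual=residual
        )
    return p_root


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def eval_cpe(params: CPEParams, grid: FrequencyGrid) -> np.ndarray:
    """CPE impedance ``Z = 1 / (c_alpha (j w)^alpha)``; constant phase -alpha*pi/2."""
    w = grid.omega
    jw_alpha = np.power(w, params.alpha) * np.exp(0.5j * np.pi * params.alpha)
    return 1.0 / (params.c_alpha * jw_alpha)


def eval_cole(
    r0: float, r_inf: float, alpha: float, tau: float, grid: FrequencyGrid
) -> np.ndarray:
    """Cole impedance ``Z = r_inf + (r0 - r_inf) / (1 + (j w tau)^alpha)``."""
    if not (np.isfinite(r_inf) and r_inf >= 0.0):
        raise InvalidParameterError(f"r_inf must be >= 0, got {r_inf}")
    if not (np.isfinite(r0) and r0 > r_inf):
        raise InvalidParameterError(f"r0 must exceed r_inf, got r0={r0}, r_inf={r_inf}")
    if not (0.0 < alpha <= 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")
    if not (np.isfinite(tau) and tau > 0.0):
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    jwt_alpha = (1j * grid.omega * tau) ** alpha
    return r_inf + (r0 - r_inf) / (1.0 + jwt_alpha)


def element_impedance(element: Element, grid: FrequencyGrid) -> np.ndarray:
    """Impedance dR / (1 + F(w)) of one reduced element, overflow-safe.

    Where Re(A) is large the direct form ``dR / (1 + e^A)`` overflows, so the
    algebraically identical ``dR e^{-A} / (1 + e^{-A})`` is used instead.
    """
    prm = element.params
    if element.kind == "cole":
        a = _scaling_exponent(grid.omega, prm.alpha, 0.0, prm.tau, 1.0)
    else:
        a = _scaling_exponent(
            grid.omega, prm.alpha, prm.beta, prm.tau, prm.p, prm.maclaurin
        )
    z = np.empty(a.shape, dtype=complex)
    grow = a.real > 0.0
    with np.errstate(over="ignore", under="ignore"):
        ea = np.exp(np.where(grow, -a, a))
    z[grow] = prm.dr * ea[grow] / (1.0 + ea[grow])
    z[~grow] = prm.dr / (1.0 + ea[~grow])
    return z


def _element_sort_key(el: Element):
    prm = el.params
    mac = prm.maclaurin.as_tuple() if prm.maclaurin is not None else ()
    return (el.kind, prm.dr, prm.alpha, prm.tau, prm.p, prm.beta, mac)


def eval_serial(spec: ModelSpec, grid: FrequencyGrid) -> np.ndarray:
    """Series circuit: ``Z = r_inf + sum_k Z_element_k``.

    Contributions are accumulated in a canonical element order, so permuted
    serial arrangements of the same elements (C1GC1 vs GC1C1) return
    bit-identical impedances.
    """
    parts = [
        element_impedance(el, grid)
        for el in sorted(spec.elements, key=_element_sort_key)
    ]
    return spec.r_inf + np.add.reduce(parts)


def eval_gc1(
    params: ElementParams, r0: float, r_inf: float, grid: FrequencyGrid
) -> np.ndarray:
    """Generalized Cole (GC1) impedance: r_inf in series with one generalized
    reduced element of increment ``r0 - r_inf``.

    For ``beta = 0`` this equals :func:`eval_cole` at every frequency.
    """
    if not (np.isfinite(r0) and r0 > r_inf >= 0.0):
        raise InvalidParameterError(f"need r0 > r_inf >= 0, got r0={r0}, r_inf={r_inf}")
    el = Element("gencole", replace(params, dr=r0 - r_inf, maclaurin=None))
    return r_inf + element_impedance(el, grid)


def eval_ggc1(
    params: ElementParams, r0: float, r_inf: float, grid: FrequencyGrid
) -> np.ndarray:
    """Maclaurin-extended generalized Cole (GGC1) impedance.

    The scaling exponent carries the five-term partial Maclaurin sum
    (beta, gamma, delta, epsilon, zeta).  With gamma = delta = epsilon =
    zeta = 0 this reduces exactly to :func:`eval_gc1`; with beta = 0 as
    well, to :func:`eval_cole`.
    """
    if params.maclaurin is None:
        raise InvalidParameterError("eval_ggc1 requires maclaurin coefficients")
    if not (np.isfinite(r0) and r0 > r_inf >= 0.0):
        raise InvalidParameterError(f"need r0 > r_inf >= 0, got r0={r0}, r_inf={r_inf}")
    el = Element("ggc", replace(params, dr=r0 - r_inf))
    return r_inf + element_impedance(el, grid)


def dc_limit(spec: ModelSpec, f_eval: float = DC_LIMIT_FREQUENCY_HZ) -> complex:
    """Numerical DC limit: the model evaluated at a small positive frequency.

    Generalized elements with beta != 0 need not approach r0 as w -> 0,
    so the limit is reported numerically rather than asserted.
    """
    if f_eval <= 0.0:
        raise InvalidParameterError("f_eval must be > 0")
    return complex(eval_serial(spec, FrequencyGrid(np.array([f_eval])))[0])
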