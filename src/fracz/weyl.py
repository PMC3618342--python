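"""Fractional operators of Weyl type on truncated Fourier series.

A 2*pi-periodic trigonometric polynomial ``sum_k c_k e^{jkx}`` is acted on
coefficient-wise: the classical operator of order ``alpha`` multiplies
``c_k`` by ``(jk)^alpha`` (derivative) or ``(jk)^{-alpha}`` (integral),
principal branch, with the mean term ``c_0`` structurally excluded.  The
generalized operator replaces the constant exponent by the remnant-memory
form ``exp(alpha M + beta (j pi/2)/M)`` with ``M = Ln(j k tau)``, mirroring
the frequency scaling used by the circuit models; ``beta = 0, tau = 1``
recovers the Weyl operator exactly.

These operators exist to cross-check the closed-form impedances: driving
the circuit's fractional constitutive relation with a unit sinusoid and
forming the voltage/current phasor ratio must reproduce the model module's
impedance (see :func:`circuit_impedance_cole` / :func:`circuit_impedance_gc1`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError
from .models import ElementParams

__all__ = [
    "FourierPoly",
    "weyl_apply",
    "weyl_compose_check",
    "gen_weyl_apply",
    "circuit_impedance_cole",
    "circuit_impedance_gc1",
]


@dataclass(frozen=True)
class FourierPoly:
    """Trigonometric polynomial with coefficients c_k, k in [-K, K], period 2*pi."""

    coeffs: np.ndarray  # length 2K+1, index 0 <-> k = -K

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coeffs, dtype=complex))
        if c.ndim != 1 or c.size < 3 or c.size % 2 == 0:
            raise InvalidParameterError(
                "coeffs must have odd length 2K+1 with K >= 1"
            )
        if not np.all(np.isfinite(c)):
            raise InvalidParameterError("coefficients must be finite")
        object.__setattr__(self, "coeffs", c)

    @property
    def degree(self) -> int:
        return (self.coeffs.size - 1) // 2

    @property
    def k(self) -> np.ndarray:
        kk = self.degree
        return np.arange(-kk, kk + 1)

    @property
    def zero_mean(self) -> bool:
        return bool(self.coeffs[self.degree] == 0.0)

    def c(self, k: int) -> complex:
        """Coefficient of e^{jkx}."""
        return complex(self.coeffs[k + self.degree])

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.tensordot(self.coeffs, np.exp(1j * np.outer(self.k, x)), axes=1)

    @classmethod
    def harmonic(cls, k: int, amplitude: complex = 1.0) -> "FourierPoly":
        """The single harmonic amplitude * e^{jkx} (k != 0)."""
        if k == 0:
            raise DomainError("the mean term k = 0 is excluded")
        kk = abs(k)
        c = np.zeros(2 * kk + 1, dtype=complex)
        c[k + kk] = amplitude
        return cls(c)


def _require_zero_mean(poly: FourierPoly) -> None:
    # structural exclusion of the mean term: exactly zero, no tolerance
    if not poly.zero_mean:
        raise DomainError(
            "the mean term c_0 must be exactly zero: the k = 0 coefficient "
            "is excluded from the fractional operator's domain"
        )


def weyl_apply(
    poly: FourierPoly, alpha: float, mode: str = "derivative"
) -> FourierPoly:
    """Weyl operator: multiply c_k by (jk)^alpha (derivative) or (jk)^{-alpha}.

    Principal-branch power; alpha = 0 is the unit operator.  Requires a
    zero-mean polynomial.
    """
    _require_zero_mean(poly)
    if mode not in ("derivative", "integral"):
        raise InvalidParameterError(f"mode must be derivative|integral, got {mode!r}")
    s = float(alpha) if mode == "derivative" else -float(alpha)
    k = poly.k.astype(complex)
    mult = np.ones_like(k)
    nz = poly.k != 0
    mult[nz] = (1j * k[nz]) ** s
    return FourierPoly(poly.coeffs * mult)


def weyl_compose_check(poly: FourierPoly, alpha: float, beta: float) -> float:
    """Max coefficient discrepancy of W^alpha W^beta vs W^(alpha+beta)."""
    two_step = weyl_apply(weyl_apply(poly, beta), alpha)
    one_step = weyl_apply(poly, alpha + beta)
    return float(np.max(np.abs(two_step.coeffs - one_step.coeffs)))


def gen_weyl_apply(
    poly: FourierPoly, alpha: float, beta: float, tau: float
) -> FourierPoly:
    """Generalized operator: multiply c_k by exp(alpha M + beta (j pi/2)/M),
    M = Ln(j k tau) principal branch.

    For beta = 0, tau = 1 this coincides with :func:`weyl_apply`; the
    operator is linear in the polynomial for all parameters.
    """
    _require_zero_mean(poly)
    if not (np.isfinite(tau) and tau > 0.0):
        raise DomainError(f"tau must be > 0 (log of zero otherwise), got {tau}")
    k = poly.k
    mult = np.ones(k.size, dtype=complex)
    nz = k != 0
    sgn = np.sign(k[nz])
    m = np.log(np.abs(k[nz]) * tau) + 0.5j * np.pi * sgn
    # conjugate-symmetric symbol so real inputs map to real outputs
    mult[nz] = np.exp(alpha * m + beta * (0.5j * np.pi * sgn) / m)
    return FourierPoly(poly.coeffs * mult)


# ---------------------------------------------------------------------------
# circuit-consistency checks
# ---------------------------------------------------------------------------


def _phasor_ratio(symbol: complex, r_inf: float, dr: float) -> complex:
    # relation (u - r_inf i) + G[u - r_inf i] = dR i, coefficient-wise:
    # u_k = r_inf + dR / (1 + g_k) for the driving harmonic k
    return r_inf + dr / (1.0 + symbol)


def circuit_impedance_cole(
    r0: float, r_inf: float, alpha: float, tau: float, k: int
) -> complex:
    """Impedance at integer angular frequency k from the fractional
    constitutive relation ``u_r + tau^alpha D^alpha u_r = dR i``.

    Routes through :func:`weyl_apply` on the driving harmonic, independent of
    the closed-form evaluation in :mod:`fracz.models`.
    """
    drive = FourierPoly.harmonic(k)
    deriv = weyl_apply(drive, alpha)
    g = tau**alpha * deriv.c(k) / drive.c(k)
    return _phasor_ratio(g, r_inf, r0 - r_inf)


def circuit_impedance_gc1(
    params: ElementParams, r0: float, r_inf: float, k: int
) -> complex:
    """Impedance at integer angular frequency k from the generalized
    constitutive relation ``u_r + p^beta G[u_r] = dR i``.

    Routes through :func:`gen_weyl_apply`; must agree with eval_gc1 at
    f = k / (2 pi).
    """
    drive = FourierPoly.harmonic(k)
    out = gen_weyl_apply(drive, params.alpha, params.beta, params.tau)
    g = params.p**params.beta * out.c(k) / drive.c(k)
    return _phasor_ratio(g, r_inf, r0 - r_inf)
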