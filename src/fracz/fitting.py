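"""Complex nonlinear least-squares fitting of impedance models.

Real-valued Levenberg-Marquardt is applied to the stacked residual vector
[Re(dZ); Im(dZ)].  Positivity of resistances and time constants is enforced
by optimizing on log scale, and alpha through a logistic transform onto
(0, 1); the remnant-memory coefficients are unconstrained.

The scaling constant p is carried as a fixed model constant and is NOT a
free fitting parameter: because p enters the scaling exponent additively
(through beta * ln p), the triple (alpha, tau, p) is exactly ridge-
degenerate and joint estimation is ill-posed.  Recovery experiments hold p
at its configured value; ``solve_p`` remains available as a consistency
diagnostic.

The staged protocol fits a classic counterpart first (Cole for the
single-element generalized models, C2 for the two-element ones), then seeds
the generalized fit with those estimates, initializing every remnant-memory
coefficient at 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import special
from scipy.optimize import least_squares

from .errors import DataError, InvalidSpecError
from .models import (
    CANONICAL_KINDS,
    Element,
    ElementParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    MaclaurinCoeffs,
    ModelSpec,
    eval_serial,
)

__all__ = [
    "FitResult",
    "ComparisonRow",
    "ComparisonResult",
    "stack_residuals",
    "fit",
    "default_initial_spec",
    "perturbed_spec",
    "staged_fit",
    "compare_models",
    "n_free_parameters",
    "MSE_TABLE_SCALE",
]

#: table convention: mse in MOhm^2 reported x 1e7 (1 ohm^2 = 1e-12 MOhm^2)
MSE_TABLE_SCALE = 1e-12 * 1e7

_DEFAULT_TOL = 1e-12
_MAX_NFEV = 5000
_BETA_FAMILY_INIT = 0.01

#: generalized label -> classic stage-1 counterpart
_STAGE1_COUNTERPART = {
    "GC1": "C1",
    "GGC1": "C1",
    "GC2": "C2",
    "C1GC1": "C2",
    "GC1C1": "C2",
}


@dataclass(frozen=True)
class FitResult:
    """Outcome of one Levenberg-Marquardt fit."""

    estimates: ModelSpec
    mse: float  # mean |Z_model - Z_data|^2 over distinct frequencies, ohm^2
    mse_scaled: float  # mse in MOhm^2 x 1e7 (printed-table convention)
    n_iter: int
    converged: bool
    residuals: np.ndarray  # complex per-frequency residuals Z_model - Z_data
    message: str = ""
    cov: Optional[np.ndarray] = None  # covariance proxy in transformed coords
    stage1: Optional["FitResult"] = None  # provenance for staged fits

    def __post_init__(self):
        if self.converged and not (np.isfinite(self.mse) and self.mse >= 0.0):
            raise InvalidSpecError("converged fit must carry a finite mse >= 0")


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    mse: float
    mse_scaled: float
    converged: bool
    n_free: int
    result: FitResult


@dataclass(frozen=True)
class ComparisonResult:
    rows: tuple[ComparisonRow, ...]  # ascending mse, non-converged last
    baseline_label: str
    improvement_pct: float  # best vs classic baseline, percent


# ---------------------------------------------------------------------------
# parameter packing (transforms)
# ---------------------------------------------------------------------------


def _logit(x: float) -> float:
    return float(np.log(x) - np.log1p(-x))


def _expit(t: float) -> float:
    return float(special.expit(t))


def _free_names(element: Element) -> list[str]:
    if element.kind == "cole":
        return ["dr", "alpha", "tau"]
    if element.kind == "gencole":
        return ["dr", "alpha", "tau", "beta"]
    return ["dr", "alpha", "tau", "beta", "gamma", "delta", "epsilon", "zeta"]


def n_free_parameters(spec: ModelSpec) -> int:
    return 1 + sum(len(_free_names(e)) for e in spec.elements)


def _pack(spec: ModelSpec) -> np.ndarray:
    theta = [np.log(spec.r_inf)]
    for el in spec.elements:
        prm = el.params
        for name in _free_names(el):
            if name in ("dr", "tau"):
                theta.append(np.log(getattr(prm, name)))
            elif name == "alpha":
                # clip away from the closed end so the logit is finite
                theta.append(_logit(min(prm.alpha, 1.0 - 1e-12)))
            elif name == "beta":
                theta.append(prm.beta)
            else:
                theta.append(getattr(prm.maclaurin, name))
    return np.asarray(theta, dtype=float)


def _unpack(theta: np.ndarray, template: ModelSpec) -> ModelSpec:
    pos = 0
    r_inf = float(np.exp(min(theta[pos], 700.0)))
    pos += 1
    elements = []
    for el in template.elements:
        prm = el.params
        values = {}
        mac = {} if el.kind == "ggc" else None
        for name in _free_names(el):
            v = float(theta[pos])
            pos += 1
            if name in ("dr", "tau"):
                # clip so exploratory LM steps cannot overflow exp
                values[name] = np.exp(min(v, 700.0))
            elif name == "alpha":
                values[name] = _expit(v)
            elif name == "beta":
                values[name] = v
            else:
                mac[name] = v
        params = replace(
            prm,
            **values,
            maclaurin=MaclaurinCoeffs(**mac) if mac is not None else None,
        )
        elements.append(Element(el.kind, params))
    return ModelSpec(template.name, r_inf, tuple(elements))


# ---------------------------------------------------------------------------
# residuals and fitting
# ---------------------------------------------------------------------------


def stack_residuals(
    spec: ModelSpec, spectrum: ImpedanceSpectrum, weighting: str = "none"
) -> np.ndarray:
    """Stacked real residual vector [Re(Z_model - Z_data); Im(...)], length 2N.

    The sum of squares equals sum |Z_model - Z_data|^2.  ``weighting`` may be
    "none" (default, plain L2) or "modulus" (each residual divided by |Z_data|).
    """
    if not np.all(np.isfinite(spectrum.z)):
        raise DataError("spectrum contains non-finite impedances")
    dz = _model_on(spec, spectrum) - spectrum.z
    if weighting == "modulus":
        dz = dz / np.abs(spectrum.z)
    elif weighting != "none":
        raise InvalidSpecError(f"unknown weighting {weighting!r}")
    return np.concatenate([dz.real, dz.imag])


def _model_on(spec: ModelSpec, spectrum: ImpedanceSpectrum) -> np.ndarray:
    """Model impedance at every spectrum row (rows may repeat across replicates)."""
    fu = spectrum.frequencies
    zu = eval_serial(spec, FrequencyGrid(fu))
    return zu[np.searchsorted(fu, spectrum.f)]


def _result_from_spec(
    spec: ModelSpec,
    spectrum: ImpedanceSpectrum,
    *,
    n_iter: int,
    converged: bool,
    message: str,
    cov: Optional[np.ndarray] = None,
    stage1: Optional[FitResult] = None,
) -> FitResult:
    res = _model_on(spec, spectrum) - spectrum.z
    mse = float(np.mean(np.abs(res) ** 2))
    return FitResult(
        estimates=spec,
        mse=mse,
        mse_scaled=mse * MSE_TABLE_SCALE,
        n_iter=n_iter,
        converged=converged,
        residuals=res,
        message=message,
        cov=cov,
        stage1=stage1,
    )


def fit(
    spec0: ModelSpec,
    spectrum: ImpedanceSpectrum,
    *,
    use_mean: bool = True,
    weighting: str = "none",
    tol: float = _DEFAULT_TOL,
    max_nfev: int = _MAX_NFEV,
) -> FitResult:
    """Levenberg-Marquardt minimizer of the stacked residual sum of squares.

    Deterministic given (spec0, spectrum, tolerances).  Replicates are
    averaged per frequency by default (``use_mean=False`` fits all
    replicates jointly).  Divergence or a non-finite cost yields a result
    with ``converged=False`` rather than an exception.
    """
    n_par = n_free_parameters(spec0)
    if n_par > 10:
        warnings.warn(
            f"{n_par} free parameters; fits with more than ten parameters "
            "are poorly conditioned for this model family",
            stacklevel=2,
        )
    data = spectrum.mean() if use_mean else spectrum
    theta0 = _pack(spec0)

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            r = stack_residuals(_unpack(theta, spec0), data, weighting)
        except (ValueError, FloatingPointError):
            return np.full(2 * len(data), 1e12)
        return np.where(np.isfinite(r), r, 1e12)

    if not np.all(np.isfinite(residual(theta0))):
        return _result_from_spec(
            spec0, data, n_iter=0, converged=False,
            message="non-finite cost at the initial point",
        )
    try:
        sol = least_squares(
            residual,
            theta0,
            method="lm",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_nfev,
        )
    except Exception as exc:  # solver failure is a diagnosis, not a crash
        return _result_from_spec(
            spec0, data, n_iter=0, converged=False, message=f"solver error: {exc}"
        )
    est = _unpack(sol.x, spec0)
    cov = None
    if sol.jac is not None and np.all(np.isfinite(sol.jac)):
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.pinv(jtj) * 2.0 * sol.cost / max(len(data) * 2 - n_par, 1)
        except np.linalg.LinAlgError:
            cov = None
    converged = bool(sol.success and np.isfinite(sol.cost))
    return _result_from_spec(
        est, data, n_iter=int(sol.nfev), converged=converged,
        message=str(sol.message), cov=cov,
    )


def perturbed_spec(spec: ModelSpec, factor: float = 1.2) -> ModelSpec:
    """Deterministic multiplicative perturbation of every free initial value.

    Used by recovery experiments: each free parameter is multiplied by
    ``factor`` (alpha is clipped to stay inside (0, 1); zero-valued
    remnant-memory coefficients stay zero under scaling).  The fixed
    scaling constant p is left untouched.
    """
    elements = []
    for el in spec.elements:
        prm = el.params
        mac = prm.maclaurin
        if mac is not None:
            mac = MaclaurinCoeffs(*(factor * v for v in mac.as_tuple()))
        params = replace(
            prm,
            dr=prm.dr * factor,
            alpha=min(prm.alpha * factor, 0.99),
            tau=prm.tau * factor,
            beta=prm.beta * factor,
            maclaurin=mac,
        )
        elements.append(Element(el.kind, params))
    return ModelSpec(spec.name, spec.r_inf * factor, tuple(elements))


# ---------------------------------------------------------------------------
# staged protocol
# ---------------------------------------------------------------------------


def default_initial_spec(label: str, spectrum: ImpedanceSpectrum) -> ModelSpec:
    """Deterministic data-driven initial guess for a classic model.

    r_inf from the smallest real part, r0 from the largest; relaxation times
    spread geometrically around the reciprocal of the frequency of the
    -Im(Z) peak; alpha starts at 0.75.
    """
    data = spectrum.mean()
    re = data.z.real
    r_inf0 = max(float(np.min(re)), 1e-3)
    r00 = max(float(np.max(re)), 2.0 * r_inf0)
    dr_total = max(r00 - r_inf0, 1e-3)
    f_peak = float(data.f[int(np.argmax(-data.z.imag))])
    tau_c = 1.0 / (2.0 * np.pi * f_peak)
    kinds = CANONICAL_KINDS.get(label)
    if kinds is None:
        raise InvalidSpecError(f"unknown model label {label!r}")
    n = len(kinds)
    # geometric spread of time constants: 1 decade apart for multi-element
    offsets = np.power(10.0, np.arange(n) - (n - 1) / 2.0)
    elements = []
    for kind, off in zip(kinds, offsets):
        params = ElementParams(
            dr=dr_total / n,
            alpha=0.75,
            tau=tau_c * off,
            p=1.0,
            beta=_BETA_FAMILY_INIT if kind in ("gencole", "ggc") else 0.0,
            maclaurin=(
                MaclaurinCoeffs(*(4 * (_BETA_FAMILY_INIT,))) if kind == "ggc" else None
            ),
        )
        elements.append(Element(kind, params))
    return ModelSpec(label, r_inf0, tuple(elements))


def _seed_from_classic(
    label: str,
    classic: ModelSpec,
    p_values: Optional[Sequence[float]] = None,
    beta_init: float = _BETA_FAMILY_INIT,
) -> ModelSpec:
    """Seed a generalized model from the fitted classic counterpart; every
    remnant-memory coefficient starts at ``beta_init`` (0.01 by default).

    ``p_values`` supplies the fixed per-element scaling constants; p cannot
    be estimated (ridge degeneracy with alpha and tau), so recovery
    experiments pass the generator's values and blind fits keep p = 1.
    """
    kinds = CANONICAL_KINDS[label]
    src = classic.elements
    if len(src) != len(kinds):
        raise InvalidSpecError(
            f"classic counterpart has {len(src)} elements, {label} needs {len(kinds)}"
        )
    if p_values is None:
        p_values = [1.0] * len(kinds)
    if len(p_values) != len(kinds):
        raise InvalidSpecError(
            f"p_values must supply one value per element ({len(kinds)})"
        )
    elements = []
    for kind, el, p in zip(kinds, src, p_values):
        prm = el.params
        params = ElementParams(
            dr=prm.dr,
            alpha=prm.alpha,
            tau=prm.tau,
            p=float(p),
            beta=beta_init if kind in ("gencole", "ggc") else 0.0,
            maclaurin=(
                MaclaurinCoeffs(*(4 * (beta_init,))) if kind == "ggc" else None
            ),
        )
        elements.append(Element(kind, params))
    return ModelSpec(label, classic.r_inf, tuple(elements))


def staged_fit(
    label: str,
    spectrum: ImpedanceSpectrum,
    *,
    p_values: Optional[Sequence[float]] = None,
    use_mean: bool = True,
    tol: float = _DEFAULT_TOL,
    max_nfev: int = _MAX_NFEV,
) -> FitResult:
    """Two-stage fit: classic counterpart first, then the generalized model
    seeded with the stage-1 estimates and remnant-memory initials of 0.01.

    Classic labels are fitted in a single stage from the data-driven
    default initialization.  Stage-1 non-convergence aborts stage 2 and is
    reported on the returned diagnostic result.  Because the classic model
    is nested in its generalized counterpart, a stage-2 outcome worse than
    stage 1 triggers one fallback fit seeded at the exact stage-1 solution
    (remnant-memory coefficients zero); Levenberg-Marquardt only accepts
    cost-reducing steps, so the returned mse never exceeds stage 1's.
    """
    if label not in CANONICAL_KINDS:
        raise InvalidSpecError(
            f"unknown model label {label!r}; valid: {sorted(CANONICAL_KINDS)}"
        )
    counterpart = _STAGE1_COUNTERPART.get(label)
    if counterpart is None:  # classic model: single stage
        spec0 = default_initial_spec(label, spectrum)
        return fit(spec0, spectrum, use_mean=use_mean, tol=tol, max_nfev=max_nfev)
    stage1_spec0 = default_initial_spec(counterpart, spectrum)
    stage1 = fit(stage1_spec0, spectrum, use_mean=use_mean, tol=tol, max_nfev=max_nfev)
    if not stage1.converged:
        return replace(
            stage1,
            converged=False,
            message=f"stage-1 {counterpart} fit did not converge: {stage1.message}",
        )
    data = spectrum.mean() if use_mean else spectrum
    swap = len(set(CANONICAL_KINDS[label])) > 1  # mixed kinds: order matters
    candidates = []
    for ordering in ((False, True) if swap else (False,)):
        classic = stage1.estimates
        pv = p_values
        if ordering:
            classic = ModelSpec(
                classic.name, classic.r_inf, tuple(reversed(classic.elements))
            )
        spec0 = _seed_from_classic(label, classic, pv)
        candidates.append(
            fit(spec0, spectrum, use_mean=use_mean, tol=tol, max_nfev=max_nfev)
        )
    # nested-model safety net: the stage-1 solution embedded with all
    # remnant-memory coefficients at zero reproduces stage 1's mse exactly
    embed = _seed_from_classic(label, stage1.estimates, p_values, beta_init=0.0)
    candidates.append(
        fit(embed, spectrum, use_mean=use_mean, tol=tol, max_nfev=max_nfev)
    )
    candidates.append(
        _result_from_spec(
            embed,
            data,
            n_iter=stage1.n_iter,
            converged=stage1.converged,
            message="embedded stage-1 solution (remnant-memory coefficients zero)",
        )
    )
    converged = [c for c in candidates if c.converged]
    stage2 = (
        min(converged, key=lambda c: c.mse)
        if converged
        else min(candidates, key=lambda c: c.mse)
    )
    return replace(stage2, stage1=stage1)


def compare_models(
    spectrum: ImpedanceSpectrum, labels: Sequence[str], *, use_mean: bool = True
) -> ComparisonResult:
    """Staged-fit every label and rank by ascending mse.

    Ties break toward fewer free parameters; non-converged fits rank last
    and are flagged.  The summary reports the relative improvement (percent)
    of the best model over the classic (Cole-family) baseline; if no classic
    label was requested, a C1 baseline is fitted for reference.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise InvalidSpecError("compare_models needs at least two labels")
    rows = []
    for label in labels:
        res = staged_fit(label, spectrum, use_mean=use_mean)
        rows.append(
            ComparisonRow(
                label=label,
                mse=res.mse,
                mse_scaled=res.mse_scaled,
                converged=res.converged,
                n_free=n_free_parameters(res.estimates),
                result=res,
            )
        )
    rows.sort(key=lambda r: (not r.converged, r.mse, r.n_free, r.label))

    classic = [r for r in rows if r.label in ("C1", "C2", "C3") and r.converged]
    if classic:
        baseline = min(classic, key=lambda r: r.mse)
        baseline_label, baseline_mse = baseline.label, baseline.mse
    else:
        base = staged_fit("C1", spectrum, use_mean=use_mean)
        baseline_label, baseline_mse = "C1", base.mse
    best = rows[0]
    improvement = (
        100.0 * (baseline_mse - best.mse) / baseline_mse if baseline_mse > 0 else 0.0
    )
    return ComparisonResult(
        rows=tuple(rows),
        baseline_label=baseline_label,
        improvement_pct=improvement,
    )
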