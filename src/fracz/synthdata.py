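"""Synthetic bioimpedance spectra with the measurement structure of a
multi-frequency sweep: 61 log-spaced frequencies from 0.1 Hz to 100 kHz,
20 replicate sweeps, relative instrument noise below 0.1%.

Also provides fixture parameter sets (published fitted-parameter columns,
converted from MOhm/kOhm to ohm) so every other module can be exercised
without measured data.  The tables publish only the total R0 and r_inf of
the two-element circuits, not the per-element split, so fixtures divide
R0 - r_inf equally between elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .models import (
    Element,
    ElementParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    MaclaurinCoeffs,
    ModelSpec,
    eval_serial,
)

__all__ = [
    "AcquisitionSpec",
    "default_grid",
    "simulate_spectrum",
    "table_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition protocol: frequency band, replication, noise, seed."""

    f_min: float = 0.1
    f_max: float = 1e5
    n_freq: int = 61
    n_replicates: int = 20
    noise_rel: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_freq < 2:
            raise InvalidSpecError(f"n_freq must be >= 2, got {self.n_freq}")
        if not (0.0 < self.f_min < self.f_max):
            raise InvalidSpecError(
                f"need 0 < f_min < f_max, got {self.f_min}, {self.f_max}"
            )
        if self.n_replicates < 1:
            raise InvalidSpecError("n_replicates must be >= 1")
        if self.noise_rel < 0.0:
            raise InvalidSpecError("noise_rel must be >= 0")


def default_grid(spec: AcquisitionSpec = AcquisitionSpec()) -> FrequencyGrid:
    """n_freq logarithmically spaced frequencies from f_min to f_max inclusive."""
    f = np.geomspace(spec.f_min, spec.f_max, spec.n_freq)
    f[0], f[-1] = spec.f_min, spec.f_max  # exact endpoints
    return FrequencyGrid(f)


def simulate_spectrum(
    spec_model: ModelSpec, acq: AcquisitionSpec = AcquisitionSpec()
) -> ImpedanceSpectrum:
    """Evaluate the model on the acquisition grid and perturb each replicate.

    Noise is independent multiplicative complex Gaussian per frequency and
    replicate: Z -> Z * (1 + s*(e_re + j*e_im)), e ~ N(0,1), s = noise_rel,
    giving a relative scatter of |Z| close to noise_rel.  noise_rel = 0
    returns the exact model curve in every replicate.  Reproducible from
    acq.seed.
    """
    grid = default_grid(acq)
    z_true = eval_serial(spec_model, grid)
    rng = np.random.default_rng(acq.seed)
    n = len(grid)
    f_all = np.tile(grid.f, acq.n_replicates)
    rep_all = np.repeat(np.arange(acq.n_replicates), n)
    if acq.noise_rel > 0.0:
        eps = rng.standard_normal((acq.n_replicates, n)) + 1j * rng.standard_normal(
            (acq.n_replicates, n)
        )
        z_all = (z_true[None, :] * (1.0 + acq.noise_rel * eps)).ravel()
    else:
        z_all = np.tile(z_true, acq.n_replicates)
    return ImpedanceSpectrum(f=f_all, z=z_all, replicate=rep_all)


def _two_cole(name, r0_mohm, rinf_kohm, e1, e2):
    r_inf = rinf_kohm * 1e3
    dr = (r0_mohm * 1e6 - r_inf) / 2.0
    return ModelSpec(
        name,
        r_inf,
        tuple(
            Element(kind, ElementParams(dr=dr, **kw)) for kind, kw in (e1, e2)
        ),
    )


def _ggc1(r0_mohm, rinf_kohm, alpha, tau, beta, gamma, delta, epsilon, zeta):
    r_inf = rinf_kohm * 1e3
    return ModelSpec(
        "GGC1",
        r_inf,
        (
            Element(
                "ggc",
                ElementParams(
                    dr=r0_mohm * 1e6 - r_inf,
                    alpha=alpha,
                    tau=tau,
                    p=1.0,
                    beta=beta,
                    maclaurin=MaclaurinCoeffs(gamma, delta, epsilon, zeta),
                ),
            ),
        ),
    )


def _build_fixtures() -> dict[str, ModelSpec]:
    return {
        # two classic elements, small electrode
        "C2-d025": _two_cole(
            "C2", 1.120, 1.911,
            ("cole", dict(alpha=0.743, tau=0.266, p=0.267)),
            ("cole", dict(alpha=0.851, tau=1.414, p=0.733)),
        ),
        # two generalized elements, small electrode
        "GC2-d025": _two_cole(
            "GC2", 1.119, 0.680,
            ("gencole", dict(alpha=0.819, tau=0.240, p=0.422, beta=-0.015)),
            ("gencole", dict(alpha=0.805, tau=2.883, p=0.655, beta=0.074)),
        ),
        # two classic elements, large electrode
        "C2-d20": _two_cole(
            "C2", 1.353, 1.718,
            ("cole", dict(alpha=0.784, tau=0.110, p=0.200)),
            ("cole", dict(alpha=0.831, tau=0.687, p=0.800)),
        ),
        # classic + generalized, large electrode
        "C1GC1-d20": _two_cole(
            "C1GC1", 1.354, 2.963,
            ("cole", dict(alpha=0.961, tau=2.704, p=0.356)),
            ("gencole", dict(alpha=0.532, tau=1.900, p=1.596, beta=0.024)),
        ),
        # Maclaurin-extended single element, both electrode sizes
        "GGC1-d025": _ggc1(
            0.642, 1.060, 0.940, 0.281,
            -0.043233, -0.131216, -0.054793, -0.009557, -0.000652,
        ),
        "GGC1-d20": _ggc1(
            1.461, 2.530, 0.707, 0.604,
            0.010132, -0.004308, -0.007025, -0.002536, -0.000206,
        ),
    }


_FIXTURES = _build_fixtures()
FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def table_fixture(name: str) -> ModelSpec:
    """Fixture ModelSpec by label (resistances in ohm, times in s)."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise InvalidSpecError(
            f"unknown fixture {name!r}; valid names: {list(FIXTURE_NAMES)}"
        ) from None
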