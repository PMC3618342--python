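# fracz

Fractional-order equivalent-circuit impedance modelling for bioimpedance
spectroscopy: constant phase elements (CPE), the Cole dispersion, a
generalized Cole element with a remnant-memory coefficient, serial
combinations of reduced elements, and a Maclaurin-extended single-element
model — together with complex nonlinear least-squares fitting and a
synthetic replicated-spectrum generator.

## What is implemented

**Models** (`fracz.models`) — closed-form complex impedance for

| label  | circuit                                                    |
| ------ | ---------------------------------------------------------- |
| C1/C2/C3 | r∞ in series with 1/2/3 reduced Cole elements dR/(1+(jωτ)^α) |
| GC1/GC2  | same with generalized elements carrying a memory coefficient β |
| C1GC1/GC1C1 | mixed classic/generalized permutations                  |
| GGC1   | one element with the five-coefficient partial Maclaurin sum (β, γ, δ, ε, ζ) |

The generalized scaling factor is
`F = exp(α·L + β·(v + ln p) + γ·v² + δ·v³ + ε·v⁴ + ζ·v⁵)` with
`L = Ln(jωτ)` (principal branch) and the bounded variable `v = (jπ/2)/L`;
`β = 0` with vanishing higher coefficients reduces `F` exactly to the Cole
factor `(jωτ)^α` for every admissible `p`.  The non-negative constant `p`
satisfies a self-consistent relation solved by `solve_p` (a diagnostic —
see the identifiability note below).

**Weyl operators** (`fracz.weyl`) — fractional derivatives/integrals of
trigonometric polynomials by coefficient-wise multiplication with `(jk)^±α`
(mean term structurally excluded), a generalized operator mirroring the
circuit scaling, and circuit-consistency checks that reproduce the
closed-form impedances from the fractional constitutive relation.

**Fitting** (`fracz.fitting`) — Levenberg–Marquardt on the stacked
residual `[Re ΔZ; Im ΔZ]` with log/logistic transforms enforcing
positivity and `α ∈ (0, 1)`; a staged protocol (classic counterpart first,
then the generalized model with every memory coefficient initialized at
0.01, plus a nested-model fallback); model comparison ranked by mean
square error, reported both in Ω² and in the MΩ²·10⁷ table convention.

*Identifiability note:* `p` enters the scaling exponent only through
`β·ln p`, which makes the triple (α, τ, p) exactly ridge-degenerate; `p` is
therefore carried as a fixed model constant, never estimated.

**Synthetic data** (`fracz.synthdata`) — the default acquisition grid (61
log-spaced frequencies, 0.1 Hz–100 kHz), 20 replicate sweeps with 0.1%
multiplicative complex Gaussian noise, seeded and reproducible, plus the
published fitted-parameter columns as ready-made fixtures
(`C2-d025`, `GC2-d025`, `C2-d20`, `C1GC1-d20`, `GGC1-d025`, `GGC1-d20`).

**I/O + CLI** (`fracz.io`, `fracz.cli`) — a single CSV dialect
(`frequency_hz,z_real_ohm,z_imag_ohm[,replicate]`), YAML model configs,
JSON/text fit reports with Cole-plot (Re Z, −Im Z) columns.

## CLI

```sh
fracz simulate --fixture GGC1-d20 --seed 7 --out synth.csv
fracz fit --model GC2 --data synth.csv --out fit.json
fracz compare --models C2,GC2,C1GC1,GGC1 --data synth.csv
fracz recover --fixture C2-d025 --perturb 1.2
fracz weyl-check --seed 0
```

Every command logs a JSON line (config hash, seed, versions) to stderr;
runs with fixed seed and inputs are bit-reproducible.

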