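"""Readers and writers: impedance CSV, model config (YAML), fit reports.

CSV dialect (single, explicit, no sniffing)::

    frequency_hz,z_real_ohm,z_imag_ohm[,replicate]

UTF-8, '.' decimal separator, one row per (frequency, replicate).  Reports
are emitted as structured JSON (the contract surface for tests) with
parameters in table units (MOhm, kOhm, s) and plot-ready Cole-plot columns
(Re Z, -Im Z); a human-readable text rendering is available as well.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ParseError
from .fitting import FitResult, n_free_parameters
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
    "read_spectrum",
    "write_spectrum",
    "read_model_config",
    "write_model_config",
    "fit_report_dict",
    "write_fit_report",
    "render_fit_report_text",
]

_HEADER = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read the impedance CSV dialect; parse errors carry the line number."""
    path = Path(path)
    f_col, re_col, im_col, rep_col = [], [], [], []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        header = [h.strip() for h in header]
        if header[:3] != _HEADER or len(header) > 4 or (
            len(header) == 4 and header[3] != "replicate"
        ):
            raise ParseError(
                f"malformed header {header!r}; expected "
                f"{_HEADER + ['[replicate]']}",
                line=1,
            )
        has_rep = len(header) == 4
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}", line=lineno
                )
            try:
                fval = float(row[0])
                re_v = float(row[1])
                im_v = float(row[2])
                rep = int(row[3]) if has_rep else 0
            except ValueError:
                raise ParseError(f"non-numeric cell in row {row!r}", line=lineno) from None
            if not np.isfinite(fval) or fval <= 0.0:
                raise ParseError(
                    f"frequency must be finite and > 0, got {row[0]}", line=lineno
                )
            f_col.append(fval)
            re_col.append(re_v)
            im_col.append(im_v)
            rep_col.append(rep)
    if not f_col:
        raise ParseError("no data rows", line=2)
    try:
        return ImpedanceSpectrum(
            f=np.array(f_col),
            z=np.array(re_col) + 1j * np.array(im_col),
            replicate=np.array(rep_col),
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write the CSV dialect at full float precision (repr round-trip)."""
    path = Path(path)
    multi = spectrum.n_replicates > 1
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER + (["replicate"] if multi else []))
        for i in range(len(spectrum)):
            row = [
                repr(float(spectrum.f[i])),
                repr(float(spectrum.z[i].real)),
                repr(float(spectrum.z[i].imag)),
            ]
            if multi:
                row.append(int(spectrum.replicate[i]))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# model config (YAML)
# ---------------------------------------------------------------------------


def _element_to_dict(el: Element) -> dict:
    prm = el.params
    d = {
        "dr_ohm": float(prm.dr),
        "alpha": float(prm.alpha),
        "tau_s": float(prm.tau),
        "p": float(prm.p),
        "beta": float(prm.beta),
    }
    if prm.maclaurin is not None:
        d.update(
            gamma=float(prm.maclaurin.gamma),
            delta=float(prm.maclaurin.delta),
            epsilon=float(prm.maclaurin.epsilon),
            zeta=float(prm.maclaurin.zeta),
        )
    return d


def write_model_config(spec: ModelSpec, path) -> None:
    doc = {
        "model": spec.name,
        "r_inf_ohm": float(spec.r_inf),
        "elements": [_element_to_dict(el) for el in spec.elements],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_model_config(path) -> ModelSpec:
    from .models import CANONICAL_KINDS  # local to avoid unused at import time

    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "model" not in doc:
        raise ParseError("config must be a mapping with a 'model' field")
    label = doc["model"]
    kinds = CANONICAL_KINDS.get(label)
    if kinds is None:
        raise ParseError(f"unknown model label {label!r}")
    raw_elements = doc.get("elements", [])
    if len(raw_elements) != len(kinds):
        raise ParseError(
            f"model {label} needs {len(kinds)} element blocks, got {len(raw_elements)}"
        )
    elements = []
    for kind, raw in zip(kinds, raw_elements):
        mac = None
        if kind == "ggc":
            mac = MaclaurinCoeffs(
                gamma=float(raw.get("gamma", 0.0)),
                delta=float(raw.get("delta", 0.0)),
                epsilon=float(raw.get("epsilon", 0.0)),
                zeta=float(raw.get("zeta", 0.0)),
            )
        params = ElementParams(
            dr=float(raw["dr_ohm"]),
            alpha=float(raw["alpha"]),
            tau=float(raw["tau_s"]),
            p=float(raw.get("p", 1.0)),
            beta=float(raw.get("beta", 0.0)),
            maclaurin=mac,
        )
        elements.append(Element(kind, params))
    return ModelSpec(label, float(doc.get("r_inf_ohm", 0.0)), tuple(elements))


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------


def _element_report(el: Element) -> dict:
    prm = el.params
    d = {
        "kind": el.kind,
        "dr_mohm": prm.dr / 1e6,
        "alpha": prm.alpha,
        "tau_s": prm.tau,
        "p": prm.p,
        "beta": prm.beta,
    }
    if prm.maclaurin is not None:
        d.update(
            gamma=prm.maclaurin.gamma,
            delta=prm.maclaurin.delta,
            epsilon=prm.maclaurin.epsilon,
            zeta=prm.maclaurin.zeta,
        )
    return d


def fit_report_dict(result: FitResult, spectrum: Optional[ImpedanceSpectrum] = None) -> dict:
    """Structured report: table-unit parameters, errors, Cole-plot columns."""
    spec = result.estimates
    report = {
        "model": spec.name,
        "converged": bool(result.converged),
        "message": result.message,
        "n_iter": int(result.n_iter),
        "n_free_parameters": n_free_parameters(spec),
        "mse_ohm2": result.mse,
        "mse_scaled_1e7_mohm2": result.mse_scaled,
        "r_inf_kohm": spec.r_inf / 1e3,
        "r0_mohm": spec.r0_classic / 1e6,
        "elements": [_element_report(el) for el in spec.elements],
    }
    f_plot = (
        np.unique(spectrum.f) if spectrum is not None else None
    )
    if f_plot is not None:
        z = eval_serial(spec, FrequencyGrid(f_plot))
        report["cole_plot"] = {
            "frequency_hz": f_plot.tolist(),
            "re_z_mohm": (z.real / 1e6).tolist(),
            "neg_im_z_mohm": (-z.imag / 1e6).tolist(),
        }
    if result.stage1 is not None:
        report["stage1"] = fit_report_dict(result.stage1)
    return report


def write_fit_report(
    result: FitResult, path, spectrum: Optional[ImpedanceSpectrum] = None
) -> None:
    """Write the report as JSON ('.json') or human-readable text (otherwise)."""
    path = Path(path)
    report = fit_report_dict(result, spectrum)
    if path.suffix == ".json":
        path.write_text(json.dumps(report, indent=2), encoding="utf-8")
    else:
        path.write_text(render_fit_report_text(report), encoding="utf-8")


def render_fit_report_text(report: dict) -> str:
    lines = [f"model: {report['model']}"]
    if not report["converged"]:
        lines.append("*** NOT CONVERGED *** " + report.get("message", ""))
    lines += [
        f"free parameters: {report['n_free_parameters']}",
        f"iterations (nfev): {report['n_iter']}",
        f"mse: {report['mse_ohm2']:.6g} ohm^2"
        f"  (x1e7 MOhm^2: {report['mse_scaled_1e7_mohm2']:.6g})",
        f"R0: {report['r0_mohm']:.6g} MOhm   Rinf: {report['r_inf_kohm']:.6g} kOhm",
    ]
    for i, el in enumerate(report["elements"], start=1):
        parts = [
            f"element {i} ({el['kind']}):",
            f"dR={el['dr_mohm']:.6g} MOhm",
            f"alpha={el['alpha']:.6g}",
            f"tau={el['tau_s']:.6g} s",
            f"p={el['p']:.6g}",
            f"beta={el['beta']:.6g}",
        ]
        for name in ("gamma", "delta", "epsilon", "zeta"):
            if name in el:
                parts.append(f"{name}={el[name]:.6g}")
        lines.append("  ".join(parts))
    return "\n".join(lines) + "\n"
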