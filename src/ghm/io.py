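"""Artifact writers and approximant serialization.

Everything is plain text: coefficient tables as TSV, trajectories and sweep
curves as CSV, error reports and approximants as JSON, expression dumps as
plain text and LaTeX.  Exact values are written as fraction strings next to
their rounded decimal rendering, so the artifacts are both byte-stable and
human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import sympy as sp

from .cascade import GHMResult, RationalApproximant
from .exppoly import ExpPoly
from .validation import ErrorReport, ReferenceSolution, SweepResult

__all__ = [
    "sigfig",
    "write_coefficient_table",
    "write_trajectories",
    "write_sweep_curve",
    "write_error_report",
    "write_expression_dump",
    "approximant_to_json",
    "approximant_from_json",
]


def sigfig(value, digits: int = 8) -> str:
    """Render a number with the given significant digits (decimal string)."""
    return str(sp.Float(sp.N(sp.sympify(value), digits), digits))


def write_coefficient_table(
    approximant: RationalApproximant, path, digits: int = 8
) -> pd.DataFrame:
    """TSV table: power, numerator coefficient, denominator coefficient.

    Only defined for polynomial quotients; exact coefficients are written
    alongside their rounded decimal rendering.
    """
    num, den = approximant.polynomial_coefficients()
    powers = sorted(set(num) | set(den))
    rows = []
    for k in powers:
        cn, cd = num.get(k, sp.S.Zero), den.get(k, sp.S.Zero)
        rows.append(
            {
                "power": k,
                "numerator": str(cn),
                "denominator": str(cd),
                "numerator_decimal": sigfig(cn, digits),
                "denominator_decimal": sigfig(cd, digits),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_trajectories(
    approximants: Mapping[str, RationalApproximant],
    reference: ReferenceSolution,
    path,
    n_points: int = 501,
    interval=None,
) -> pd.DataFrame:
    """CSV: t, per-unknown approximant, reference, and absolute error."""
    lo, hi = interval if interval is not None else reference.interval
    t = np.linspace(float(lo), float(hi), n_points)
    data = {"t": t}
    for name, a in approximants.items():
        fn = sp.lambdify(a.var, a.numerator, "numpy")
        fd = sp.lambdify(a.var, a.denominator, "numpy")
        approx = np.broadcast_to(np.asarray(fn(t), float), t.shape) / np.broadcast_to(
            np.asarray(fd(t), float), t.shape
        )
        ref = reference(name, t)
        data[f"{name}_ghm"] = approx
        data[f"{name}_ref"] = ref
        data[f"{name}_abs_error"] = np.abs(approx - ref)
    df = pd.DataFrame(data)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_sweep_curve(sweep: SweepResult, path) -> pd.DataFrame:
    df = pd.DataFrame({"hbar": sweep.grid, "E_m": sweep.errors})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_error_report(report: ErrorReport, path) -> dict:
    doc = report.to_dict()
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def write_expression_dump(result: GHMResult, txt_path, tex_path=None) -> str:
    """Homotopy, cascade, solved composites and approximants, human-readable."""
    lines = ["# homotopy residuals"]
    from .homotopy import build_homotopy

    homotopy = build_homotopy(result.problem, result.config)
    for name, h in homotopy.items():
        lines.append(f"H[{name}] = {h}")
    lines.append("")
    lines.append("# cascade equations (one per p-power per unknown)")
    for eq in result.cascade:
        lines.append(f"p^{eq.order} [{eq.unknown}]: {eq.expr} = 0")
    lines.append("")
    lines.append("# solved composites")
    for name, comps in result.solution.composites.items():
        for k, g in enumerate(comps):
            lines.append(f"g_{k}[{name}] = {g.to_expr()}")
    lines.append("")
    lines.append("# assembled approximants (p -> 1)")
    for name, a in result.approximants.items():
        lines.append(f"{name} = ({a.numerator}) / ({a.denominator})")
    text = "\n".join(lines) + "\n"
    if txt_path is not None:
        Path(txt_path).write_text(text)
    if tex_path is not None:
        tex = []
        for name, a in result.approximants.items():
            tex.append(f"{name}(t) = {sp.latex(a.expr)}")
        Path(tex_path).write_text("\n\n".join(tex) + "\n")
    return text


# ---------------------------------------------------------------------------
# approximant (de)serialization
# ---------------------------------------------------------------------------


def _part_to_doc(expr: sp.Expr, var: sp.Symbol) -> list[dict]:
    ep = ExpPoly.from_expr(expr, var, tuple(expr.free_symbols - {var}))
    doc = []
    for mu, poly in sorted(ep.terms.items(), key=lambda kv: kv[0]):
        for d, c in sorted(poly.items()):
            doc.append({"exp": str(mu), "power": int(d), "coeff": str(c)})
    return doc


def _part_from_doc(doc, var: sp.Symbol) -> sp.Expr:
    total = sp.S.Zero
    for term in doc:
        mu = sp.Rational(term["exp"])
        c = sp.sympify(term["coeff"])
        total += c * var ** int(term["power"]) * sp.exp(mu * var)
    return sp.expand(total)


def approximant_to_json(approximant: RationalApproximant, path=None) -> dict:
    """Serialize numerator/denominator as exact power/coefficient terms.

    Coefficients are stored as strings (exact rationals survive the round
    trip bit-for-bit); terms carry the polynomial power and the rational
    multiple of the independent variable inside an exponential factor (0 for
    plain polynomials).
    """
    doc = {
        "unknown": approximant.unknown,
        "variable": str(approximant.var),
        "numerator": _part_to_doc(approximant.numerator, approximant.var),
        "denominator": _part_to_doc(approximant.denominator, approximant.var),
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def approximant_from_json(source) -> RationalApproximant:
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    var = sp.Symbol(doc["variable"])
    return RationalApproximant(
        unknown=doc["unknown"],
        numerator=_part_from_doc(doc["numerator"], var),
        denominator=_part_from_doc(doc["denominator"], var),
        var=var,
        metadata={"source": "json"},
    )
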