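"""Run orchestration: problem -> homotopy -> cascade -> assembly -> validation.

Deterministic end to end (there is no randomness anywhere in the pipeline):
two runs with identical configurations produce byte-identical artifacts.
Each stage logs to stderr with a stage prefix; failures propagate with the
stage name and, for cascade failures, the offending order.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import sympy as sp

from .cascade import GHMResult, run_ghm
from .case_studies import HBAR, get_case_study
from .config import RunConfig
from .fixtures import check_fixture
from .io import (
    write_coefficient_table,
    write_error_report,
    write_expression_dump,
    write_sweep_curve,
    write_trajectories,
    approximant_to_json,
)
from .validation import (
    SweepResult,
    hbar_grid,
    mean_square_error,
    reference_bvp,
    reference_ivp,
    tune_hbar,
)

__all__ = ["run", "sweep", "check", "configure_logging"]

logger = logging.getLogger("ghm")


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler()  # stderr
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    root = logging.getLogger("ghm")
    root.handlers[:] = [handler]
    root.setLevel(logging.INFO if verbose else logging.WARNING)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("%s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("%s: done in %.2f s", name, dt)
            else:
                logger.error("%s: failed after %.2f s: %s", name, dt, exc)
            return False

    return _Ctx()


def _reference(config: RunConfig):
    problem = config.problem
    is_bvp = len({c.abscissa for c in problem.conditions}) > 1
    if is_bvp:
        return reference_bvp(problem, abs_tol=max(config.tolerance, 1e-10))
    hi = max(
        float(problem.domain_interval[1]),
        config.K * config.dt,
    )
    interval = config.interval or (0.0, hi)
    return reference_ivp(problem, abs_tol=config.tolerance, interval=interval)


def _solve(config: RunConfig) -> GHMResult:
    with _stage("cascade"):
        result = run_ghm(
            config.problem,
            config.homotopy,
            config.ansatz,
            mode=config.mode,
            precision=config.precision,
        )
    for eq in result.cascade:
        logger.info("cascade: order %d (%s) solved", eq.order, eq.unknown)
    return result


def run(config: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline and write artifacts; returns a summary."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    result = _solve(config)

    approximants = result.approximants
    hbar_used = None
    if config.homotopy.control_parameter.is_Symbol:
        hbar_used = config.hbar
        if hbar_used is None and config.case_name:
            hbar_used = get_case_study(config.case_name).default_hbar
        if hbar_used is None:
            raise ValueError("a symbolic control parameter needs an 'hbar' value")
        approximants = result.substitute({config.homotopy.control_parameter: hbar_used})

    summary = {
        "problem": config.case_name or "inline",
        "order": result.ansatz.truncation_order,
        "mode": config.mode,
        "hbar": None if hbar_used is None else float(hbar_used),
        "unknowns": {},
    }
    with _stage("artifacts"):
        if write:
            write_expression_dump(result, outdir / "expressions.txt", outdir / "expressions.tex")
        for name, a in approximants.items():
            an = a
            try:
                an = a.normalized()
                if write:
                    write_coefficient_table(an, outdir / f"coefficients_{name}.tsv", config.digits)
            except (sp.PolynomialError, ZeroDivisionError):
                pass  # non-polynomial quotients have no coefficient table
            if write:
                approximant_to_json(a, outdir / f"approximant_{name}.json")
            summary["unknowns"][name] = {
                "numerator_terms": len(sp.Add.make_args(sp.expand(a.numerator))),
                "denominator_terms": len(sp.Add.make_args(sp.expand(a.denominator))),
            }

    with _stage("validation"):
        is_bvp = len({c.abscissa for c in config.problem.conditions}) > 1
        K, dt = config.K, config.dt
        if is_bvp:
            lo, hi = (float(v) for v in config.problem.domain_interval)
            dt = (hi - lo) / K
        free = set().union(
            *(a.free_parameters for a in approximants.values())
        )
        if not free:
            reference = _reference(config)
            report = mean_square_error(
                approximants, reference, K=K, dt=dt,
                hbar=None if hbar_used is None else float(hbar_used),
            )
            summary["E_m"] = report.value
            summary["max_abs_error"] = {
                k: float(v.max()) for k, v in report.abs_errors.items()
            }
            if write:
                write_error_report(report, outdir / "error_report.json")
                write_trajectories(approximants, reference, outdir / "trajectories.csv")
        else:
            logger.info("validation: skipped (free symbolic parameters: %s)",
                        sorted(map(str, free)))
    logger.info("run: complete")
    return summary


def sweep(config: RunConfig, write: bool = True) -> SweepResult:
    """Control-parameter sweep; writes the E_m curve and the argmin."""
    if config.sweep_grid is None:
        raise ValueError("sweep needs an 'hbar: {lo, hi, step}' grid")
    if not config.homotopy.control_parameter.is_Symbol:
        raise ValueError("sweep needs a symbolic control parameter (hbar embedding)")
    lo, hi, step = config.sweep_grid
    grid = hbar_grid(lo, hi, step)
    result = _solve(config)
    with _stage("sweep"):
        reference = _reference(config)
        out = tune_hbar(
            config.problem,
            config.homotopy,
            config.ansatz,
            grid,
            K=config.K,
            dt=config.dt,
            abs_tol=config.tolerance,
            reference=reference,
            result=result,
        )
    logger.info("sweep: argmin hbar* = %s (E_m = %.6g)",
                out.hbar_star, float(out.errors.min()))
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sweep_curve(out, outdir / "hbar_sweep.csv")
        (outdir / "hbar_star.txt").write_text(f"{out.hbar_star}\n")
    return out


def check(fixture_name: str, result: GHMResult | None = None) -> list[dict]:
    """Recompute a reproduction fixture and compare row by row."""
    with _stage(f"check:{fixture_name}"):
        rows = check_fixture(fixture_name, result=result)
    n_fail = sum(not r["passed"] for r in rows)
    logger.info("check %s: %d/%d passed", fixture_name, len(rows) - n_fail, len(rows))
    return rows
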