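"""Nonlinear least-squares estimation of solubility-model parameters.

Deviation metrics follow the conventions of the source analysis:

* RD_i  = (x_exp,i − x_cal,i) / x_exp,i   (signed relative deviation)
* ARD   = mean |RD_i|
* RMSD  = sqrt(Σ(x_exp − x_cal)² / n)
* RSS   = Σ(x_exp − x_cal)²

Two objectives are available.  ``objective="lnx"`` minimises squared
residuals of ln x — for the log-linear Apelblat and van't Hoff models this
is an ordinary least-squares problem solved in closed form, and it is the
convention that reproduces the study's printed parameter tables.  The
nonlinear models (λh, NRTL, UNIQUAC, Wilson variants) default to
``objective="x"``, squared residuals in mole-fraction space, minimised by
Levenberg–Marquardt/trust-region least squares from a fixed multistart
grid.  Metrics are always reported in x-space regardless of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data import SolubilityDataset, SoluteProperties, DEHYDROABIETIC_ACID
from . import models as M

__all__ = ["FitResult", "deviation_metrics", "fit_model", "MODEL_NAMES", "FitError"]


class FitError(RuntimeError):
    """Model fitting failed from every start."""


def deviation_metrics(x_exp, x_cal) -> tuple[np.ndarray, float, float, float]:
    """Return (rd, ard, rmsd, rss) between experimental and calculated x."""
    x_exp = np.asarray(x_exp, dtype=float)
    x_cal = np.asarray(x_cal, dtype=float)
    if x_exp.shape != x_cal.shape:
        raise ValueError("x_exp and x_cal must have equal length")
    if x_exp.size == 0:
        raise ValueError("need at least one point")
    if np.any(x_exp == 0):
        raise ValueError("experimental solubility must be non-zero")
    resid = x_exp - x_cal
    rd = resid / x_exp
    ard = float(np.mean(np.abs(rd)))
    rss = float(np.sum(resid**2))
    rmsd = float(np.sqrt(rss / x_exp.size))
    return rd, ard, rmsd, rss


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its calculated curve and deviation metrics."""

    model_name: str
    params: object
    x_cal: np.ndarray
    rd: np.ndarray
    ard: float
    rmsd: float
    rss: float
    n_points: int
    n_params: int
    k_aic: int  # parameter count used in AIC bookkeeping
    converged: bool
    objective: str
    dataset_label: str = ""

    def summary_row(self) -> dict:
        """One row in the style of the study's parameter tables."""
        row = {"system": self.dataset_label, "model": self.model_name}
        row.update(_param_dict(self.params))
        row["1e3_RMSD"] = round(1e3 * self.rmsd, 5)
        row["100_ARD"] = round(100 * self.ard, 5)
        return row


def _param_dict(params) -> dict:
    d = {}
    for k, v in vars(params).items():
        d[k] = v
    return d


# --------------------------------------------------------------------------
# model registry: vector <-> params, evaluator, starts, bounds, AIC k


def _apelblat_from_vec(v):
    return M.ApelblatParams(*v)


def _lnx_design(model: str, T: np.ndarray) -> np.ndarray:
    if model == "apelblat":
        return np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])
    return np.column_stack([np.ones_like(T), 1.0 / T])


@dataclass(frozen=True)
class _Spec:
    n_params: int
    k_aic: int
    default_objective: str
    to_params: Callable
    evaluate: Callable  # (params, dataset, context) -> x_cal
    starts: Callable  # (dataset, context) -> list of vectors
    bounds: tuple


def _eval_apelblat(p, ds, ctx):
    return M.apelblat_x(p, ds.T)


def _eval_vanthoff(p, ds, ctx):
    return M.vanthoff_x(p, ds.T)


def _eval_lambda_h(p, ds, ctx):
    return M.lambda_h_x(p, ds.T, ctx["solute"].Tm)


def _eval_nrtl(p, ds, ctx):
    solute = ctx["solute"]
    g1 = lambda x, T: M.nrtl_gamma(x, T, p)[0]
    return M.sle_solve_x_grid(g1, ds.T, solute)


def _eval_uniquac(p, ds, ctx):
    solute, structure = ctx["solute"], ctx["structure"]
    g1 = lambda x, T: M.uniquac_gamma(x, T, p, structure)[0]
    return M.sle_solve_x_grid(g1, ds.T, solute)


def _eval_wilson(p, ds, ctx):
    w1 = ds.system.w1 if ds.system.w1 is not None else np.array(
        [pt.w1 for pt in ds.points]
    )
    x1p = ctx["x1_pure"](ds.T)
    x2p = ctx["x2_pure"](ds.T)
    return M.modified_wilson_xm(p, w1, x1p, x2p)


def _eval_wilson_vanthoff(p, ds, ctx):
    w1 = ds.system.w1 if ds.system.w1 is not None else np.array(
        [pt.w1 for pt in ds.points]
    )
    vh1, vh2 = ctx["vanthoff_pure"]
    full = M.WilsonVantHoffParams(
        lam12=p.lam12, lam21=p.lam21, A1=vh1.A, B1=vh1.B, A2=vh2.A, B2=vh2.B
    )
    return M.wilson_vanthoff_xm(full, w1, ds.T)


def _starts_lnx(model):
    def f(ds, ctx):
        X = _lnx_design(model, ds.T)
        coef, *_ = np.linalg.lstsq(X, np.log(ds.x_exp), rcond=None)
        return [coef]

    return f


def _starts_lambda_h(ds, ctx):
    solute = ctx["solute"]
    h0 = solute.dHfus / M.R_GAS
    return [np.array([lam, h]) for lam in (0.1, 0.3, 1.0, 3.0) for h in (h0, 1000.0, 3000.0, 6000.0)]


_DG_GRID = (-6000.0, -3000.0, -1000.0, -500.0, 500.0, 1000.0, 3000.0, 6000.0)


def _starts_gamma(ds, ctx):
    return [np.array([a, b]) for a in _DG_GRID for b in _DG_GRID]


def _starts_wilson(ds, ctx):
    vals = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)
    return [np.array([a, b]) for a in vals for b in vals]


_REGISTRY: dict[str, _Spec] = {
    "apelblat": _Spec(
        3, 3, "lnx", lambda v: M.ApelblatParams(*v), _eval_apelblat,
        _starts_lnx("apelblat"), (-np.inf, np.inf),
    ),
    "vanthoff": _Spec(
        2, 2, "lnx", lambda v: M.VantHoffParams(*v), _eval_vanthoff,
        _starts_lnx("vanthoff"), (-np.inf, np.inf),
    ),
    "lambda_h": _Spec(
        2, 2, "x", lambda v: M.LambdaHParams(*v), _eval_lambda_h,
        _starts_lambda_h, ([1e-6, 1.0], [50.0, 1e6]),
    ),
    "nrtl": _Spec(
        2, 4, "x", lambda v: M.NRTLParams(*v), _eval_nrtl,
        _starts_gamma, ([-5e4, -5e4], [5e4, 5e4]),
    ),
    "uniquac": _Spec(
        2, 4, "x", lambda v: M.UNIQUACParams(*v), _eval_uniquac,
        _starts_gamma, ([-5e4, -5e4], [5e4, 5e4]),
    ),
    "wilson": _Spec(
        2, 2, "x", lambda v: M.WilsonParams(*v), _eval_wilson,
        _starts_wilson, ([-50.0, -50.0], [50.0, 50.0]),
    ),
    "wilson_vanthoff": _Spec(
        2, 2, "x", lambda v: M.WilsonParams(*v), _eval_wilson_vanthoff,
        _starts_wilson, ([-50.0, -50.0], [50.0, 50.0]),
    ),
}

MODEL_NAMES = tuple(_REGISTRY)


def fit_model(
    dataset: SolubilityDataset,
    model: str,
    solute: SoluteProperties = DEHYDROABIETIC_ACID,
    objective: str | None = None,
    structure: M.UNIQUACStructure | None = None,
    x1_pure: Callable | None = None,
    x2_pure: Callable | None = None,
    vanthoff_pure: tuple[M.VantHoffParams, M.VantHoffParams] | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit a named solubility model to a dataset by least squares.

    Parameters
    ----------
    model : one of :data:`MODEL_NAMES`.
    objective : ``"x"`` (squared residuals in mole fraction) or ``"lnx"``
        (squared residuals in ln x); defaults to the model's convention.
    structure : UNIQUAC r/q; derived from the shipped group table when the
        dataset's solvent names are known and none is given.
    x1_pure, x2_pure : callables T -> pure-solvent solubility, required for
        the modified Wilson rule.
    vanthoff_pure : pure-solvent van't Hoff parameter pairs, required for
        the Wilson–van't Hoff rule.

    The optimiser is deterministic: a fixed multistart grid of initial
    vectors, each refined by trust-region least squares, with ties broken
    by lowest objective value then lexicographic parameter order.
    """
    if model not in _REGISTRY:
        raise FitError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    spec = _REGISTRY[model]
    if len(dataset) <= spec.n_params:
        raise ValueError(
            f"need more than {spec.n_params} points to fit {model!r}, have {len(dataset)}"
        )
    objective = objective or spec.default_objective
    if objective not in ("x", "lnx"):
        raise ValueError("objective must be 'x' or 'lnx'")

    ctx = {"solute": solute, "x1_pure": x1_pure, "x2_pure": x2_pure,
           "vanthoff_pure": vanthoff_pure}
    if model == "uniquac":
        if structure is None:
            if not dataset.system.molar_masses:
                raise ValueError("uniquac needs a UNIQUACStructure or known solvent names")
            structure = M.structure_for(solute.name, dataset.system.names)
        ctx["structure"] = structure
    if model == "wilson" and (x1_pure is None or x2_pure is None):
        raise ValueError("the modified Wilson rule needs x1_pure and x2_pure callables")
    if model == "wilson_vanthoff" and vanthoff_pure is None:
        raise ValueError("the Wilson-van't Hoff rule needs pure-solvent van't Hoff parameters")

    x_exp = dataset.x_exp

    # closed-form OLS for log-linear models under the ln-x objective
    if model in ("apelblat", "vanthoff") and objective == "lnx":
        X = _lnx_design(model, dataset.T)
        coef, *_ = np.linalg.lstsq(X, np.log(x_exp), rcond=None)
        params = spec.to_params(coef)
        x_cal = spec.evaluate(params, dataset, ctx)
        rd, ard, rmsd, rss = deviation_metrics(x_exp, x_cal)
        return FitResult(model, params, np.asarray(x_cal), rd, ard, rmsd, rss,
                         len(dataset), spec.n_params, spec.k_aic, True, objective,
                         dataset.label)

    def residuals(vec):
        try:
            x_cal = spec.evaluate(spec.to_params(vec), dataset, ctx)
        except (M.ModelError, M.ConvergenceError):
            return np.full(len(dataset), 1e6)
        x_cal = np.asarray(x_cal, dtype=float)
        # a mole fraction outside (0, 1) marks an unphysical parameter region
        if np.any(~np.isfinite(x_cal)) or np.any(x_cal <= 0) or np.any(x_cal >= 1):
            return np.full(len(dataset), 1e6)
        if objective == "lnx":
            return np.log(x_cal) - np.log(x_exp)
        return x_cal - x_exp

    starts = list(spec.starts(dataset, ctx)) + list(extra_starts)
    best = None
    for v0 in starts:
        lo, hi = spec.bounds
        v0 = np.clip(np.asarray(v0, dtype=float), lo, hi) if spec.bounds != (-np.inf, np.inf) else np.asarray(v0, dtype=float)
        try:
            sol = least_squares(residuals, v0, bounds=spec.bounds,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        cost = 2.0 * sol.cost
        key = (cost, tuple(sol.x))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitError(f"{model}: no start converged")
    sol = best[1]
    params = spec.to_params(sol.x)
    x_cal = np.asarray(spec.evaluate(params, dataset, ctx), dtype=float)
    rd, ard, rmsd, rss = deviation_metrics(x_exp, x_cal)
    return FitResult(model, params, x_cal, rd, ard, rmsd, rss, len(dataset),
                     spec.n_params, spec.k_aic, bool(sol.success), objective,
                     dataset.label)
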