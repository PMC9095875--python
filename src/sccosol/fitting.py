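"""Multi-start nonlinear regression of solubility correlations.

Each fit runs ``n_starts`` local optimizations from scrambled-Halton
starting points inside the parameter bounds (plus one deterministic start
obtained by log-linearizing the model where its structure allows it), keeps
the best local optimum, and records per-start diagnostics. A seeded Halton
sequence is prefix-nested: the starts used at ``n_starts = k`` are the
first k of those used at any larger count, so adding starts can only
improve (or preserve) the best objective. Every stage is seeded, so a fit
is a pure function of (dataset, model, config, constants).

Objectives:

* ``aard`` -- mean absolute relative deviation of y2 (the field's headline
  statistic); minimized via an L2 pass on relative residuals followed by a
  Nelder-Mead polish of the true L1 objective.
* ``sse_y`` -- sum of squared residuals in mole-fraction space (the basis of
  the variance term in the corrected AIC).
* ``sse_log_y`` -- squared residuals of ln(y2); robust for magnitudes
  spanning a decade.

The Mendez-Santiago--Teja model is special-cased: it is linear in its
parameters in the transformed space ``T ln(y2 P) = H0 + H1 rho1 + H2 T`` and
is fitted there exactly by ordinary least squares (the conventional route
for this model), after which metrics are evaluated in mole-fraction space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .dataset import SolubilityDataset, SubstanceConstants
from .models import ModelDefinition, ParameterSet, get_model

__all__ = [
    "FitConfig",
    "FitResult",
    "FittingError",
    "fit_model",
    "fit_per_isotherm",
    "objective_value",
]

_OBJECTIVES = ("aard", "sse_y", "sse_log_y")


class FittingError(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitConfig:
    """Regression settings. ``bounds`` overrides the model's default box."""

    objective: str = "aard"
    n_starts: int = 64
    seed: int = 1
    bounds: tuple[tuple[float, float], ...] | None = None
    tolerance: float = 1.0e-10
    max_iterations: int = 2000

    def __post_init__(self) -> None:
        if self.objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {_OBJECTIVES}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class FitResult:
    parameter_set: ParameterSet
    objective: str
    objective_value: float
    predictions: tuple[float, ...]
    converged: bool
    n_starts_converged: int
    best_start_index: int

    @property
    def theta(self) -> np.ndarray:
        return np.asarray(self.parameter_set.values)


# ---------------------------------------------------------------------------
# Objective evaluation


def _residuals(kind: str, y_exp, y_calc):
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if kind == "aard":
        return (y_calc - y_exp) / y_exp
    if kind == "sse_y":
        return y_calc - y_exp
    if kind == "sse_log_y":
        bad = y_calc <= 0
        out = np.empty_like(y_exp)
        out[~bad] = np.log(y_calc[~bad]) - np.log(y_exp[~bad])
        out[bad] = 50.0  # heavy penalty for non-positive predictions
        return out
    raise ValueError(kind)


def objective_value(kind: str, y_exp, y_calc) -> float:
    """Scalar objective: mean |rel. dev.| for ``aard``, sum of squares else."""
    r = _residuals(kind, y_exp, y_calc)
    if not np.all(np.isfinite(r)):
        return np.inf
    if kind == "aard":
        return float(np.mean(np.abs(r)))
    return float(np.sum(r**2))


# ---------------------------------------------------------------------------
# Starting points


def _qmc_starts(model: ModelDefinition, bounds, n: int, seed: int) -> np.ndarray:
    """Scrambled-Halton starts inside the bounds; parameters flagged
    ``log_sample`` are sampled log-uniformly over (max(lb, 1e-2), ub)."""
    q = len(bounds)
    sampler = qmc.Halton(d=q, scramble=True, seed=seed)
    u = sampler.random(n)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    logmask = np.array(model.log_sample or (False,) * q)
    starts = np.empty((n, q))
    lin = ~logmask
    starts[:, lin] = lo[lin] + u[:, lin] * (hi[lin] - lo[lin])
    if logmask.any():
        llo = np.log10(np.maximum(lo[logmask], 1.0e-2))
        lhi = np.log10(hi[logmask])
        starts[:, logmask] = 10.0 ** (llo + u[:, logmask] * (lhi - llo))
    return starts


def _mt_design(T, P, rho1):
    """Design matrix and response of the MT transformed-space regression."""
    lhs = T * np.log(np.asarray(P, dtype=float))
    return np.column_stack([np.ones_like(T), rho1, T]), lhs


def _smart_start(model: ModelDefinition, T, P, rho1, y, constants):
    """Deterministic start from a log-linearization of the model, where one
    exists. Returns None for models without a useful linear form."""
    ln_y = np.log(y)
    mid = model.model_id
    try:
        if mid == "chrastil":
            # ln(y/(1-y)) = (kappa-1) ln rho + E0 + E1/T
            resp = np.log(y / (1.0 - y))
            X = np.column_stack([np.log(rho1), np.ones_like(T), 1.0 / T])
            c, *_ = np.linalg.lstsq(X, resp, rcond=None)
            return np.array([c[0] + 1.0, c[1], c[2]])
        if mid == "r_chrastil":
            M_kg = constants.solvent_molar_mass / 1000.0
            base = np.log(constants.gas_constant * T * rho1 / (M_kg * constants.rchrastil_f0 * 1e6))
            X = np.column_stack([base, np.ones_like(T), 1.0 / T])
            c, *_ = np.linalg.lstsq(X, ln_y, rcond=None)
            return np.array([c[0] + 1.0, c[1], c[2]])
        if mid == "bartle":
            resp = np.log(y * P / constants.bartle_Pref)
            X = np.column_stack([np.ones_like(T), 1.0 / T, rho1 - constants.bartle_rhoref])
            c, *_ = np.linalg.lstsq(X, resp, rcond=None)
            return c
        if mid == "alwi_garlapati":
            Tr = T / constants.solvent_Tc
            rr = rho1 / constants.solvent_rhoc
            resp = np.log(y * rr * Tr)
            X = np.column_stack([np.ones_like(T), 1.0 / Tr, rr])
            c, *_ = np.linalg.lstsq(X, resp, rcond=None)
            return c
        if mid == "sodeifian":
            X = np.column_stack(
                [
                    np.ones_like(T),
                    P**2 / T,
                    np.log(rho1 * T),
                    rho1 * np.log(rho1),
                    P * np.log(T),
                    np.log(rho1) / T,
                ]
            )
            c, *_ = np.linalg.lstsq(X, ln_y, rcond=None)
            return c
        if mid == "reddy_garlapati":
            Tr = T / constants.solvent_Tc
            Pr = P / constants.solvent_Pc
            X = np.column_stack(
                [Tr**2, Pr * Tr**2, Pr**2 * Tr**2, np.ones_like(T), Pr, Pr**2]
            )
            c, *_ = np.linalg.lstsq(X, y, rcond=None)
            return c
        if mid == "mt":
            X, lhs = _mt_design(T, P, rho1)
            c, *_ = np.linalg.lstsq(X, ln_y * T + lhs, rcond=None)
            return c
        if mid in ("new_model", "new_model_textual"):
            # relaxed linearization: R T (melt - ln y) =
            #   dCp * T g(T) + a11 s^2 - 2 sqrt(a11 a22) s + a22,  s = sqrt(v2 rho1)
            # solved by OLS with sqrt(a11 a22) as a free 4th coefficient,
            # then projected back onto (dCp, a11, a22)
            R = constants.gas_constant
            Tm = constants.solute_melting_temperature
            if mid == "new_model":
                melt = 6.54 * (1.0 - T / Tm)
            else:
                melt = 6.54 * (1.0 - Tm / T)
            g = np.log(T / Tm) - Tm * (1.0 / Tm - 1.0 / T)
            s_ = np.sqrt(constants.solute_molar_volume * rho1)
            w = R * T * (melt - ln_y)
            X = np.column_stack([T * g, s_**2, -2.0 * s_, np.ones_like(T)])
            c, *_ = np.linalg.lstsq(X, w, rcond=None)
            dCp, a11, a22 = c[0], max(c[1], 0.0), max(c[3], 0.0)
            return np.array([dCp, a11, a22])
    except np.linalg.LinAlgError:
        return None
    return None


# ---------------------------------------------------------------------------
# Core fit


def _fit_mt_linear(dataset, config, constants) -> FitResult:
    """Exact OLS fit of the MT model in T ln(y2 P) space."""
    T, P, rho1, y = dataset.arrays()
    X, lhs = _mt_design(T, P, rho1)
    resp = T * np.log(y * P)
    coef, *_ = np.linalg.lstsq(X, resp, rcond=None)
    model = get_model("mt")
    y_calc = model(T, P, rho1, coef, constants)
    return FitResult(
        parameter_set=ParameterSet("mt", tuple(float(v) for v in coef)),
        objective=config.objective,
        objective_value=objective_value(config.objective, y, y_calc),
        predictions=tuple(float(v) for v in y_calc),
        converged=True,
        n_starts_converged=1,
        best_start_index=0,
    )


def fit_model(
    dataset: SolubilityDataset,
    model: ModelDefinition | str,
    config: FitConfig | None = None,
    constants: SubstanceConstants | None = None,
) -> FitResult:
    """Fit one correlation to a dataset by seeded multi-start regression.

    Each start runs a bounded trust-region least-squares pass on the
    objective's residual vector, then a bounded Nelder-Mead polish of the
    scalar objective. The best converged start wins; ties at equal objective
    go to the lower start index, making the result deterministic.
    """
    if isinstance(model, str):
        model = get_model(model)
    config = config or FitConfig()
    constants = constants or SubstanceConstants()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if len(dataset) < model.parameter_count:
        raise ValueError(
            f"dataset has {len(dataset)} points but {model.model_id} has "
            f"{model.parameter_count} parameters"
        )

    if model.model_id == "mt":
        return _fit_mt_linear(dataset, config, constants)

    T, P, rho1, y = dataset.arrays()
    bounds = config.bounds or model.bounds
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)

    def resid(theta):
        y_calc = model(T, P, rho1, theta, constants)
        r = _residuals(config.objective, y, y_calc)
        return np.where(np.isfinite(r), r, 1.0e6)

    def scalar(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return np.inf
        return objective_value(config.objective, y, model(T, P, rho1, theta, constants))

    starts = list(_qmc_starts(model, bounds, config.n_starts, config.seed))
    smart = _smart_start(model, T, P, rho1, y, constants)
    if smart is not None and np.all(np.isfinite(smart)):
        starts.insert(0, np.clip(smart, lo, hi))

    best = None
    diagnostics = []
    n_ok = 0
    for i, theta0 in enumerate(starts):
        try:
            ls = optimize.least_squares(
                resid,
                theta0,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=config.max_iterations,
            )
            polish = optimize.minimize(
                scalar,
                np.clip(ls.x, lo, hi),
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={
                    "xatol": 1e-12,
                    "fatol": config.tolerance,
                    "maxiter": config.max_iterations,
                    "maxfev": config.max_iterations,
                },
            )
            val = float(polish.fun)
            theta = polish.x
            if not np.isfinite(val):
                raise RuntimeError("non-finite objective at optimum")
            n_ok += 1
            diagnostics.append((i, val, True))
            if best is None or val < best[1]:
                best = (i, val, theta)
        except Exception as exc:  # noqa: BLE001 - per-start failures are data
            diagnostics.append((i, math.inf, False))
    if best is None:
        raise FittingError(
            f"all {len(starts)} starts failed for {model.model_id}", diagnostics
        )

    i_best, val, theta = best
    # one re-polish from the incumbent: restarts the simplex, which often
    # escapes the flat facets of the L1 (aard) objective
    try:
        ls2 = optimize.least_squares(
            resid, theta, bounds=(lo, hi), method="trf", x_scale="jac",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=config.max_iterations,
        )
        for x0 in (theta, np.clip(ls2.x, lo, hi)):
            p2 = optimize.minimize(
                scalar, x0, method="Nelder-Mead", bounds=list(zip(lo, hi)),
                options={"xatol": 1e-13, "fatol": config.tolerance,
                         "maxiter": 4 * config.max_iterations,
                         "maxfev": 4 * config.max_iterations},
            )
            if np.isfinite(p2.fun) and p2.fun < val:
                val, theta = float(p2.fun), p2.x
    except Exception:  # noqa: BLE001 - keep the incumbent on any failure
        pass
    y_calc = model(T, P, rho1, theta, constants)
    return FitResult(
        parameter_set=ParameterSet(model.model_id, tuple(float(v) for v in theta)),
        objective=config.objective,
        objective_value=val,
        predictions=tuple(float(v) for v in y_calc),
        converged=n_ok > 0,
        n_starts_converged=n_ok,
        best_start_index=i_best,
    )


def fit_per_isotherm(
    dataset: SolubilityDataset,
    model: ModelDefinition | str,
    config: FitConfig | None = None,
    constants: SubstanceConstants | None = None,
) -> list[FitResult]:
    """One independent fit per temperature, ascending. Each isotherm must
    hold at least as many points as the model has parameters."""
    if isinstance(model, str):
        model = get_model(model)
    results = []
    for t, iso in dataset.isotherms().items():
        if len(iso) < model.parameter_count:
            raise ValueError(
                f"isotherm {t} K has {len(iso)} points, fewer than the "
                f"{model.parameter_count} parameters of {model.model_id}"
            )
        res = fit_model(iso, model, config, constants)
        res = replace(
            res,
            parameter_set=replace(
                res.parameter_set, scope="per_isotherm", isotherm_temperature=t
            ),
        )
        results.append(res)
    return results
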