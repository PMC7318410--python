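"""Parameter estimation and model validation for the fermentation model.

Fitting minimizes the residual between simulated and measured time courses
over a chosen subset of kinetic parameters.  The default objective is the
sum of squared differences (SSD), minimized by damped Gauss-Newton
(Levenberg-Marquardt-type) steps via :func:`scipy.optimize.least_squares`
with box bounds; a sum-of-absolute-differences objective is selectable and
handled by a derivative-free simplex search.

Validation metrics per measured variable:

    RMSE = sqrt( sum (X_p - X_exp)^2 / n )
    R^2  = 1 - SS_res / SS_tot
    BF   = 10 ^ mean( log10(X_exp / X_p) )        (bias factor)
    AF   = 10 ^ mean( |log10(X_p / X_exp)| )      (accuracy factor)

BF = AF = 1 indicates a perfect match; AF >= 1 always.  Pairs with a
non-positive prediction or observation are excluded from BF/AF (count
reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import GrowthParams, OrganismParams
from .reactor import (
    OperatingPhase,
    ReactorState,
    SimulationResult,
    simulate_schedule,
)
from .stoich import SUGARS, yield_set_from_cell_mass_yield

__all__ = [
    "VARIABLES",
    "ObservationSet",
    "ParamBound",
    "FitConfig",
    "Metrics",
    "FitResult",
    "objective",
    "validation_metrics",
    "fit_parameters",
    "set_param",
    "get_param",
]

#: Measured variables, mapped to trajectory columns (all g/L).
VARIABLES = {"glucose": 0, "cellobiose": 1, "xylose": 2, "biomass": 3, "lactate": 4}


@dataclass
class ObservationSet:
    """Measured time series plus the schedule that produced them.

    ``data`` is long-form with columns time_h, variable, value_gL, replicate;
    variables are named as in :data:`VARIABLES`.
    """

    data: pd.DataFrame
    schedule: list[OperatingPhase]
    initial_state: ReactorState

    def __post_init__(self) -> None:
        required = {"time_h", "variable", "value_gL", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        bad = set(self.data["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown variables {sorted(bad)}")
        if (self.data["value_gL"] < 0).any():
            raise ValueError("observed values must be >= 0")
        span = sum(p.duration for p in self.schedule)
        if (self.data["time_h"] < 0).any() or (self.data["time_h"] > span + 1e-9).any():
            raise ValueError("observation times outside the schedule span")

    @property
    def n(self) -> int:
        return len(self.data)


class ParamBound(NamedTuple):
    """Box bound and initial guess for one free parameter."""

    lower: float
    upper: float
    init: float


@dataclass
class FitConfig:
    """Free-parameter set and optimizer settings.

    Free parameters are addressed by dotted paths into OrganismParams:
    "<sugar>.mu_max|Ks|Kis|Kip|cell_mass_yield", "K_D", "K_ccr".
    Default bounds: [1e-6, 5] h^-1 for rates, [1e-6, 1e4] g/L for
    concentration coefficients.
    """

    free: dict[str, ParamBound]
    norm: str = "sum_of_squares"
    multistart: int = 1
    seed: int = 0
    grid_dt: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.norm not in ("sum_of_squares", "sum_of_absolute"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        for name, b in self.free.items():
            if not (0.0 <= b.lower <= b.init <= b.upper):
                raise ValueError(
                    f"{name}: need 0 <= lower <= init <= upper, got {b}"
                )


@dataclass(frozen=True)
class Metrics:
    """Goodness-of-fit metrics for one variable."""

    rmse: float
    r2: float
    bf: float
    af: float
    n: int
    excluded_pairs: int = 0


@dataclass
class FitResult:
    """Estimates with uncertainties, objective value and per-variable metrics."""

    params: OrganismParams
    estimates: dict[str, float]
    stderr: dict[str, float]
    objective_value: float
    converged: bool
    warnings: list[str] = field(default_factory=list)
    metrics: dict[str, Metrics] = field(default_factory=dict)
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "stderr": self.stderr,
            "objective_value": self.objective_value,
            "converged": self.converged,
            "warnings": self.warnings,
            "n_obs": self.n_obs,
            "metrics": {
                v: {
                    "rmse": m.rmse,
                    "r2": m.r2,
                    "bf": m.bf,
                    "af": m.af,
                    "n": m.n,
                    "excluded_pairs": m.excluded_pairs,
                }
                for v, m in self.metrics.items()
            },
        }


def objective(predictions, observations, norm: str = "sum_of_squares") -> float:
    """Residual objective: SSD (default) or sum of absolute differences."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    r = p - o
    if norm == "sum_of_squares":
        return float(np.sum(r * r))
    if norm == "sum_of_absolute":
        return float(np.sum(np.abs(r)))
    raise ValueError(f"unknown norm {norm!r}")


def validation_metrics(predictions, observations) -> Metrics:
    """RMSE, R2, bias factor and accuracy factor for paired sequences."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    n = p.size
    if n == 0:
        raise ValueError("empty sequences")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    pos = (p > 0) & (o > 0)
    excluded = int(n - pos.sum())
    if pos.any():
        logratio = np.log10(p[pos] / o[pos])
        bf = float(10.0 ** (-np.mean(logratio)))  # 10^mean(log10(obs/pred))
        af = float(10.0 ** np.mean(np.abs(logratio)))
    else:
        bf = af = float("nan")
    return Metrics(rmse=rmse, r2=r2, bf=bf, af=af, n=n, excluded_pairs=excluded)


# ---------------------------------------------------------------------------
# parameter addressing


def _split(path: str) -> tuple[str | None, str]:
    if path in ("K_D", "K_ccr"):
        return None, path
    sugar, _, attr = path.partition(".")
    if sugar not in SUGARS or attr not in (
        "mu_max",
        "Ks",
        "Kis",
        "Kip",
        "cell_mass_yield",
    ):
        raise KeyError(f"unknown parameter path {path!r}")
    return sugar, attr


def get_param(params: OrganismParams, path: str) -> float:
    sugar, attr = _split(path)
    if sugar is None:
        v = getattr(params, attr)
        return float("nan") if v is None else v
    if attr == "cell_mass_yield":
        return params.yields[sugar].cell_mass_yield
    return getattr(params.per_sugar[sugar], attr)


def set_param(params: OrganismParams, path: str, value: float) -> OrganismParams:
    """Return a copy of ``params`` with one dotted-path entry replaced."""
    sugar, attr = _split(path)
    if sugar is None:
        return replace(params, **{attr: value})
    if attr == "cell_mass_yield":
        yields = dict(params.yields)
        yields[sugar] = yield_set_from_cell_mass_yield(value, SUGARS[sugar])
        return replace(params, yields=yields)
    per_sugar = dict(params.per_sugar)
    per_sugar[sugar] = replace(per_sugar[sugar], **{attr: value})
    return replace(params, per_sugar=per_sugar)


# ---------------------------------------------------------------------------
# fitting


def _predict(
    obs: ObservationSet, params: OrganismParams, config: FitConfig
) -> np.ndarray:
    """Model predictions at every observation row, via schedule simulation."""
    res = simulate_schedule(
        obs.schedule,
        obs.initial_state,
        params,
        grid_dt=config.grid_dt,
        rtol=config.rtol,
        atol=config.atol,
    )
    out = np.empty(obs.n)
    for j, (t, var) in enumerate(zip(obs.data["time_h"], obs.data["variable"])):
        out[j] = np.interp(t, res.time, res.states[:, VARIABLES[var]])
    return out


def fit_parameters(
    obs: ObservationSet | list[ObservationSet],
    config: FitConfig,
    params0: OrganismParams,
) -> FitResult:
    """Estimate free parameters by simulating the schedule(s) per candidate.

    ``obs`` may be a single observation set or a list of sets (e.g. batches
    at several initial sugar concentrations fitted jointly, which is what
    identifies the saturation and inhibition coefficients separately);
    residuals are pooled.  Deterministic given ``config.seed`` and
    ``config.multistart``: extra starts are drawn log-uniformly within the
    bounds.  Non-convergence returns the best point found with
    ``converged=False``; a flat objective direction raises an
    'unidentifiable' warning in the result.
    """
    obs_sets = [obs] if isinstance(obs, ObservationSet) else list(obs)
    names = list(config.free)
    n_total = sum(o.n for o in obs_sets)
    if n_total < len(names):
        raise ValueError("need at least as many observations as free parameters")
    lo = np.array([config.free[n].lower for n in names])
    hi = np.array([config.free[n].upper for n in names])
    x0 = np.array([config.free[n].init for n in names])
    values = np.concatenate(
        [o.data["value_gL"].to_numpy(dtype=float) for o in obs_sets]
    )

    def apply(x: np.ndarray) -> OrganismParams:
        p = params0
        for name, v in zip(names, x):
            p = set_param(p, name, v)
        return p

    def predict_all(p: OrganismParams) -> np.ndarray:
        return np.concatenate([_predict(o, p, config) for o in obs_sets])

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            return predict_all(apply(x)) - values
        except Exception:
            return np.full(n_total, 1e6)

    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(config.multistart - 1):
        lo_s = np.maximum(lo, 1e-6)
        starts.append(np.exp(rng.uniform(np.log(lo_s), np.log(np.maximum(hi, lo_s)))))

    fit_warnings: list[str] = []
    best = None
    if config.norm == "sum_of_squares":
        for start in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(
                    residuals, start, bounds=(lo, hi), method="trf", x_scale="jac"
                )
            if best is None or sol.cost < best.cost:
                best = sol
        x_hat = best.x
        ssd = objective(residuals(x_hat) + values, values)
        converged = bool(best.success)
        jac = best.jac
    else:
        def f(x):
            return objective(predict_all(apply(np.clip(x, lo, hi))), values,
                             norm="sum_of_absolute")

        best_val = np.inf
        x_hat = x0
        converged = False
        for start in starts:
            sol = optimize.minimize(f, start, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10})
            if sol.fun < best_val:
                best_val, x_hat, converged = sol.fun, np.clip(sol.x, lo, hi), bool(sol.success)
        ssd = best_val
        jac = None

    if not converged:
        fit_warnings.append("optimizer did not report convergence; best point returned")

    stderr = {n: float("nan") for n in names}
    if jac is not None:
        col_norms = np.linalg.norm(jac, axis=0)
        for n, cn in zip(names, col_norms):
            if cn < 1e-10:
                fit_warnings.append(f"unidentifiable parameter {n!r} (flat objective)")
        dof = n_total - len(names)
        if dof > 0 and np.all(col_norms > 1e-10):
            try:
                cov = np.linalg.inv(jac.T @ jac) * (2.0 * best.cost / dof)
                stderr = {n: float(np.sqrt(max(cov[i, i], 0.0)))
                          for i, n in enumerate(names)}
            except np.linalg.LinAlgError:
                pass
    if not values.any():
        fit_warnings.append("all observations are zero: parameters unidentifiable")

    params_hat = apply(x_hat)
    pred = predict_all(params_hat)
    variables = np.concatenate(
        [o.data["variable"].to_numpy() for o in obs_sets]
    )
    metrics: dict[str, Metrics] = {}
    for var in pd.unique(variables):
        m = variables == var
        metrics[var] = validation_metrics(pred[m], values[m])
    return FitResult(
        params=params_hat,
        estimates={n: float(v) for n, v in zip(names, x_hat)},
        stderr=stderr,
        objective_value=float(ssd),
        converged=converged,
        warnings=fit_warnings,
        metrics=metrics,
        n_obs=n_total,
    )
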