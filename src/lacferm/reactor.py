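"""Bioreactor mass balances: batch, chemostat (CFSTR) and cell-recycle (CF/CR).

Five coupled ODEs describe the three sugars, biomass and lactate:

    dS_sug/dt = D (S_sug_in - S_sug) - mu_sug X / Y^X_sug
    dX/dt     = D (X_in - sigma X) + (sum_sug mu_sug - K_D) X
    dS_la/dt  = D (S_la_in - S_la) + sum_sug (Y^la_sug / Y^X_sug) mu_sug X

where D is the dilution rate (h^-1) and sigma = ``cell_passes_membrane`` is
the fraction of the reactor cell concentration leaving with the effluent:
1 for a plain CFSTR (cells wash out with the liquid), 0 for ideal membrane
retention (CF/CR), so the effective cell removal rate is sigma*D and the
cell retention time decouples from the hydraulic retention time 1/D.

Schedules are ordered phases (batch -> continuous, dilution-rate ladders,
cell-concentration events at phase start) integrated piecewise with state
continuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import OrganismParams, growth_rates

__all__ = [
    "ReactorState",
    "FeedSpec",
    "ConcentrationEvent",
    "OperatingPhase",
    "SimulationResult",
    "SimulationError",
    "state_derivatives",
    "simulate_schedule",
    "simulate_to_steady_state",
    "concentration_event",
    "productivity",
    "consumed_ratio",
    "detect_steady_state",
    "STATE_FIELDS",
    "CSV_COLUMNS",
]

STATE_FIELDS = ("S_glu", "S_cel", "S_xyl", "X", "S_la")
#: Trajectory CSV schema (fixed units: hours, g/L).
CSV_COLUMNS = (
    "time_h",
    "glucose_gL",
    "cellobiose_gL",
    "xylose_gL",
    "biomass_gL",
    "lactate_gL",
)
_SUGAR_FIELD = {"glucose": "S_glu", "cellobiose": "S_cel", "xylose": "S_xyl"}


@dataclass(frozen=True)
class ReactorState:
    """Concentrations at one instant, all g/L (dry cell weight for X)."""

    S_glu: float = 0.0
    S_cel: float = 0.0
    S_xyl: float = 0.0
    X: float = 0.0
    S_la: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            if getattr(self, name) < 0.0:
                raise ValueError(f"ReactorState.{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ReactorState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(**dict(zip(STATE_FIELDS, y)))


@dataclass(frozen=True)
class FeedSpec:
    """Influent composition, g/L.  Default: sterile, product-free feed."""

    S_glu: float = 0.0
    S_cel: float = 0.0
    S_xyl: float = 0.0
    X_in: float = 0.0
    S_la_in: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S_glu", "S_cel", "S_xyl", "X_in", "S_la_in"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"FeedSpec.{name} must be >= 0")


@dataclass(frozen=True)
class ConcentrationEvent:
    """Instantaneous membrane concentration of cells at phase start.

    Broth volume is reduced ``volume_ratio``-fold with cells retained, so X
    is multiplied by the ratio while solutes pass to the permeate unchanged.
    """

    volume_ratio: float

    def __post_init__(self) -> None:
        if self.volume_ratio < 1.0:
            raise ValueError(f"volume_ratio must be >= 1, got {self.volume_ratio}")


@dataclass(frozen=True)
class OperatingPhase:
    """One reactor phase: mode, duration (h), dilution rate D (h^-1), feed."""

    mode: str
    duration: float
    D: float = 0.0
    cell_passes_membrane: float | None = None
    feed: FeedSpec = field(default_factory=FeedSpec)
    start_event: ConcentrationEvent | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "cfstr", "cfcr"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration <= 0.0:
            raise ValueError("duration must be > 0")
        if (self.mode == "batch") != (self.D == 0.0):
            raise ValueError("D must be 0 iff mode is batch")
        if self.D < 0.0:
            raise ValueError("D must be >= 0")
        sigma = self.cell_passes_membrane
        if sigma is None:
            sigma = {"batch": 1.0, "cfstr": 1.0, "cfcr": 0.0}[self.mode]
            object.__setattr__(self, "cell_passes_membrane", sigma)
        if not 0.0 <= sigma <= 1.0:
            raise ValueError("cell_passes_membrane must be in [0, 1]")
        if self.mode == "cfstr" and sigma != 1.0:
            raise ValueError("cfstr requires cell_passes_membrane == 1")


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid time and state."""

    def __init__(self, message: str, time: float, state: ReactorState):
        super().__init__(message)
        self.time = time
        self.state = state


def _check_sugars(phase: OperatingPhase, init: ReactorState, params: OrganismParams):
    for sugar, fld in _SUGAR_FIELD.items():
        present = getattr(init, fld) > 0.0 or getattr(phase.feed, fld) > 0.0
        if present and sugar not in params.per_sugar:
            raise ValueError(
                f"sugar {sugar!r} present in state/feed but absent from params"
            )


def state_derivatives(
    state: ReactorState, phase: OperatingPhase, params: OrganismParams
) -> np.ndarray:
    """Right-hand side of the five mass balances, in STATE_FIELDS order."""
    _check_sugars(phase, state, params)
    return _rhs(0.0, state.as_array(), phase, params)


def _rhs(t: float, y: np.ndarray, phase: OperatingPhase, params: OrganismParams):
    # reaction terms evaluated on max(S, 0): guards against solver undershoot
    yc = np.maximum(y, 0.0)
    state = ReactorState(**dict(zip(STATE_FIELDS, yc)))
    mus = growth_rates(state, params)
    D = phase.D
    sigma = phase.cell_passes_membrane
    feed = phase.feed

    dy = np.zeros(5)
    mu_sum = 0.0
    dla_rxn = 0.0
    for sugar, mu in mus.items():
        i = STATE_FIELDS.index(_SUGAR_FIELD[sugar])
        ys = params.yields[sugar]
        dy[i] = D * (getattr(feed, _SUGAR_FIELD[sugar]) - y[i]) - mu * state.X / ys.cell_mass_yield
        mu_sum += mu
        dla_rxn += (ys.lactate_mass_yield / ys.cell_mass_yield) * mu
    # sugars without kinetics entries are inert solutes
    for sugar, fld in _SUGAR_FIELD.items():
        if sugar not in mus:
            i = STATE_FIELDS.index(fld)
            dy[i] = D * (getattr(feed, fld) - y[i])
    dy[3] = D * (feed.X_in - sigma * y[3]) + (mu_sum - params.K_D) * state.X
    dy[4] = D * (feed.S_la_in - y[4]) + dla_rxn * state.X
    return dy


@dataclass
class SimulationResult:
    """Dense trajectory over a schedule, with derived per-step quantities.

    ``states`` is (n, 5) in STATE_FIELDS order; ``mu`` maps sugar name to an
    (n,) array of specific growth rates; ``productivity`` is D*S_la at each
    point; ``crt`` is the cell retention time (1/(sigma*D) in continuous
    phases, elapsed run time under full retention, inf during batch).
    """

    time: np.ndarray
    states: np.ndarray
    mu: dict[str, np.ndarray]
    productivity: np.ndarray
    crt: np.ndarray
    phase_index: np.ndarray
    schedule: list[OperatingPhase]

    @property
    def trajectory(self) -> list[ReactorState]:
        return [ReactorState.from_array(row) for row in self.states]

    def state_at(self, i: int) -> ReactorState:
        return ReactorState.from_array(self.states[i])

    @property
    def final_state(self) -> ReactorState:
        return self.state_at(-1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.time,
                "glucose_gL": self.states[:, 0],
                "cellobiose_gL": self.states[:, 1],
                "xylose_gL": self.states[:, 2],
                "biomass_gL": self.states[:, 3],
                "lactate_gL": self.states[:, 4],
            }
        )
        return df


def simulate_schedule(
    schedule: list[OperatingPhase],
    init: ReactorState,
    params: OrganismParams,
    *,
    grid_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the ODE system piecewise over an ordered phase schedule.

    State is carried over verbatim across phase boundaries; a phase's
    ``start_event`` (cell concentration) is applied instantaneously first.
    Output is on a fixed grid (default 0.1 h); concentrations are clipped
    at zero on output.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    phase_idx: list[np.ndarray] = []
    t0 = 0.0
    y = init.as_array()
    for k, phase in enumerate(schedule):
        if phase.start_event is not None:
            y = concentration_event(
                ReactorState.from_array(y), phase.start_event.volume_ratio
            ).as_array()
        _check_sugars(phase, ReactorState.from_array(y), params)
        t1 = t0 + phase.duration
        n = max(int(round(phase.duration / grid_dt)), 1)
        t_eval = np.linspace(t0, t1, n + 1)
        sol = solve_ivp(
            _rhs,
            (t0, t1),
            y,
            args=(phase, params),
            t_eval=t_eval,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last_t = sol.t[-1] if sol.t.size else t0
            last_y = sol.y[:, -1] if sol.t.size else y
            raise SimulationError(
                f"integration failed in phase {k} ({phase.mode}): {sol.message}",
                last_t,
                ReactorState.from_array(last_y),
            )
        keep = slice(1, None) if times else slice(None)  # strictly increasing grid
        times.append(sol.t[keep])
        states.append(np.maximum(sol.y[:, keep].T, 0.0))
        phase_idx.append(np.full(times[-1].shape, k, dtype=int))
        y = sol.y[:, -1]
        t0 = t1

    time = np.concatenate(times)
    st = np.concatenate(states)
    pidx = np.concatenate(phase_idx)

    mu = {s: np.empty_like(time) for s in params.per_sugar}
    prod = np.empty_like(time)
    crt = np.empty_like(time)
    for i in range(time.size):
        phase = schedule[pidx[i]]
        state = ReactorState.from_array(st[i])
        for s, v in growth_rates(state, params).items():
            mu[s][i] = v
        prod[i] = phase.D * state.S_la
        removal = phase.D * phase.cell_passes_membrane
        crt[i] = 1.0 / removal if removal > 0.0 else (time[i] if phase.D > 0 else np.inf)
    return SimulationResult(
        time=time,
        states=st,
        mu=mu,
        productivity=prod,
        crt=crt,
        phase_index=pidx,
        schedule=list(schedule),
    )


def simulate_to_steady_state(
    phase: OperatingPhase,
    init: ReactorState,
    params: OrganismParams,
    *,
    rel_tol: float = 1e-10,
    chunk: float | None = None,
    max_time: float = 20000.0,
    **solver_opts,
) -> ReactorState:
    """Run a single continuous phase until the state stops changing.

    Integrates in chunks (default 20/D h) and stops when every variable's
    relative change over a chunk is below ``rel_tol``.
    """
    if phase.D <= 0.0:
        raise ValueError("steady-state integration requires a continuous phase")
    if chunk is None:
        chunk = 20.0 / phase.D
    t = 0.0
    state = init
    while t < max_time:
        p = replace(phase, duration=chunk, start_event=None)
        res = simulate_schedule([p], state, params, **solver_opts)
        new = res.final_state
        old = state.as_array()
        delta = np.abs(new.as_array() - old) / np.maximum(np.abs(old), 1e-8)
        state = new
        t += chunk
        if np.max(delta) < rel_tol:
            return state
    return state


def concentration_event(state: ReactorState, volume_ratio: float) -> ReactorState:
    """Apply a membrane cell-concentration step: X scales, solutes unchanged."""
    if volume_ratio < 1.0:
        raise ValueError(f"volume_ratio must be >= 1, got {volume_ratio}")
    return replace(state, X=state.X * volume_ratio)


def productivity(S_la: float, D: float) -> float:
    """Volumetric lactate productivity, g L^-1 h^-1 (= product titer x D)."""
    if S_la < 0.0 or D < 0.0:
        raise ValueError("S_la and D must be >= 0")
    return S_la * D


def consumed_ratio(consumed_pentose: float, consumed_hexose: float) -> float:
    """Mass ratio of consumed pentose to consumed hexose (X/G or X/C)."""
    if consumed_pentose < 0.0 or consumed_hexose < 0.0:
        raise ValueError("consumed amounts must be >= 0")
    if consumed_hexose == 0.0:
        raise ZeroDivisionError("ratio undefined: zero hexose consumption")
    return consumed_pentose / consumed_hexose


def detect_steady_state(
    result: SimulationResult,
    window: float = 5.0,
    rel_tol: float = 1e-3,
    *,
    phase: int | None = None,
) -> tuple[float, ReactorState] | None:
    """Earliest time after which every variable varies < rel_tol over a window.

    Relative change is (max - min)/max(|max|, 1e-6 g/L) per variable over the
    trailing window.  Returns (window start time, state at window end), or
    None if the trajectory never settles.  ``phase`` restricts the search to
    one schedule phase.
    """
    mask = slice(None) if phase is None else result.phase_index == phase
    time = result.time[mask]
    states = result.states[mask]
    if time.size < 2 or time[-1] - time[0] < window:
        return None
    for i in range(time.size):
        # first index whose time covers the window (1e-6 h slack for float grids)
        j = min(np.searchsorted(time, time[i] + window - 1e-6, side="left") + 1,
                time.size)
        if time[j - 1] - time[i] < window - 1e-6:
            return None
        sl = states[i:j]
        span = sl.max(axis=0) - sl.min(axis=0)
        scale = np.maximum(np.abs(sl).max(axis=0), 1e-6)
        if np.all(span / scale < rel_tol):
            return time[i], ReactorState.from_array(states[j - 1])
    return None
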