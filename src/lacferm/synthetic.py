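"""Synthetic fermentation experiments mirroring the study protocols.

Presets cover single-sugar batches (10/20/50/100/150 g/L of glucose,
cellobiose or xylose), mixed-sugar batches (G100X50, C100X50), CFSTR
dilution-rate ladders on C100X60 (D = 0.05..0.25 h^-1) and C50X30
(D = 0.05..0.35 h^-1) run for three retention times per step, and a
cell-recycle run (36 h batch on C50X30, a 10x membrane cell-concentration
event, then continuous feeding of C50X30 at D = 0.2 h^-1 with full cell
retention, ~117 h total).

Measurements are the simulated trajectory sampled at a fixed interval with
multiplicative lognormal noise per replicate: value * exp(sigma*z) with
sigma = sqrt(ln(1 + cv^2)), which has exactly the requested coefficient of
variation and zero log-domain bias.  Ground truth (parameters, schedule,
seed, noise) is recorded in a manifest for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import VARIABLES, ObservationSet
from .kinetics import OrganismParams, qu25_table1
from .reactor import (
    ConcentrationEvent,
    FeedSpec,
    OperatingPhase,
    ReactorState,
    simulate_schedule,
)

__all__ = [
    "NoiseModel",
    "ExperimentPreset",
    "generate_experiment",
    "od_to_dcw",
    "list_presets",
    "get_preset",
    "DEFAULT_K_D",
    "DEFAULT_K_CCR",
    "DEFAULT_X0",
]

#: Generator decay coefficient, h^-1 (not reported by the study; chosen once).
DEFAULT_K_D = 0.02
#: Glucose-on-xylose repression coefficient for G+X presets, g/L (chosen once).
DEFAULT_K_CCR = 1.0
#: Inoculum dry cell weight after a 10% v/v transfer, g/L.
DEFAULT_X0 = 0.1

#: OD562 to dry-cell-weight conversion, g/L per OD unit.
OD562_TO_DCW = 0.218


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-scatter model for synthetic sampling."""

    cv: float = 0.03
    seed: int = 0
    sampling_interval: float = 3.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv < 0.0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sampling_interval <= 0.0:
            raise ValueError("sampling_interval must be > 0")


@dataclass(frozen=True)
class ExperimentPreset:
    """A named experiment: schedule, true parameters and initial state."""

    name: str
    schedule: tuple[OperatingPhase, ...]
    params: OrganismParams
    initial_state: ReactorState


def od_to_dcw(od562: float) -> float:
    """Convert optical density at 562 nm to dry cell weight (g/L)."""
    if od562 < 0.0:
        raise ValueError(f"OD562 must be >= 0, got {od562}")
    return OD562_TO_DCW * od562


def _batch(duration: float) -> OperatingPhase:
    return OperatingPhase(mode="batch", duration=duration)


def _ladder(feed: FeedSpec, rates: tuple[float, ...]) -> tuple[OperatingPhase, ...]:
    # three retention times per dilution step
    return tuple(
        OperatingPhase(mode="cfstr", duration=3.0 / d, D=d, feed=feed) for d in rates
    )


def _build_presets() -> dict[str, ExperimentPreset]:
    presets: dict[str, ExperimentPreset] = {}
    qu25 = {
        "glu": ("glucose", "S_glu"),
        "cel": ("cellobiose", "S_cel"),
        "xyl": ("xylose", "S_xyl"),
    }
    for short, (sugar, fld) in qu25.items():
        for s0 in (10, 20, 50, 100, 150):
            name = f"batch_{short}_{s0}"
            params = qu25_table1(sugars=(sugar,), K_D=DEFAULT_K_D)
            init = ReactorState(**{fld: float(s0), "X": DEFAULT_X0})
            presets[name] = ExperimentPreset(name, (_batch(48.0),), params, init)

    presets["batch_G100X50"] = ExperimentPreset(
        "batch_G100X50",
        (_batch(48.0),),
        qu25_table1(sugars=("glucose", "xylose"), K_D=DEFAULT_K_D, K_ccr=DEFAULT_K_CCR),
        ReactorState(S_glu=100.0, S_xyl=50.0, X=DEFAULT_X0),
    )
    presets["batch_C100X50"] = ExperimentPreset(
        "batch_C100X50",
        (_batch(60.0),),
        qu25_table1(sugars=("cellobiose", "xylose"), K_D=DEFAULT_K_D),
        ReactorState(S_cel=100.0, S_xyl=50.0, X=DEFAULT_X0),
    )

    cx = qu25_table1(sugars=("cellobiose", "xylose"), K_D=DEFAULT_K_D)
    feed_c100x60 = FeedSpec(S_cel=100.0, S_xyl=60.0)
    presets["cfstr_C100X60_ladder"] = ExperimentPreset(
        "cfstr_C100X60_ladder",
        (_batch(60.0),) + _ladder(feed_c100x60, (0.05, 0.10, 0.15, 0.20, 0.25)),
        cx,
        ReactorState(S_cel=100.0, S_xyl=60.0, X=DEFAULT_X0),
    )
    feed_c50x30 = FeedSpec(S_cel=50.0, S_xyl=30.0)
    presets["cfstr_C50X30_ladder"] = ExperimentPreset(
        "cfstr_C50X30_ladder",
        (_batch(36.0),)
        + _ladder(feed_c50x30, (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)),
        cx,
        ReactorState(S_cel=50.0, S_xyl=30.0, X=DEFAULT_X0),
    )
    presets["cfcr_C50X30"] = ExperimentPreset(
        "cfcr_C50X30",
        (
            _batch(36.0),
            OperatingPhase(
                mode="cfcr",
                duration=81.0,  # 117 h total run
                D=0.2,
                cell_passes_membrane=0.0,
                feed=feed_c50x30,
                start_event=ConcentrationEvent(volume_ratio=10.0),
            ),
        ),
        cx,
        ReactorState(S_cel=50.0, S_xyl=30.0, X=DEFAULT_X0),
    )
    return presets


_PRESETS = _build_presets()


def list_presets() -> tuple[str, ...]:
    """Names of all shipped experiment presets."""
    return tuple(_PRESETS)


def get_preset(name: str) -> ExperimentPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None


def generate_experiment(
    preset: ExperimentPreset, noise: NoiseModel
) -> tuple[ObservationSet, dict]:
    """Simulate a preset and sample noisy replicate measurements.

    Returns the observation set (long-form table) and a ground-truth
    manifest dict (true parameters, schedule, seed, noise settings).
    Deterministic per seed; cv = 0 reproduces the simulator output exactly.
    """
    res = simulate_schedule(list(preset.schedule), preset.initial_state, preset.params)
    total = res.time[-1]
    sample_times = np.arange(0.0, total + 1e-9, noise.sampling_interval)
    # variables actually modeled: sugars with kinetics entries, biomass, lactate
    sugar_vars = {"glucose": "glucose", "cellobiose": "cellobiose", "xylose": "xylose"}
    variables = [v for v in sugar_vars if v in preset.params.per_sugar]
    variables += ["biomass", "lactate"]

    rng = np.random.default_rng(noise.seed)
    sigma = math.sqrt(math.log(1.0 + noise.cv**2)) if noise.cv > 0 else 0.0
    rows = []
    for var in variables:
        col = VARIABLES[var]
        truth = np.interp(sample_times, res.time, res.states[:, col])
        for rep in range(noise.replicates):
            if sigma > 0:
                noisy = truth * np.exp(sigma * rng.standard_normal(truth.size))
            else:
                noisy = truth.copy()
            noisy = np.maximum(noisy, 0.0)
            rows.extend(
                {"time_h": t, "variable": var, "value_gL": v, "replicate": rep}
                for t, v in zip(sample_times, noisy)
            )
    data = pd.DataFrame(rows, columns=["time_h", "variable", "value_gL", "replicate"])
    obs = ObservationSet(
        data=data, schedule=list(preset.schedule), initial_state=preset.initial_state
    )
    manifest = {
        "preset": preset.name,
        "seed": noise.seed,
        "noise": {
            "cv": noise.cv,
            "sampling_interval_h": noise.sampling_interval,
            "replicates": noise.replicates,
        },
        "true_params": _params_dict(preset.params),
        "schedule": [_phase_dict(p) for p in preset.schedule],
        "initial_state": {f: getattr(preset.initial_state, f) for f in
                          ("S_glu", "S_cel", "S_xyl", "X", "S_la")},
    }
    return obs, manifest


def _params_dict(params: OrganismParams) -> dict:
    return {
        "per_sugar": {
            s: {"mu_max": g.mu_max, "Ks": g.Ks,
                "Kis": None if math.isinf(g.Kis) else g.Kis,
                "Kip": None if math.isinf(g.Kip) else g.Kip}
            for s, g in params.per_sugar.items()
        },
        "yields": {
            s: {"molar_cell_yield": y.molar_cell_yield,
                "cell_mass_yield": y.cell_mass_yield,
                "lactate_mass_yield": y.lactate_mass_yield}
            for s, y in params.yields.items()
        },
        "K_D": params.K_D,
        "K_ccr": params.K_ccr,
    }


def _phase_dict(p: OperatingPhase) -> dict:
    return {
        "mode": p.mode,
        "duration_h": p.duration,
        "D_per_h": p.D,
        "cell_passes_membrane": p.cell_passes_membrane,
        "feed_gL": {"glucose": p.feed.S_glu, "cellobiose": p.feed.S_cel,
                    "xylose": p.feed.S_xyl, "biomass": p.feed.X_in,
                    "lactate": p.feed.S_la_in},
        "event_volume_ratio": None if p.start_event is None
        else p.start_event.volume_ratio,
    }
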