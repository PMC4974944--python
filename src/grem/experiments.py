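"""Validation experiments: accuracy and precision of the density estimator
measured against simulated truth.

Four studies are provided, mirroring the validation protocol of the
encounter model:

1. *Submodel accuracy* — fixed-duration surveys over a grid of sensor and
   signal widths; per-cell median / IQR / SD of the percentage error of the
   estimated density.
2. *Capture-count* — surveys run until a target number of captures, with
   the elapsed time as survey duration; precision (coefficient of
   variation) as a function of the number of captures.
3. *Movement models* — stop-start and correlated-random-walk movement; the
   estimator is fed the realised average speed ``v * (1 - S)``, since the
   model's speed parameter is the average distance travelled per unit time
   during the survey.
4. *Parameter error* — surveys simulated with true parameters but estimated
   with a single parameter perturbed by a given relative error (the
   stochastic counterpart of :func:`grem.estimator.parameter_sensitivity`).

The canonical study grid is seven sensor widths
``2*pi * {1,2,3,4,5,7,9}/9`` by eleven signal widths ``pi * {1..11}/11``
with 100 replicates on a 7.5 km arena.  The default *desk scale* keeps the
density, duration and geometry (so expected captures per survey are
unchanged — the expected count ``p_bar * v * t * D`` does not involve the
arena size) but shrinks the arena to 1.5 km and uses 30 replicates on six
cells spanning the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimator import SurveyCounts, SurveyParams, estimate_density
from .geometry import SensorSpec, SignalSpec, classify_submodel, mean_profile_closed
from .simulator import MovementModel, SimConfig, SimulationTimeout, run_survey, run_until_captures

__all__ = [
    "ExperimentGrid",
    "PAPER_THETAS",
    "PAPER_ALPHAS",
    "DESK_CELLS",
    "CORNER_CELLS",
    "percent_error",
    "coefficient_of_variation",
    "submodel_accuracy_experiment",
    "capture_count_experiment",
    "movement_model_experiment",
    "parameter_error_experiment",
]

# canonical study grid: seven sensor widths, eleven signal widths
PAPER_THETAS = tuple(2.0 * math.pi * k / 9.0 for k in (1, 2, 3, 4, 5, 7, 9))
PAPER_ALPHAS = tuple(math.pi * k / 11.0 for k in range(1, 12))

# four corners of the tested grid, standing in for the "representative"
# submodels spanning the range of sensor and signal widths
CORNER_CELLS = (
    (PAPER_THETAS[0], PAPER_ALPHAS[0]),
    (PAPER_THETAS[0], PAPER_ALPHAS[-1]),
    (PAPER_THETAS[-1], PAPER_ALPHAS[0]),
    (PAPER_THETAS[-1], PAPER_ALPHAS[-1]),
)

# desk-scale cell selection: the four corners plus two interior cells
DESK_CELLS = CORNER_CELLS + (
    (PAPER_THETAS[3], PAPER_ALPHAS[5]),
    (PAPER_THETAS[5], PAPER_ALPHAS[2]),
)


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid of (theta, alpha) cells with replication and arena settings."""

    theta_values: tuple = PAPER_THETAS
    alpha_values: tuple = PAPER_ALPHAS
    replicates: int = 100
    arena_side: float = 7.5

    def __post_init__(self) -> None:
        for th in self.theta_values:
            SensorSpec(th, 0.01)
        for al in self.alpha_values:
            SignalSpec(al)
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    @property
    def cells(self):
        return tuple(
            (th, al) for th in self.theta_values for al in self.alpha_values
        )


def percent_error(estimate: float, truth: float) -> float:
    """Signed percentage error ``100 * (estimate - truth) / truth``."""
    if truth <= 0.0:
        raise ValueError("truth must be positive")
    return 100.0 * (estimate - truth) / truth


def coefficient_of_variation(values) -> float:
    """100 * sample standard deviation / mean.  Not shift-invariant: adding a
    constant to every value changes the CV (it is a relative dispersion)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    if m == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return 100.0 * v.std(ddof=1) / m


def _derive_seed(*keys) -> int:
    """Deterministic, order-independent sub-seed from integer keys."""
    ent = [int(k) & 0xFFFFFFFF for k in keys]
    return int(np.random.SeedSequence(ent).generate_state(1)[0] & 0x7FFFFFFF)


def _cell_key(theta: float, alpha: float):
    return int(round(theta * 1e9)), int(round(alpha * 1e9))


def _replicate_config(
    theta: float,
    alpha: float,
    movement: MovementModel,
    rep: int,
    seed: int,
    arena_side: float,
    base: SimConfig,
) -> SimConfig:
    tk, ak = _cell_key(theta, alpha)
    sub = _derive_seed(
        seed,
        tk,
        ak,
        int(round(movement.stationary_prob * 1e6)),
        int(round(movement.max_turn * 1e9)),
        rep,
    )
    return replace(
        base,
        arena_side=arena_side,
        sensor=SensorSpec(theta, base.sensor.r),
        signal=SignalSpec(alpha),
        movement=movement,
        seed=sub,
    )


def _estimate_from_result(res: SimConfig, z: float, t: float) -> float:
    cfg = res
    v_eff = cfg.speed * (1.0 - cfg.movement.stationary_prob)
    params = SurveyParams(v_eff, t, cfg.sensor, cfg.signal)
    return estimate_density(SurveyCounts(z), params).D_hat


def _summarise(reps: pd.DataFrame, by) -> pd.DataFrame:
    if reps.empty:
        cols = list(by) + [
            "median_pct_error", "iqr_pct_error", "sd_pct_error",
            "n_replicates", "mean_z",
        ]
        return pd.DataFrame(columns=cols)
    g = reps.groupby(list(by), sort=False)["pct_error"]
    out = g.agg(
        median_pct_error="median",
        iqr_pct_error=lambda s: s.quantile(0.75) - s.quantile(0.25),
        sd_pct_error=lambda s: s.std(ddof=1),
        n_replicates="count",
    ).reset_index()
    mean_z = reps.groupby(list(by), sort=False)["z"].mean().reset_index(name="mean_z")
    return out.merge(mean_z, on=list(by))


def submodel_accuracy_experiment(
    grid: ExperimentGrid,
    seed: int,
    cells=None,
    base_config: SimConfig | None = None,
):
    """Fixed-duration surveys per (theta, alpha) cell, estimated with the
    matching closed-form mean profile.

    Returns ``(summary, replicates)``: per-cell median / IQR / SD of the
    percentage density error and mean captures, plus the per-replicate
    table.  Cells whose mean profile is zero are skipped.
    """
    base = base_config or SimConfig()
    cells = tuple(cells) if cells is not None else grid.cells
    truth = base.density
    rows = []
    for theta, alpha in cells:
        if mean_profile_closed(SensorSpec(theta, base.sensor.r), SignalSpec(alpha)).p_bar <= 0.0:
            continue
        for rep in range(grid.replicates):
            cfg = _replicate_config(
                theta, alpha, MovementModel(), rep, seed, grid.arena_side, base
            )
            res = run_survey(cfg)
            d_hat = _estimate_from_result(cfg, res.z, res.t_total)
            rows.append(
                {
                    "theta": theta,
                    "alpha": alpha,
                    "region": classify_submodel(cfg.sensor, cfg.signal),
                    "replicate": rep,
                    "z": res.z,
                    "D_hat": d_hat,
                    "pct_error": percent_error(d_hat, truth),
                }
            )
    reps = pd.DataFrame(rows)
    return _summarise(reps, ("theta", "alpha", "region")), reps


def capture_count_experiment(
    representative_cells,
    targets,
    replicates: int,
    seed: int,
    arena_side: float = 1.5,
    base_config: SimConfig | None = None,
    max_steps: int = 2_000_000,
):
    """Run-until-capture surveys: for each cell and replicate the simulation
    runs until the largest target count, and every requested target is
    evaluated from the same run using the interpolated time of its z-th
    encounter.  Density is estimated with ``t`` equal to that elapsed time.

    Returns ``(summary, replicates_table)`` with the per-(cell, target) CV
    and median percentage error.  Cells that hit the step guard are flagged
    with ``timed_out`` and excluded from the summary.
    """
    targets = sorted(int(t) for t in targets)
    n_max = targets[-1]
    base = base_config or SimConfig()
    truth = base.density
    rows = []
    for theta, alpha in representative_cells:
        for rep in range(replicates):
            cfg = _replicate_config(
                theta, alpha, MovementModel(), rep, seed, arena_side, base
            )
            try:
                res = run_until_captures(cfg, n_max, max_steps=max_steps)
            except SimulationTimeout:
                rows.append(
                    {
                        "theta": theta,
                        "alpha": alpha,
                        "replicate": rep,
                        "n_target": n_max,
                        "t_elapsed": math.nan,
                        "D_hat": math.nan,
                        "pct_error": math.nan,
                        "timed_out": True,
                    }
                )
                continue
            times = res.encounters["time"].to_numpy()
            for n_t in targets:
                t_n = float(times[n_t - 1])
                if t_n <= 0.0:
                    continue
                d_hat = _estimate_from_result(cfg, n_t, t_n)
                rows.append(
                    {
                        "theta": theta,
                        "alpha": alpha,
                        "replicate": rep,
                        "n_target": n_t,
                        "t_elapsed": t_n,
                        "D_hat": d_hat,
                        "pct_error": percent_error(d_hat, truth),
                        "timed_out": False,
                    }
                )
    reps = pd.DataFrame(rows)
    ok = reps[~reps["timed_out"]]
    g = ok.groupby(["theta", "alpha", "n_target"], sort=False)
    summary = g.agg(
        cv_pct=("D_hat", lambda s: coefficient_of_variation(s)),
        median_pct_error=("pct_error", "median"),
        n_replicates=("D_hat", "count"),
    ).reset_index()
    return summary, reps


def movement_model_experiment(
    cells,
    movement_settings,
    replicates: int,
    seed: int,
    arena_side: float = 1.5,
    base_config: SimConfig | None = None,
):
    """Accuracy under stop-start and correlated-random-walk movement.

    ``movement_settings`` is an iterable of :class:`MovementModel`.  The
    estimator receives the realised average speed ``v * (1 - S)``: the
    encounter model's speed is the average distance covered per unit time,
    and an animal stationary for a fraction S of steps realises exactly that
    reduction.  Returns ``(summary, replicates_table)`` keyed by
    (theta, alpha, S, A).
    """
    base = base_config or SimConfig()
    truth = base.density
    rows = []
    for theta, alpha in cells:
        for mv in movement_settings:
            for rep in range(replicates):
                cfg = _replicate_config(theta, alpha, mv, rep, seed, arena_side, base)
                res = run_survey(cfg)
                d_hat = _estimate_from_result(cfg, res.z, res.t_total)
                rows.append(
                    {
                        "theta": theta,
                        "alpha": alpha,
                        "S": mv.stationary_prob,
                        "A": mv.max_turn,
                        "replicate": rep,
                        "z": res.z,
                        "D_hat": d_hat,
                        "pct_error": percent_error(d_hat, truth),
                    }
                )
    reps = pd.DataFrame(rows)
    return _summarise(reps, ("theta", "alpha", "S", "A")), reps


def parameter_error_experiment(
    cells,
    replicates: int,
    seed: int,
    errors=(-0.10, -0.05, 0.0, 0.05, 0.10),
    arena_side: float = 1.5,
    base_config: SimConfig | None = None,
):
    """Stochastic parameter-error study: simulate with true parameters,
    estimate with one parameter perturbed by each relative error.

    For error 0 every parameter row reproduces the accuracy experiment.
    Perturbed angles leaving ``[0, 2*pi]`` are clipped (flagged in the
    ``clipped`` column).  Returns ``(summary, replicates_table)`` keyed by
    (theta, alpha, parameter, rel_error).
    """
    from .geometry import TWO_PI

    base = base_config or SimConfig()
    truth = base.density
    rows = []
    for theta, alpha in cells:
        surveys = []
        for rep in range(replicates):
            cfg = _replicate_config(
                theta, alpha, MovementModel(), rep, seed, arena_side, base
            )
            res = run_survey(cfg)
            surveys.append((cfg, res))
        for name in ("alpha", "theta", "r", "v"):
            for e in errors:
                th_e, al_e, r_e, v_e = theta, alpha, base.sensor.r, base.speed
                clipped = False
                if name == "alpha":
                    al_e = alpha * (1.0 + e)
                    if al_e > TWO_PI:
                        al_e, clipped = TWO_PI, True
                elif name == "theta":
                    th_e = theta * (1.0 + e)
                    if th_e > TWO_PI:
                        th_e, clipped = TWO_PI, True
                elif name == "r":
                    r_e = r_e * (1.0 + e)
                elif name == "v":
                    v_e = v_e * (1.0 + e)
                params = SurveyParams(
                    v_e, base.t_total, SensorSpec(th_e, r_e), SignalSpec(al_e)
                )
                for rep, (cfg, res) in enumerate(surveys):
                    d_hat = estimate_density(SurveyCounts(res.z), params).D_hat
                    rows.append(
                        {
                            "theta": theta,
                            "alpha": alpha,
                            "parameter": name,
                            "rel_error": e,
                            "clipped": clipped,
                            "replicate": rep,
                            "z": res.z,
                            "D_hat": d_hat,
                            "pct_error": percent_error(d_hat, truth),
                        }
                    )
    reps = pd.DataFrame(rows)
    g = reps.groupby(["theta", "alpha", "parameter", "rel_error"], sort=False)
    summary = g.agg(
        median_pct_error=("pct_error", "median"),
        sd_pct_error=("pct_error", lambda s: s.std(ddof=1)),
        clipped=("clipped", "any"),
        n_replicates=("pct_error", "count"),
    ).reset_index()
    return summary, reps
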