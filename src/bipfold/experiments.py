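"""In-silico experiments: parameter sweeps, cooperativity and abundance
scans, the single-parameter correlation study, variance-based global
sensitivity analysis, and the translocation-flux scenario.

Every experiment returns a tidy :class:`pandas.DataFrame`.  Solver
failures on individual grid points are recorded per row (``failed``
column), not raised.  All stochastic components draw from a single seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import metrics as _metrics
from .dynamics import (
    CompiledSystem,
    IntegrationError,
    simulate_to_steady_state,
    simulate_with_influx,
)
from .network import ModelSpec, build_network
from .params import STUDY_PARAMETERS, ConfigurationError, ParameterSet
from .sobol import saltelli_sample, scale_loguniform, sobol_indices

log = logging.getLogger(__name__)

#: the seven (k, C) scenarios: four non-cooperative models plus the three
#: cooperative multi-site models (the single-site model has no multi-BiP
#: complex for C to act on).
DEFAULT_SCENARIOS: tuple[tuple[int, float], ...] = (
    (1, 1.0), (2, 1.0), (3, 1.0), (4, 1.0),
    (2, 10.0), (3, 10.0), (4, 10.0),
)

#: six-decade sweep ranges of the single-parameter correlation study
CORRELATION_RANGES: dict[str, tuple[float, float]] = {
    "k_on": (1e3, 1e8),
    "k_agg": (1e3, 1e8),
    "k_off": (1e-3, 1e2),
    "k_fold": (1e-3, 1e2),
    "k_unfold": (1e-3, 1e2),
    "k_misfold": (1e-3, 1e2),
    "k_seq": (1e-3, 1e2),
}

#: efficiency range below which a sweep response is considered flat and
#: its correlation reported as 0 (degenerate)
DEGENERATE_RANGE = 0.02


@dataclass(frozen=True)
class SweepDesign:
    """Log-spaced single-parameter sweep over a set of (k, C) scenarios."""

    parameter: str
    low: float
    high: float
    n_points: int = 13
    scenarios: tuple[tuple[int, float], ...] = DEFAULT_SCENARIOS
    base_params: ParameterSet = field(default_factory=ParameterSet)
    seed: int = 0
    tol: float = 1e-8
    t_max: float = 1e6

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ConfigurationError("sweep range must be positive, increasing")
        if self.n_points < 3:
            raise ConfigurationError("sweep needs at least 3 grid points")
        if self.parameter not in ParameterSet.__dataclass_fields__:
            raise ConfigurationError(f"unknown parameter {self.parameter!r}")

    @property
    def grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.low), np.log10(self.high), self.n_points)


@dataclass(frozen=True)
class SensitivityDesign:
    """Saltelli design over the seven study parameters, log-uniform over
    one decade either side of the default."""

    n_samples: int = 1024
    parameters: tuple[str, ...] = STUDY_PARAMETERS
    span: float = 10.0
    scenarios: tuple[tuple[int, float], ...] = DEFAULT_SCENARIOS
    base_params: ParameterSet = field(default_factory=ParameterSet)
    seed: int = 0
    metric: str = "folding_efficiency"

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ConfigurationError("sensitivity design needs >= 8 samples")
        if self.span <= 1.0:
            raise ConfigurationError("span must exceed 1")


def _run_point(
    spec: ModelSpec, tol: float, t_max: float,
) -> tuple[_metrics.MetricsResult | None, bool, str]:
    try:
        net = build_network(spec)
        traj = simulate_to_steady_state(net, tol=tol, t_max=t_max)
        return _metrics.evaluate(traj, spec.params.u0), traj.steady_state_reached, ""
    except (IntegrationError, ConfigurationError) as exc:
        log.warning("solver failure for %s: %s", spec, exc)
        return None, False, str(exc)


def _row(k: int, C: float, result, steady: bool, err: str, **extra) -> dict:
    row = {"k": k, "C": C, **extra}
    if result is None:
        row.update(
            folding_efficiency=np.nan, chaperone_cost=np.nan,
            coverage=np.nan, failed=True, error=err, steady_state=False,
        )
    else:
        row.update(
            **result.to_dict(), failed=False, error="", steady_state=steady,
        )
    return row


def run_rate_sweep(design: SweepDesign) -> pd.DataFrame:
    """Steady-state metrics along a log grid of one rate constant."""
    rows = []
    for (k, C), value in itertools.product(design.scenarios, design.grid):
        params = design.base_params.replace(**{design.parameter: value})
        spec = ModelSpec(k=k, C=C, params=params)
        result, steady, err = _run_point(spec, design.tol, design.t_max)
        rows.append(
            _row(k, C, result, steady, err,
                 parameter=design.parameter, value=value)
        )
    return pd.DataFrame(rows)


def run_cooperativity_scan(
    c_grid,
    models: tuple[int, ...] = (1, 2, 3, 4),
    base_params: ParameterSet | None = None,
    tol: float = 1e-8,
    t_max: float = 1e6,
) -> pd.DataFrame:
    """Efficiency per (k, C) over a cooperativity grid within [1, 100]."""
    c_grid = np.asarray(list(c_grid), dtype=float)
    if (c_grid < 1.0).any() or (c_grid > 100.0).any():
        raise ConfigurationError("C grid must lie within [1, 100]")
    params = base_params or ParameterSet()
    rows = []
    for k, C in itertools.product(models, c_grid):
        spec = ModelSpec(k=k, C=C, params=params)
        result, steady, err = _run_point(spec, tol, t_max)
        rows.append(_row(k, C, result, steady, err))
    return pd.DataFrame(rows)


def argmax_model(table: pd.DataFrame, C: float) -> int:
    """Model k with the highest folding efficiency at cooperativity C."""
    sub = table[(table["C"] == C) & ~table["failed"]]
    best = sub.loc[sub["folding_efficiency"].idxmax()]
    return int(best["k"])


def run_abundance_scan(
    bip_grid,
    u_grid,
    models: tuple[int, ...] = (1, 2, 3, 4),
    C: float = 1.0,
    base_params: ParameterSet | None = None,
    tol: float = 1e-8,
    t_max: float = 1e6,
) -> pd.DataFrame:
    """Metrics over a grid of total BiP and initial unfolded copy numbers."""
    params = base_params or ParameterSet()
    rows = []
    for k, bip, u in itertools.product(models, bip_grid, u_grid):
        spec = ModelSpec(k=k, C=C, params=params.replace(bip_total=bip, u0=u))
        result, steady, err = _run_point(spec, tol, t_max)
        rows.append(
            _row(k, C, result, steady, err,
                 bip_total=bip, u_total=u, bip_u_ratio=bip / u)
        )
    return pd.DataFrame(rows)


def run_cost_comparison(
    models: tuple[int, ...] = (1, 2, 3, 4),
    C: float = 10.0,
    base_params: ParameterSet | None = None,
    horizon: float | None = None,
    tol: float = 1e-8,
    t_max: float = 1e6,
) -> pd.DataFrame:
    """Chaperone cost of the non-cooperative single-site model against the
    cooperative multi-site models, on a common integration horizon."""
    params = base_params or ParameterSet()
    scenarios = [(k, 1.0 if k == 1 else C) for k in models]
    trajectories = {}
    for k, c in scenarios:
        spec = ModelSpec(k=k, C=c, params=params)
        trajectories[(k, c)] = simulate_to_steady_state(
            build_network(spec), tol=tol, t_max=t_max
        )
    common = horizon or max(tr.times[-1] for tr in trajectories.values())
    rows = []
    for k, c in scenarios:
        spec = ModelSpec(k=k, C=c, params=params)
        net = build_network(spec)
        # integrate every model over the same horizon so the time averages
        # are comparable (tol=1e-300 disables early truncation)
        traj = simulate_to_steady_state(net, tol=1e-300, t_max=common)
        rows.append(
            {
                "k": k, "C": c,
                "chaperone_cost": _metrics.chaperone_cost(traj),
                "chaperone_cost_end": _metrics.chaperone_cost(traj, end_state=True),
                "folding_efficiency": _metrics.folding_efficiency(traj, params.u0),
                "horizon": common,
            }
        )
    return pd.DataFrame(rows)


def run_correlation_study(
    base_params: ParameterSet | None = None,
    parameters: tuple[str, ...] = STUDY_PARAMETERS,
    scenarios: tuple[tuple[int, float], ...] = DEFAULT_SCENARIOS,
    n_points: int = 13,
    tol: float = 1e-8,
    t_max: float = 1e6,
) -> pd.DataFrame:
    """Single-parameter six-decade sweeps -> correlation heat-map table.

    Pearson is computed on log10(parameter) vs raw efficiency; Spearman is
    reported alongside.  A response whose total range is below
    ``DEGENERATE_RANGE`` carries no information about the parameter, so its
    correlation is reported as 0 with the ``degenerate`` flag set.
    """
    params = base_params or ParameterSet()
    rows = []
    for pname in parameters:
        low, high = CORRELATION_RANGES[pname]
        design = SweepDesign(
            parameter=pname, low=low, high=high, n_points=n_points,
            scenarios=scenarios, base_params=params, tol=tol, t_max=t_max,
        )
        table = run_rate_sweep(design)
        for (k, C) in scenarios:
            sub = table[(table["k"] == k) & (table["C"] == C) & ~table["failed"]]
            effs = sub["folding_efficiency"].to_numpy()
            grid = np.log10(sub["value"].to_numpy())
            resp_range = float(effs.max() - effs.min()) if len(effs) else 0.0
            degenerate = resp_range < DEGENERATE_RANGE
            if degenerate or len(effs) < 3:
                r_p, r_s = 0.0, 0.0
            else:
                r_p = float(pearsonr(grid, effs)[0])
                r_s = float(spearmanr(grid, effs)[0])
            rows.append(
                {
                    "parameter": pname, "k": k, "C": C,
                    "pearson_log": r_p, "spearman": r_s,
                    "response_range": resp_range, "degenerate": degenerate,
                    "n_ok": len(effs),
                }
            )
    return pd.DataFrame(rows)


def run_global_sensitivity(design: SensitivityDesign) -> pd.DataFrame:
    """First/total-order Sobol indices per parameter per (k, C) scenario.

    Parameters are sampled log-uniformly over [default/span, default*span]
    (span 10 -> two orders of magnitude overall).  Reduced sample counts
    are supported; bootstrap 95% intervals quantify estimator noise.
    """
    base = design.base_params
    d = len(design.parameters)
    sample = saltelli_sample(design.n_samples, d, design.seed)
    defaults = np.array([getattr(base, p) for p in design.parameters])
    low, high = defaults / design.span, defaults * design.span
    values = scale_loguniform(sample.points, low, high)

    rows = []
    for (k, C) in design.scenarios:
        outputs = np.empty(len(values))
        for i, vec in enumerate(values):
            params = base.replace(**dict(zip(design.parameters, vec)))
            spec = ModelSpec(k=k, C=C, params=params)
            result, _, _ = _run_point(spec, tol=1e-8, t_max=1e6)
            outputs[i] = (
                np.nan if result is None else getattr(result, design.metric)
            )
        ok = np.isfinite(outputs)
        if not ok.all():
            # impute failures with the mean to keep the estimator usable
            outputs[~ok] = outputs[ok].mean()
            log.warning("%d solver failures imputed in GSA", (~ok).sum())
        idx = sobol_indices(
            outputs, design.n_samples, d, seed=design.seed + 1
        )
        for j, pname in enumerate(design.parameters):
            rows.append(
                {
                    "k": k, "C": C, "parameter": pname,
                    "metric": design.metric,
                    "S1": idx.first_order[j], "ST": idx.total_order[j],
                    "S1_lo": idx.first_order_ci[j, 0],
                    "S1_hi": idx.first_order_ci[j, 1],
                    "ST_lo": idx.total_order_ci[j, 0],
                    "ST_hi": idx.total_order_ci[j, 1],
                    "output_variance": float(np.var(outputs[: 2 * design.n_samples])),
                    "output_mean": float(np.mean(outputs[: 2 * design.n_samples])),
                }
            )
    return pd.DataFrame(rows)


DEFAULT_FLUX_GRID = (10.0, 1e2, 1e3, 1e4, 1e5)


def run_translocation_scenario(
    flux_grid=DEFAULT_FLUX_GRID,
    scenarios: tuple[tuple[int, float], ...] = DEFAULT_SCENARIOS,
    duration: float = 100.0,
    horizon: float = 1000.0,
    base_params: ParameterSet | None = None,
) -> pd.DataFrame:
    """Folding efficiency under a 100 s translocation burst of nascent
    protein at each printed flux, starting from the standard luminal pool.

    The metric is evaluated at a fixed horizon (default 1000 s): at high
    flux the limited pore capacity leaves a backlog of untranslocated
    nascent protein at the membrane, which counts against efficiency.
    """
    params = base_params or ParameterSet()
    flux_grid = np.asarray(list(flux_grid), dtype=float)
    if (flux_grid <= 0).any():
        raise ConfigurationError("flux grid must be positive")
    if horizon <= duration:
        raise ConfigurationError("horizon must exceed the influx duration")
    rows = []
    for (k, C), flux in itertools.product(scenarios, flux_grid):
        spec = ModelSpec(k=k, C=C, params=params)
        try:
            net = build_network(spec)
            # tol=1e-300 disables early truncation: every run is evaluated
            # at exactly t = horizon
            traj = simulate_with_influx(
                net, influx_rate=flux, duration=duration,
                tol=1e-300, t_max=horizon - duration,
            )
            eff = _metrics.folding_efficiency(traj, params.u0)
            rows.append(
                {
                    "k": k, "C": C, "flux": flux, "duration": duration,
                    "folding_efficiency": eff,
                    "chaperone_cost": _metrics.chaperone_cost(traj),
                    "failed": False, "error": "",
                    "steady_state": traj.steady_state_reached,
                }
            )
        except (IntegrationError, ConfigurationError) as exc:
            rows.append(
                {
                    "k": k, "C": C, "flux": flux, "duration": duration,
                    "folding_efficiency": np.nan, "chaperone_cost": np.nan,
                    "failed": True, "error": str(exc), "steady_state": False,
                }
            )
    return pd.DataFrame(rows)


def translocation_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario flux-efficiency correlations (raw and log flux)."""
    rows = []
    for (k, C), sub in table[~table["failed"]].groupby(["k", "C"]):
        eff = sub["folding_efficiency"].to_numpy()
        flux = sub["flux"].to_numpy()
        rows.append(
            {
                "k": k, "C": C,
                "pearson_raw": float(pearsonr(flux, eff)[0]),
                "pearson_log": float(pearsonr(np.log10(flux), eff)[0]),
                "spearman": float(spearmanr(flux, eff)[0]),
            }
        )
    return pd.DataFrame(rows)
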