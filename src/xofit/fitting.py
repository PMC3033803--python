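"""Parameter search and confidence intervals.

The two-dimensional space (interference strength, P2 proportion ``p``) is
searched either by an exhaustive grid scan -- slow but immune to local
maxima, and yielding the full objective surface -- or by hill climbing:
evaluate the 8 neighbours at the current step sizes, move to the best
strictly-improving one, halve both steps when no neighbour improves, stop
once both steps drop below the requested precision.

Confidence intervals come from the observed Fisher information (numerical
Hessian of the log-likelihood; gamma family only) or from parametric
resimulation: refit datasets simulated at the fitted parameters and take
percentile intervals of the refitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import defaults
from .beam_film import calibrate_stress
from .io_data import BivalentDataset, GameteDataset
from .likelihood import dataset_loglik
from .models import ModelSpec
from .renewal import GammaSprinklingParams
from .score import (
    HistogramBins,
    ScoreSettings,
    build_histograms,
    model_histograms,
    projected_likelihood_score,
)
from .synthetic import genotype_gametes, simulate_gamma_bivalents, thin_to_gametes
from .beam_film import simulate_bfs_population

__all__ = [
    "FitSettings",
    "FitResult",
    "grid_scan",
    "hill_climb",
    "fit_model",
    "make_objective",
    "fisher_ci",
    "resim_ci",
]


@dataclass(frozen=True)
class FitSettings:
    """Search configuration.

    ``x1`` refers to parameter 1 (``nu`` or ``d``), ``p`` to parameter 2.
    ``x1_step`` / ``p_step`` are the scan grid steps and the initial hill
    steps; ``precision`` values are the per-parameter stop thresholds of
    the hill climber.
    """

    algorithm: str = "hill"  # hill | scan
    x1_range: tuple[float, float] = (defaults.NU_MIN, 20.0)
    p_range: tuple[float, float] = (0.0, 1.0)
    x1_step: float = 0.5
    p_step: float = 0.05
    start: tuple[float, float] | None = None
    x1_precision: float = 0.01
    p_precision: float = 0.005
    fix_p: bool = False
    objective: str = "loglik"  # loglik | score
    n_boot: int = 100
    seed: int = 0
    max_evaluations: int = 10**4
    grid_step: float | None = None  # likelihood quadrature resolution

    def __post_init__(self) -> None:
        if self.algorithm not in ("hill", "scan"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.objective not in ("loglik", "score"):
            raise ValueError(f"unknown objective {self.objective!r}")
        for lo, hi in (self.x1_range, self.p_range):
            if hi < lo:
                raise ValueError("ranges must be ordered")
        if self.x1_step <= 0 or self.p_step <= 0:
            raise ValueError("steps must be positive")
        if self.x1_precision <= 0 or self.p_precision <= 0:
            raise ValueError("precision must be positive")


@dataclass
class FitResult:
    """Best parameters and the search record."""

    x1: float
    p: float
    value: float
    evaluations: int
    algorithm: str
    surface: pd.DataFrame | None = None
    trajectory: pd.DataFrame | None = None
    ci: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "interference": self.x1,
            "p": self.p,
            "objective_value": self.value,
            "evaluations": self.evaluations,
            "algorithm": self.algorithm,
        }
        if self.ci is not None:
            out["ci"] = self.ci
        return out


class _CachedObjective:
    def __init__(self, fn, budget: int):
        self.fn = fn
        self.budget = budget
        self.cache: dict[tuple[float, float], float] = {}

    def __call__(self, x1: float, p: float) -> float:
        key = (round(float(x1), 10), round(float(p), 10))
        if key not in self.cache:
            if len(self.cache) >= self.budget:
                raise RuntimeError(
                    f"evaluation budget ({self.budget}) exhausted"
                )
            self.cache[key] = float(self.fn(*key))
        return self.cache[key]


def grid_scan(objective, settings: FitSettings) -> FitResult:
    """Evaluate every node of the parameter grid; return argmax + surface.

    Halving both steps quadruples the node count (and hence the runtime);
    the full surface is kept for export and 3-D inspection.
    """
    lo1, hi1 = settings.x1_range
    x1s = np.arange(lo1, hi1 + settings.x1_step / 2, settings.x1_step)
    if settings.fix_p:
        ps = np.array([settings.p_range[0]])
    else:
        lop, hip = settings.p_range
        ps = np.arange(lop, hip + settings.p_step / 2, settings.p_step)
    n_nodes = x1s.size * ps.size
    if n_nodes > settings.max_evaluations:
        raise ValueError(
            f"grid has {n_nodes} nodes, over the budget of "
            f"{settings.max_evaluations}; coarsen the steps or use "
            "algorithm='hill'"
        )
    obj = _CachedObjective(objective, settings.max_evaluations)
    rows = []
    for x1 in x1s:
        for p in ps:
            rows.append((float(x1), float(p), obj(x1, p)))
    surface = pd.DataFrame(rows, columns=["x1", "p", "objective"])
    best = surface.loc[surface["objective"].idxmax()]
    return FitResult(
        x1=float(best["x1"]),
        p=float(best["p"]),
        value=float(best["objective"]),
        evaluations=len(obj.cache),
        algorithm="scan",
        surface=surface,
    )


_NEIGHBOURS = [
    (-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)
]


def hill_climb(objective, settings: FitSettings) -> FitResult:
    """Hill climbing with step halving.

    From the start point, repeatedly move to the best strictly-improving
    of the 8 neighbours at the current step sizes (clipped to the bounds);
    when none improves, halve both steps; stop when both steps are below
    the precision thresholds.  Deterministic: ties break on the fixed
    neighbour order.
    """
    lo1, hi1 = settings.x1_range
    lop, hip = settings.p_range
    if settings.start is not None:
        x1, p = settings.start
    else:
        x1 = 0.5 * (lo1 + hi1)
        p = lop if settings.fix_p else 0.5 * (lop + hip)
    if not (lo1 <= x1 <= hi1) or not (lop <= p <= hip):
        raise ValueError("start point outside bounds")
    obj = _CachedObjective(objective, settings.max_evaluations)
    s1, sp = settings.x1_step, settings.p_step
    value = obj(x1, p)
    traj = [(x1, p, value)]
    while s1 >= settings.x1_precision or sp >= settings.p_precision:
        best = None
        for d1, dp in _NEIGHBOURS:
            if settings.fix_p and dp != 0:
                continue
            c1 = float(np.clip(x1 + d1 * s1, lo1, hi1))
            cp = float(np.clip(p + dp * sp, lop, hip))
            if (c1, cp) == (x1, p):
                continue
            v = obj(c1, cp)
            if v > value and (best is None or v > best[2]):
                best = (c1, cp, v)
        if best is None:
            s1 *= 0.5
            sp *= 0.5
        else:
            x1, p, value = best
            traj.append(best)
    trajectory = pd.DataFrame(traj, columns=["x1", "p", "objective"])
    return FitResult(
        x1=x1,
        p=p,
        value=value,
        evaluations=len(obj.cache),
        algorithm="hill",
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def make_objective(
    family: str,
    data,
    settings: FitSettings,
    score_settings: ScoreSettings | None = None,
    bins: HistogramBins = HistogramBins(),
    n_precursors: float = 10.0,
):
    """Objective function ``(x1, p) -> value`` for a model family.

    Gamma-family fits use the exact log-likelihood unless the score is
    requested; beam-film fits always use the projected-likelihood score
    (no likelihood exists).  Score evaluations reuse one master seed per
    fit (common random numbers), which smooths the surface seen by the
    hill climber; beam-film evaluations recalibrate the terminal stress at
    every parameter point.
    """
    two_pathway = family in ("gs", "bfs")
    if family in ("gamma", "gs") and settings.objective == "loglik":
        def objective(x1: float, p: float) -> float:
            params = GammaSprinklingParams(
                nu=x1, p=p if two_pathway else 0.0
            )
            return dataset_loglik(data, params, grid_step=_fit_grid_step(data, settings))
        return objective
    if score_settings is None:
        score_settings = ScoreSettings(seed=settings.seed)
    obs = build_histograms(data, bins=bins)
    if isinstance(data, BivalentDataset):
        target_mean = float(np.mean(data.counts()))
    else:
        target_mean = None  # gamete design: intensity fixed by the map

    def objective(x1: float, p: float) -> float:
        model = ModelSpec(
            family, x1, p if two_pathway else 0.0, n_precursors=n_precursors
        )
        if not model.is_gamma:
            tgt = target_mean if target_mean is not None else 2.0 * obs.L
            s_max = calibrate_stress(
                _bf_uncal(model),
                tgt,
                np.random.default_rng(score_settings.seed),
            )
            model = replace(model, s_max=s_max)
        sim = model_histograms(model, data, score_settings, bins=bins)
        return projected_likelihood_score(obs, sim, score_settings).score

    return objective


def _bf_uncal(model: ModelSpec):
    from .beam_film import BeamFilmParams

    return BeamFilmParams(
        d=model.interference,
        p=model.p,
        n_precursors=model.n_precursors,
        s_max=1.0,
    )


def _fit_grid_step(data, settings: FitSettings) -> float | None:
    if settings.grid_step is not None:
        return settings.grid_step
    if isinstance(data, GameteDataset) and data.map is not None:
        return data.map.span / defaults.FIT_GRID_CELLS
    return None


def fit_model(family: str, data, settings: FitSettings, **kwargs) -> FitResult:
    """Fit one model family to a dataset with the configured search."""
    if family in ("gamma", "bf"):
        settings = replace(settings, fix_p=True, p_range=(0.0, settings.p_range[1]))
    if family in ("bf", "bfs") and settings.objective == "loglik":
        settings = replace(settings, objective="score")
    objective = make_objective(family, data, settings, **kwargs)
    if settings.algorithm == "scan":
        return grid_scan(objective, settings)
    return hill_climb(objective, settings)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def fisher_ci(
    loglik_fn,
    theta_hat,
    bounds=None,
    alpha: float = 0.05,
) -> dict:
    """95% Wald intervals from the observed Fisher information.

    The Hessian of ``loglik_fn`` at ``theta_hat`` is computed by central
    differences (step ``max(1e-3 |theta|, 1e-4)``); the intervals are
    ``theta_j +/- z * sqrt((-H)^-1_jj)``.  A parameter sitting on a bound
    gets a one-sided interval (curvature from one-sided differences); if
    the negated Hessian is not positive definite no interval is reported
    and the result is flagged.
    """
    theta = np.asarray(theta_hat, dtype=float)
    k = theta.size
    if bounds is None:
        bounds = [(-np.inf, np.inf)] * k
    h = np.maximum(1e-3 * np.abs(theta), 1e-4)
    on_lower = np.array([abs(t - b[0]) <= 1e-12 for t, b in zip(theta, bounds)])
    on_upper = np.array([abs(t - b[1]) <= 1e-12 for t, b in zip(theta, bounds)])

    def f(dvec):
        return float(loglik_fn(theta + dvec))

    H = np.empty((k, k))
    f0 = f(np.zeros(k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        if on_lower[i] or on_upper[i]:
            s = 1.0 if on_lower[i] else -1.0
            H[i, i] = (f(2 * s * ei) - 2 * f(s * ei) + f0) / h[i] ** 2
        else:
            H[i, i] = (f(ei) - 2 * f0 + f(-ei)) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ei[i] = h[i]
            ej = np.zeros(k)
            ej[j] = h[j]
            si = 1.0 if on_lower[i] else (-1.0 if on_upper[i] else 0.0)
            sj = 1.0 if on_lower[j] else (-1.0 if on_upper[j] else 0.0)
            if si == 0.0 and sj == 0.0:
                H[i, j] = (
                    f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
                ) / (4 * h[i] * h[j])
            else:
                # one-sided cross difference away from the bound
                bi = si if si != 0.0 else 1.0
                bj = sj if sj != 0.0 else 1.0
                H[i, j] = (
                    f(bi * ei + bj * ej) - f(bi * ei) - f(bj * ej) + f0
                ) / (bi * bj * h[i] * h[j])
            H[j, i] = H[i, j]
    info = -H
    try:
        np.linalg.cholesky(info)
        cov = np.linalg.inv(info)
        pd_ok = True
    except np.linalg.LinAlgError:
        cov = None
        pd_ok = False
    from scipy import stats as _st

    z = _st.norm.ppf(1 - alpha / 2)
    out: dict = {"method": "fisher", "positive_definite": pd_ok, "params": []}
    for i in range(k):
        entry: dict = {"estimate": float(theta[i])}
        if not pd_ok:
            entry["ci"] = None
            entry["flag"] = "information matrix not positive definite"
        else:
            se = float(np.sqrt(cov[i, i]))
            lo = theta[i] - z * se
            hi = theta[i] + z * se
            if on_lower[i]:
                entry["ci"] = [float(bounds[i][0]), float(hi)]
                entry["flag"] = "one-sided (estimate on lower bound)"
            elif on_upper[i]:
                entry["ci"] = [float(lo), float(bounds[i][1])]
                entry["flag"] = "one-sided (estimate on upper bound)"
            else:
                entry["ci"] = [float(lo), float(hi)]
        out["params"].append(entry)
    return out


def _simulate_like(model: ModelSpec, design, rng: np.random.Generator):
    """Simulate one dataset matching the observed design at ``model``."""
    if isinstance(design, BivalentDataset):
        L = design.frame.length_morgans
        n = design.n_cells
        if model.is_gamma:
            return simulate_gamma_bivalents(model.gamma_params(), L, n, rng)
        return simulate_bfs_population(model.bf_params(), n, L, rng)
    gmap = design.require_map()
    L = gmap.span
    n = design.n_gametes
    if model.is_gamma:
        biv = simulate_gamma_bivalents(model.gamma_params(), L, n, rng)
    else:
        biv = simulate_bfs_population(model.bf_params(), n, L, rng)
    gametes = thin_to_gametes(biv, rng)
    gd = genotype_gametes(gametes, gmap, 0.0, rng)
    obs_mask = design.genotypes.isna().to_numpy()
    if obs_mask.any():
        vals = gd.genotypes.to_numpy(dtype=object)
        vals[obs_mask] = np.nan
        gd = GameteDataset(
            pd.DataFrame(
                vals, index=gd.genotypes.index, columns=gd.genotypes.columns
            ),
            gmap,
        )
    return gd


def resim_ci(
    model: ModelSpec,
    design,
    settings: FitSettings,
    alpha: float = 0.05,
) -> dict:
    """Percentile CIs from refits of datasets resimulated at the estimate.

    ``n_boot`` datasets with the same record count, marker map and missing
    pattern as the observed design are simulated at the fitted parameters
    and refitted by hill climbing (warm-started at the estimate); the
    2.5/97.5 percentiles of the refitted parameters are the intervals.
    """
    if settings.n_boot < 20:
        raise ValueError("n_boot must be at least 20")
    rng = np.random.default_rng(settings.seed)
    # warm start at the estimate with steps on the scale of the expected
    # sampling spread, so each refit converges in a handful of rounds
    refit_settings = replace(
        settings,
        algorithm="hill",
        start=(model.interference, model.p),
        x1_step=max(8 * settings.x1_precision, settings.x1_step / 8),
        p_step=max(8 * settings.p_precision, settings.p_step / 8),
    )
    x1s, ps = [], []
    failures = 0
    for b in range(settings.n_boot):
        sim = _simulate_like(model, design, rng)
        try:
            res = fit_model(model.family, sim, refit_settings)
            x1s.append(res.x1)
            ps.append(res.p)
        except Exception as exc:  # refit failure recorded, not fatal
            failures += 1
            warnings.warn(f"resimulation refit {b} failed: {exc}", stacklevel=2)
    if failures > 0.1 * settings.n_boot:
        raise RuntimeError(
            f"{failures}/{settings.n_boot} resimulation refits failed"
        )
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    x1_lo, x1_hi = np.percentile(x1s, qs)
    out = {
        "method": "resimulation",
        "n_boot": settings.n_boot,
        "failures": failures,
        "params": [
            {
                "estimate": model.interference,
                "ci": [float(x1_lo), float(x1_hi)],
            }
        ],
    }
    if model.two_pathway:
        p_lo, p_hi = np.percentile(ps, qs)
        out["params"].append(
            {"estimate": model.p, "ci": [float(p_lo), float(p_hi)]}
        )
    return out
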