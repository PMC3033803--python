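"""Beam-film model: crossovers as stress-relieving cracks.

A mechanical analogy for interference: precursor sites on the chromosome
carry random critical thresholds; a rising global stress cracks precursors
one by one (each crack designating a crossover), and every crack relieves
stress in its neighbourhood through an exponential kernel
``exp(-|x - x_c| / d)``, pushing nearby precursors' effective stress down
and thereby suppressing close crossovers.  ``d`` is the interference
distance ("parameter 1"); ``d -> 0`` removes interference and ``d`` much
larger than the chromosome allows at most one crack.

No likelihood is available for this model; fits use the projected-
likelihood score of :mod:`xofit.score`.  Sprinkling (BFS) superposes a
Poisson pathway P2 exactly as in the gamma-sprinkling model.

This is a deliberately minimal, seedable variant of beam-film mechanics
(uniform precursors, uniform thresholds, quasi-static cracking order,
exponential relief) exposing a single interference parameter; it does not
reproduce the full ceramic-film elasticity treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import defaults
from .io_data import BivalentDataset, ChromosomeFrame

__all__ = [
    "BeamFilmParams",
    "simulate_bf_bivalent",
    "simulate_bf_population",
    "calibrate_stress",
    "simulate_bfs_population",
]


@dataclass(frozen=True)
class BeamFilmParams:
    """Beam-film parameters.

    ``d`` is the stress-relief distance in relative chromosome units
    (chromosome = ``[0, 1]``); ``p`` the P2 sprinkling proportion;
    ``n_precursors`` the mean precursor count per bivalent; ``s_max`` the
    terminal global stress, normally set by :func:`calibrate_stress` so the
    mean crossover count matches the data (it is not fitted directly).
    """

    d: float
    p: float = 0.0
    n_precursors: float = 10.0
    s_max: float = 1.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("relief distance d must be positive")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.n_precursors <= 0:
            raise ValueError("n_precursors must be positive")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")


def simulate_bf_bivalent(
    params: BeamFilmParams, rng: np.random.Generator
) -> np.ndarray:
    """Crack (P1 crossover) positions of one bivalent, sorted, in [0, 1].

    Precursors are Poisson(``n_precursors``) uniform with thresholds
    uniform on (0, 1); the global stress rises quasi-statically to
    ``s_max``, always cracking the precursor that needs the smallest
    stress under the current relief field
    ``sigma_eff(x) = sigma * max(0, 1 - sum_cracks exp(-|x-x_c|/d))``.
    """
    n = rng.poisson(params.n_precursors)
    x = rng.random(n)
    beta = rng.random(n)
    pos = _crack(x, beta, params.d, params.s_max)
    return np.sort(pos)


def _crack(x: np.ndarray, beta: np.ndarray, d: float, s_max: float) -> np.ndarray:
    relief = np.ones_like(x)
    uncracked = np.ones(x.size, dtype=bool)
    cracked: list[float] = []
    while True:
        with np.errstate(divide="ignore"):
            required = np.where(
                uncracked & (relief > 0.0), beta / np.maximum(relief, 1e-300),
                np.inf,
            )
        i = int(np.argmin(required)) if required.size else 0
        if not required.size or required[i] > s_max:
            break
        uncracked[i] = False
        cracked.append(float(x[i]))
        relief = relief - np.exp(-np.abs(x - x[i]) / d)
        relief = np.maximum(relief, 0.0)
    return np.asarray(cracked)


def simulate_bf_population(
    params: BeamFilmParams, n_cells: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """P1 crack lists for ``n_cells`` bivalents (relative units [0, 1]).

    Vectorized across cells: each quasi-static round cracks at most one
    precursor per cell simultaneously, which is equivalent to per-cell
    sequential cracking because cells are independent.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    counts = rng.poisson(params.n_precursors, size=n_cells)
    P = int(counts.max()) if n_cells else 0
    if P == 0:
        return [np.empty(0) for _ in range(n_cells)]
    x = rng.random((n_cells, P))
    beta = rng.random((n_cells, P))
    exists = np.arange(P)[None, :] < counts[:, None]
    relief = np.where(exists, 1.0, 0.0)
    uncracked = exists.copy()
    is_cracked = np.zeros_like(exists)
    while True:
        ok = uncracked & (relief > 0.0)
        required = np.where(ok, beta / np.maximum(relief, 1e-300), np.inf)
        i_min = np.argmin(required, axis=1)
        rows = np.arange(n_cells)
        can = required[rows, i_min] <= params.s_max
        if not np.any(can):
            break
        r = rows[can]
        c = i_min[can]
        uncracked[r, c] = False
        is_cracked[r, c] = True
        dx = np.abs(x[r] - x[r, c][:, None]) / params.d
        relief[r] = np.maximum(relief[r] - np.exp(-dx), 0.0)
    return [np.sort(x[i][is_cracked[i]]) for i in range(n_cells)]


def calibrate_stress(
    params: BeamFilmParams,
    target_mean: float,
    rng: np.random.Generator,
    n_cal: int = 20000,
    tol: float = 0.02,
) -> float:
    """Find ``s_max`` whose mean P1 crack count matches the data.

    Genetic space fixes the total intensity at 2 crossovers per Morgan on
    the bivalent, so the beam-film output must be scaled to the observed
    mean count: bisection on ``s_max`` against simulated means (common
    random numbers across iterations) until the P1 target
    ``target_mean * (1 - p)`` is met within ``tol``.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    if n_cal < 2 * 10**4:
        raise ValueError("n_cal must be at least 2e4 for a stable mean")
    p1_target = target_mean * (1.0 - params.p)
    if p1_target > params.n_precursors:
        raise ValueError(
            f"target P1 mean {p1_target:.3g} exceeds the precursor supply "
            f"{params.n_precursors:.3g}"
        )
    if p1_target == 0.0:
        return params.s_max
    seed = int(rng.integers(0, 2**31 - 1))

    def mean_at(s: float) -> float:
        pars = replace(params, s_max=s)
        cells = simulate_bf_population(
            pars, n_cal, np.random.default_rng(seed)
        )
        return float(np.mean([c.size for c in cells]))

    lo, hi = 1e-3, 4.0
    while mean_at(hi) < p1_target:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(
                "target mean unreachable: interference saturates the crack "
                "count below the target; increase n_precursors or lower d"
            )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - p1_target) <= tol:
            return mid
        if m < p1_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_bfs_population(
    params: BeamFilmParams,
    n_cells: int,
    L: float,
    rng: np.random.Generator,
) -> BivalentDataset:
    """Beam-film-sprinkling bivalents on ``[0, L]`` Morgans.

    P1 cracks (relative units) are scaled to ``[0, L]`` and united with a
    Poisson(``2pL``) set of uniform P2 positions.  ``s_max`` should have
    been calibrated so the total mean count is ``2L``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if L <= 0:
        raise ValueError("L must be positive")
    if params.p < 1.0:
        cells = [L * c for c in simulate_bf_population(params, n_cells, rng)]
    else:
        cells = [np.empty(0) for _ in range(n_cells)]
    if params.p > 0.0:
        lam2 = defaults.BIVALENT_INTENSITY * params.p
        k2 = rng.poisson(lam2 * L, size=n_cells)
        cells = [
            np.sort(np.concatenate([c, L * rng.random(k)])) if k else c
            for c, k in zip(cells, k2)
        ]
    return BivalentDataset(cells, ChromosomeFrame(L, "morgan"))
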