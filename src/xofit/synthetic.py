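"""Synthetic crossover data with the statistical structure the models assume.

Generates bivalent crossover position sets from the gamma / gamma-sprinkling
model, thins them to gametes (each crossover transmitted with probability
1/2, no chromatid interference), genotypes gametes against a marker map, and
writes fixture files in the :mod:`xofit.io_data` formats.

Presets emulate three study designs:

* ``mouse_backcross`` -- a backcross panel of 200 gametes over 20
  chromosomes with chromosome-specific maps;
* ``wheat_segregation`` -- a single-chromosome doubled-haploid segregation
  set;
* ``nodule_bivalents`` -- a few hundred cells of continuous crossover
  positions in physical units (synaptonemal-complex micrometers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_data import (
    BivalentDataset,
    ChromosomeFrame,
    GameteDataset,
    GeneticMap,
    write_bivalent_positions,
    write_segregation,
)
from .renewal import GammaSprinklingParams, integrated_survival

__all__ = [
    "FixtureSpec",
    "simulate_gamma_bivalents",
    "thin_to_gametes",
    "genotype_gametes",
    "make_fixture",
    "PRESETS",
]

#: grid resolution for inverse-CDF sampling of the equilibrium first point
_FE_GRID = 4000


def _sample_first_point(
    params: GammaSprinklingParams, L: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the first P1 point after 0 from the equilibrium density.

    Inverse-CDF on a ``_FE_GRID``-point grid with linear interpolation;
    draws falling beyond ``L`` are reported as ``inf`` (no P1 point in the
    window).
    """
    xs = np.linspace(0.0, L, _FE_GRID + 1)
    cdf = params.intensity_p1 * np.asarray(integrated_survival(xs, params))
    u = rng.random(n)
    first = np.interp(u, cdf, xs)
    first[u > cdf[-1]] = np.inf
    return first


def simulate_gamma_bivalents(
    params: GammaSprinklingParams,
    L: float,
    n: int,
    rng: np.random.Generator,
) -> BivalentDataset:
    """Simulate ``n`` bivalents of the gamma-sprinkling model on ``[0, L]``.

    P1: stationary renewal start (equilibrium first point) followed by
    i.i.d. gamma gaps; P2: a Poisson(``2pL``) number of uniform positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if L <= 0:
        raise ValueError("L must be positive")
    rows_parts: list[np.ndarray] = []
    vals_parts: list[np.ndarray] = []
    if params.p < 1.0:
        first = _sample_first_point(params, L, n, rng)
        alive = np.isfinite(first)
        mean_count = params.intensity_p1 * L
        K = int(np.ceil(mean_count + 10.0 * np.sqrt(mean_count + 1.0) + 20.0))
        gaps = rng.gamma(params.nu, 1.0 / params.rate, size=(n, K))
        pos = np.where(alive, first, np.inf)[:, None] + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1
        )
        valid = pos <= L
        row_idx, col_idx = np.nonzero(valid)
        rows_parts.append(row_idx)
        vals_parts.append(pos[row_idx, col_idx])
        # rare cells whose K gaps did not carry them past L get extensions
        for i in np.nonzero(valid[:, -1])[0]:
            t = pos[i, -1]
            more = []
            while True:
                t = t + rng.gamma(params.nu, 1.0 / params.rate)
                if t > L:
                    break
                more.append(t)
            if more:
                rows_parts.append(np.full(len(more), i))
                vals_parts.append(np.asarray(more))
    if params.p > 0.0:
        k2 = rng.poisson(params.intensity_p2 * L, size=n)
        total2 = int(k2.sum())
        if total2:
            rows_parts.append(np.repeat(np.arange(n), k2))
            vals_parts.append(L * rng.random(total2))
    if rows_parts:
        rows = np.concatenate(rows_parts)
        vals = np.concatenate(vals_parts)
        order = np.lexsort((vals, rows))
        flat = vals[order]
        counts = np.bincount(rows, minlength=n)
    else:
        flat = np.empty(0)
        counts = np.zeros(n, dtype=int)
    cells = np.split(flat, np.cumsum(counts)[:-1])
    return BivalentDataset.from_sorted(cells, ChromosomeFrame(L, "morgan"))


def thin_to_gametes(
    data: BivalentDataset, rng: np.random.Generator
) -> BivalentDataset:
    """Transmit each bivalent crossover to the gamete with probability 1/2."""
    cells = [c[rng.random(c.size) < 0.5] for c in data.cells]
    return BivalentDataset.from_sorted(cells, data.frame)


def genotype_gametes(
    gametes: BivalentDataset,
    gmap: GeneticMap,
    missing_rate: float,
    rng: np.random.Generator,
) -> GameteDataset:
    """Read marker genotypes off gamete crossover lists.

    Each gamete starts from a fair-coin parental allele and flips at every
    crossover; calls are independently masked with probability
    ``missing_rate``.
    """
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    pos = gmap.positions_morgans
    if pos[0] < 0 or pos[-1] > gametes.frame.length_morgans + 1e-12:
        raise ValueError("map extends beyond the chromosome")
    n = gametes.n_cells
    calls = np.empty((n, pos.size), dtype=object)
    for i, cell in enumerate(gametes.cells):
        start = rng.integers(0, 2)
        phase = (start + np.searchsorted(cell, pos, side="right")) % 2
        calls[i] = np.where(phase == 0, "A", "B")
    if missing_rate > 0.0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan
    geno = pd.DataFrame(
        calls,
        index=[f"g{i + 1}" for i in range(n)],
        columns=list(gmap.names),
    )
    return GameteDataset(geno, gmap)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Recipe for a synthetic on-disk dataset (seed mandatory)."""

    model: GammaSprinklingParams
    seed: int
    kind: str = "bivalent"  # bivalent | gamete
    n_cells: int = 500
    L: float = 1.0
    n_markers: int = 11
    missing_rate: float = 0.0
    physical_length: float | None = None  # emit physical units if set
    physical_units: str = "um"

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.L <= 0 or self.n_markers < 2:
            raise ValueError("sizes must be positive")
        if self.kind not in ("bivalent", "gamete"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _equally_spaced_map(L: float, n_markers: int) -> GeneticMap:
    pos = np.linspace(0.0, L, n_markers)
    names = tuple(f"m{i + 1}" for i in range(n_markers))
    return GeneticMap(names, pos)


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write one synthetic dataset to ``out_dir``; returns the manifest.

    Bivalent fixtures may be emitted in physical units (positions rescaled
    monotonically onto ``[0, physical_length]`` with a smooth distortion) to
    exercise the genetic-space conversion.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    data = simulate_gamma_bivalents(spec.model, spec.L, spec.n_cells, rng)
    manifest: dict = {
        "kind": spec.kind,
        "seed": spec.seed,
        "nu": spec.model.nu,
        "p": spec.model.p,
        "n_cells": spec.n_cells,
        "L_morgans": spec.L,
        "files": {},
    }
    if spec.kind == "bivalent":
        if spec.physical_length is not None:
            # smooth monotone distortion: genetic position u in [0,1] maps to
            # physical u + 0.15*sin(pi*u), stretched to the physical length
            P = spec.physical_length
            cells = []
            for c in data.cells:
                u = c / spec.L
                cells.append(P * (u + 0.15 * np.sin(np.pi * u)) / 1.15)
            data = BivalentDataset(
                cells, ChromosomeFrame(P, spec.physical_units)
            )
        path = out_dir / "positions.txt"
        write_bivalent_positions(data, path)
        manifest["files"]["positions"] = path.name
    else:
        gmap = _equally_spaced_map(spec.L, spec.n_markers)
        gametes = thin_to_gametes(data, rng)
        gd = genotype_gametes(gametes, gmap, spec.missing_rate, rng)
        gpath = out_dir / "genotypes.tsv"
        mpath = out_dir / "map.tsv"
        write_segregation(gd, gpath, mpath)
        manifest["files"]["genotypes"] = gpath.name
        manifest["files"]["map"] = mpath.name
        manifest["n_markers"] = spec.n_markers
        manifest["missing_rate"] = spec.missing_rate
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _mouse_backcross(seed: int, out_dir) -> dict:
    """Backcross panel: 200 gametes on each of 20 mouse-like chromosomes."""
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    chrom_manifests = []
    # genetic lengths spread between ~0.4 and ~0.9 Morgans, larger first
    lengths = np.linspace(0.92, 0.42, 20)
    for c, L in enumerate(lengths, start=1):
        sub = FixtureSpec(
            model=GammaSprinklingParams(nu=6.0, p=0.1),
            seed=int(rng.integers(0, 2**31 - 1)),
            kind="gamete",
            n_cells=200,
            L=float(L),
            n_markers=10,
            missing_rate=0.02,
        )
        chrom_manifests.append(make_fixture(sub, out_dir / f"chr{c:02d}"))
    manifest = {"preset": "mouse_backcross", "seed": seed,
                "chromosomes": chrom_manifests}
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


PRESETS = {
    "mouse_backcross": _mouse_backcross,
    "wheat_segregation": lambda seed, out: make_fixture(
        FixtureSpec(
            model=GammaSprinklingParams(nu=4.0, p=0.15),
            seed=seed,
            kind="gamete",
            n_cells=180,
            L=1.5,
            n_markers=20,
            missing_rate=0.03,
        ),
        out,
    ),
    "nodule_bivalents": lambda seed, out: make_fixture(
        FixtureSpec(
            model=GammaSprinklingParams(nu=5.6, p=0.18),
            seed=seed,
            kind="bivalent",
            n_cells=300,
            L=1.6,
            physical_length=50.0,
            physical_units="um",
        ),
        out,
    ),
}
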