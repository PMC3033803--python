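"""Histogram summaries and the projected-likelihood score.

Three histograms summarize a crossover dataset: the distribution of the
number of crossovers per chromosome, the distribution of crossover
positions along the chromosome, and the distribution of distances between
successive crossovers.  For gamete segregation data the "crossover
positions" are the midpoints of recombinant marker intervals and the count
is the number of recombination events.

The projected-likelihood score measures how well a model reproduces the
observed histograms: it is the multinomial log-likelihood of the observed
bin counts under the bin frequencies of a large simulated population
(zero simulated bins are floored at ``eps = 1/(2 n_sim)``).  Higher is
better; the observed proportions themselves maximize it (Gibbs'
inequality).  The score is the fitting objective for the beam-film family,
where no likelihood is computable, and an option for the gamma family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import defaults
from .beam_film import simulate_bfs_population
from .io_data import BivalentDataset, GameteDataset
from .models import ModelSpec
from .synthetic import genotype_gametes, simulate_gamma_bivalents, thin_to_gametes

__all__ = [
    "HistogramBins",
    "HistogramSet",
    "ScoreSettings",
    "ScoreResult",
    "build_histograms",
    "model_histograms",
    "projected_likelihood_score",
]


@dataclass(frozen=True)
class HistogramBins:
    kmax: int = defaults.HIST_KMAX
    n_pos: int = defaults.HIST_POS_BINS
    n_dist: int = defaults.HIST_DIST_BINS


@dataclass
class Histogram:
    """One histogram: counts per bin with optional 95% CI on proportions."""

    edges: np.ndarray  # bin edges (len nbins+1); count histogram uses k bins
    counts: np.ndarray
    total: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total


@dataclass
class HistogramSet:
    """Count, position and inter-crossover-distance histograms."""

    count: Histogram
    position: Histogram
    distance: Histogram
    n_records: int
    L: float


@dataclass(frozen=True)
class ScoreSettings:
    """Settings of the projected-likelihood score.

    ``n_sim`` simulated meioses per model evaluation (the projection);
    ``score_type`` selects which histogram components enter the score.
    ``epsilon`` floors empty simulated bins; by default ``1/(2 n_sim)``.
    """

    n_sim: int = defaults.SCORE_N_SIM
    score_type: str = "combined"  # counts | distances | combined
    seed: int = 0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.n_sim < 10**4:
            raise ValueError("n_sim must be at least 1e4")
        if self.score_type not in ("counts", "distances", "combined"):
            raise ValueError(f"unknown score_type {self.score_type!r}")

    @property
    def eps(self) -> float:
        return self.epsilon if self.epsilon is not None else 0.5 / self.n_sim


@dataclass
class ScoreResult:
    score: float
    components: dict
    settings: ScoreSettings


def _clopper_pearson(k: np.ndarray, n: int, alpha: float = 0.05):
    """Exact binomial CI per bin (beta quantile closed form)."""
    k = np.asarray(k, dtype=float)
    lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return lo, hi


def _flat_records(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-record CO counts, pooled positions and within-record distances.

    Gamete records use midpoints of recombinant merged intervals.  Pooled
    positions are concatenated record by record (each record sorted), so
    within-record distances are consecutive differences that do not cross a
    record boundary.
    """
    if isinstance(data, BivalentDataset):
        if data.n_cells == 0:
            raise ValueError("empty dataset")
        counts = data.counts()
        pooled = data.pooled_positions()
        L = data.frame.length_morgans
    elif isinstance(data, GameteDataset):
        if data.n_gametes == 0:
            raise ValueError("empty dataset")
        gmap = data.require_map()
        pos = gmap.positions_morgans
        mids, counts = [], []
        for tokens in data.partitions():
            rec = [0.5 * (pos[i] + pos[j]) for i, j, r in tokens if r == 1]
            counts.append(len(rec))
            mids.extend(rec)
        counts = np.asarray(counts, dtype=int)
        pooled = np.asarray(mids)
        L = gmap.span
    else:
        raise TypeError(f"unsupported dataset type: {type(data).__name__}")
    if pooled.size > 1:
        gaps = np.diff(pooled)
        keep = np.ones(pooled.size - 1, dtype=bool)
        ends = np.cumsum(counts)
        keep[ends[(ends > 0) & (ends < pooled.size)] - 1] = False
        dists = gaps[keep]
    else:
        dists = np.empty(0)
    return counts, pooled, dists, L


def build_histograms(
    data,
    bins: HistogramBins = HistogramBins(),
    with_ci: bool = True,
) -> HistogramSet:
    """Histogram a dataset, with 95% Clopper-Pearson CIs per bin.

    Inter-crossover distances are computed within records only; records
    with fewer than two crossovers contribute none.
    """
    counts, pooled, dists, L = _flat_records(data)
    n = counts.size
    k_edges = np.arange(bins.kmax + 2) - 0.5
    k_hist = np.histogram(np.minimum(counts, bins.kmax), bins=k_edges)[0]
    pos_edges = np.linspace(0.0, L, bins.n_pos + 1)
    pos_hist = np.histogram(np.clip(pooled, 0, L), bins=pos_edges)[0]
    dist_edges = np.linspace(0.0, L, bins.n_dist + 1)
    dist_hist = np.histogram(np.clip(dists, 0, L), bins=dist_edges)[0]

    def make(edges, hist, total):
        h = Histogram(edges=edges, counts=hist, total=int(total))
        if with_ci and total > 0:
            h.ci_low, h.ci_high = _clopper_pearson(hist, int(total))
        return h

    return HistogramSet(
        count=make(k_edges, k_hist, n),
        position=make(pos_edges, pos_hist, pooled.size),
        distance=make(dist_edges, dist_hist, dists.size),
        n_records=n,
        L=L,
    )


def _simulate_design(model: ModelSpec, design, n_sim: int, rng):
    """Simulate ``n_sim`` records mirroring the observed data's structure."""
    if isinstance(design, BivalentDataset):
        L = design.frame.length_morgans
        gametic = False
    elif isinstance(design, GameteDataset):
        L = design.require_map().span
        gametic = True
    else:
        raise TypeError(f"unsupported design type: {type(design).__name__}")
    if model.family in ("gamma", "gs"):
        biv = simulate_gamma_bivalents(model.gamma_params(), L, n_sim, rng)
    elif model.family in ("bf", "bfs"):
        biv = simulate_bfs_population(model.bf_params(), n_sim, L, rng)
    else:
        raise ValueError(f"unknown model family {model.family!r}")
    if not gametic:
        return biv
    gmap = design.map
    gametes = thin_to_gametes(biv, rng)
    gd = genotype_gametes(gametes, gmap, 0.0, rng)
    # reproduce the observed missing pattern by recycling observed masks
    obs_mask = design.genotypes.isna().to_numpy()
    if obs_mask.any():
        idx = rng.integers(0, obs_mask.shape[0], size=n_sim)
        vals = gd.genotypes.to_numpy(dtype=object)
        vals[obs_mask[idx]] = np.nan
        gd = GameteDataset(
            gd.genotypes.__class__(
                vals, index=gd.genotypes.index, columns=gd.genotypes.columns
            ),
            gmap,
        )
    return gd


def model_histograms(
    model: ModelSpec,
    design,
    settings: ScoreSettings,
    bins: HistogramBins = HistogramBins(),
) -> HistogramSet:
    """Histograms predicted by a model, via a simulated population.

    ``design`` is the observed dataset whose structure (bivalent vs gamete,
    marker map, missing pattern) the simulation mirrors.  No CIs are
    attached: frequencies of a large simulated population play the role of
    model probabilities.
    """
    rng = np.random.default_rng(settings.seed)
    sim = _simulate_design(model, design, settings.n_sim, rng)
    return build_histograms(sim, bins=bins, with_ci=False)


def projected_likelihood_score(
    obs: HistogramSet,
    sim: HistogramSet,
    settings: ScoreSettings,
) -> ScoreResult:
    """Multinomial log-likelihood of the observed bins under the model.

    ``S = sum_b n_obs,b * ln(max(pi_sim,b, eps))`` over the crossover-count
    histogram, plus the same over the inter-crossover-distance histogram
    when ``score_type`` is ``combined``.  Components are reported
    separately; the unweighted sum is the score.
    """
    comps = {}
    for name in ("count", "distance"):
        ho: Histogram = getattr(obs, name)
        hs: Histogram = getattr(sim, name)
        if ho.counts.size != hs.counts.size or not np.allclose(
            ho.edges, hs.edges
        ):
            raise ValueError(f"{name} histogram bins do not match")
        pi = np.maximum(hs.proportions, settings.eps)
        comps[name + "s"] = float(np.sum(ho.counts * np.log(pi)))
    if settings.score_type == "counts":
        total = comps["counts"]
    elif settings.score_type == "distances":
        total = comps["distances"]
    else:
        total = comps["counts"] + comps["distances"]
    if not np.isfinite(total):
        raise ValueError("score is not finite")
    return ScoreResult(score=float(total), components=comps, settings=settings)
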