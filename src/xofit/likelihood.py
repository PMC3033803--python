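"""Exact log-likelihoods for the gamma and gamma-sprinkling models.

Two observation levels are supported:

* **Bivalents** -- continuous crossover positions.  The likelihood of a cell
  sums over every assignment of its crossovers to the interfering pathway P1
  (stationary renewal factors) and the Poisson pathway P2.  The sum over the
  ``2^k`` assignments is evaluated with an O(k^2) dynamic program over the
  sorted positions, since only consecutive P1 members are coupled.

* **Gametes** -- marker segregation patterns.  Without chromatid
  interference every bivalent crossover enters a gamete independently with
  probability 1/2, so the recombination parity of a marker interval is 1/2
  whenever the interval holds at least one bivalent crossover and forced to
  0 when it is empty.  This yields the inclusion-exclusion identity

      P(r) = 2^-M * sum_{B subset of intervals} (-1)^{|B & R|} Z(B)

  over gap probabilities ``Z(B)``, and equivalently a signed two-branch
  transfer operator (one "free" and one "empty" propagation per interval)
  that evaluates the same quantity in time linear in the number of
  intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import defaults
from .io_data import BivalentDataset, ChromosomeFrame, GameteDataset
from .renewal import (
    GammaSprinklingParams,
    RenewalFilter,
    RenewalGrid,
    integrated_survival,
)

__all__ = [
    "GametePattern",
    "bivalent_loglik",
    "pattern_prob_ie",
    "pattern_prob_dp",
    "dataset_loglik",
]

_IE_MAX_INTERVALS = 12
_BIVALENT_MAX_COS = 200


def _gamma_funcs(params: GammaSprinklingParams):
    """Vectorized pdf and survival of the inter-arrival gamma law.

    Direct special-function evaluation (valid for nonnegative arguments);
    avoids the frozen-distribution overhead in likelihood inner loops.
    """
    from scipy import special

    a, rate = params.nu, params.rate
    log_norm = a * np.log(rate) - special.gammaln(a)

    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.exp(log_norm + special.xlogy(a - 1.0, x) - rate * x)

    def sf(x):
        return special.gammaincc(a, rate * np.asarray(x, dtype=float))

    return pdf, sf


@dataclass(frozen=True)
class GametePattern:
    """Recombination pattern of one gamete.

    ``bounds`` are the ordered, disjoint genetic intervals (Morgans) of the
    gamete's merged marker partition; ``parity[j]`` is 1 when the alleles at
    the two ends of interval j differ (an odd number of transmitted
    crossovers) and 0 otherwise.
    """

    bounds: tuple[tuple[float, float], ...]
    parity: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.parity):
            raise ValueError("bounds and parity must have equal length")
        if len(self.bounds) == 0:
            raise ValueError("pattern needs at least one interval")
        prev_end = -np.inf
        for (a, b) in self.bounds:
            if b <= a:
                raise ValueError("intervals must have positive length")
            if a < prev_end:
                raise ValueError("intervals must be disjoint and ordered")
            prev_end = b
        if any(r not in (0, 1) for r in self.parity):
            raise ValueError("parity entries must be 0 or 1")

    @property
    def M(self) -> int:
        return len(self.bounds)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.bounds])


# ---------------------------------------------------------------------------
# Bivalent likelihood
# ---------------------------------------------------------------------------


def _zp1_window(L: float, params: GammaSprinklingParams) -> float:
    """P1 gap probability of the full window [0, L] (closed form)."""
    if params.p >= 1.0:
        return 1.0
    return float(1.0 - params.intensity_p1 * integrated_survival(L, params))


def bivalent_loglik(
    cell,
    frame: ChromosomeFrame,
    params: GammaSprinklingParams,
) -> float:
    """Log-density of one bivalent's sorted crossover positions.

    Sums over all P1/P2 assignments of the ``k`` crossovers: a P1 subset
    contributes the stationary renewal density (equilibrium first point,
    gamma gaps, survival past ``L``; the gap probability of the whole window
    when the subset is empty) and the complement contributes the Poisson
    factor ``(2p)^{#P2} * exp(-2pL)``.
    """
    L = frame.length_morgans
    x = np.asarray(cell, dtype=float)
    if x.size and (x.min() < 0.0 or x.max() > L):
        raise ValueError("positions must lie inside [0, L]")
    if np.any(np.diff(x) < 0):
        x = np.sort(x)
    k = x.size
    if k > _BIVALENT_MAX_COS:
        raise ValueError(f"cell with {k} crossovers exceeds supported size")
    lam2 = params.intensity_p2
    if k == 0:
        return float(np.log(_zp1_window(L, params)) - lam2 * L)
    if params.p >= 1.0:
        return float(k * np.log(lam2) - lam2 * L)
    lam1 = params.intensity_p1
    pdf, sf = _gamma_funcs(params)
    fe = lam1 * sf(x)
    surv = sf(L - x)
    # W[i]: sum over P1 subsets whose rightmost member is i, of the renewal
    # density up to i times lam2 for every skipped (P2) point before i.
    W = np.empty(k)
    for i in range(k):
        acc = fe[i] * lam2**i
        if i:
            acc += float(
                np.sum(W[:i] * lam2 ** (i - 1 - np.arange(i)) * pdf(x[i] - x[:i]))
            )
        W[i] = acc
    total = float(np.sum(W * lam2 ** (k - 1 - np.arange(k)) * surv))
    total += lam2**k * _zp1_window(L, params)
    return float(np.log(total) - lam2 * L)


def _bivalent_dataset_loglik(
    data: BivalentDataset,
    params: GammaSprinklingParams,
) -> float:
    """Sum of per-cell log-densities, vectorized across equal-count cells."""
    L = data.frame.length_morgans
    lam2 = params.intensity_p2
    counts = data.counts()
    ll = 0.0
    n0 = int(np.sum(counts == 0))
    if n0:
        ll += n0 * (np.log(_zp1_window(L, params)) - lam2 * L)
    if params.p >= 1.0:
        ktot = int(counts.sum())
        return float(ll + ktot * np.log(lam2) - lam2 * L * np.sum(counts > 0))
    lam1 = params.intensity_p1
    pdf_fn, sf_fn = _gamma_funcs(params)
    zp1 = _zp1_window(L, params)
    for k in np.unique(counts):
        k = int(k)
        if k == 0:
            continue
        if k > _BIVALENT_MAX_COS:
            idx = int(np.argmax(counts == k))
            raise ValueError(f"cell {idx} has {k} crossovers; unsupported")
        X = np.stack([c for c in data.cells if c.size == k])  # (m, k)
        m = X.shape[0]
        fe = lam1 * sf_fn(X)
        surv = sf_fn(L - X)
        if k > 1:
            diffs = X[:, :, None] - X[:, None, :]  # [m, i, j] = x_i - x_j
            tri = np.tril(np.ones((k, k), dtype=bool), -1)
            pdf = np.zeros((m, k, k))
            pdf[:, tri] = pdf_fn(diffs[:, tri])
        W = np.empty((m, k))
        for i in range(k):
            acc = fe[:, i] * lam2**i
            if i:
                acc = acc + np.sum(
                    W[:, :i] * lam2 ** (i - 1 - np.arange(i)) * pdf[:, i, :i],
                    axis=1,
                )
            W[:, i] = acc
        total = np.sum(W * lam2 ** (k - 1 - np.arange(k)) * surv, axis=1)
        total = total + lam2**k * zp1
        ll += float(np.sum(np.log(np.maximum(total, defaults.PROB_FLOOR))))
        ll -= m * lam2 * L
    return float(ll)


# ---------------------------------------------------------------------------
# Gamete pattern probabilities
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _cached_grid(bounds_key: tuple, grid_step: float | None) -> RenewalGrid:
    return RenewalGrid(np.asarray(bounds_key), grid_step=grid_step)


@lru_cache(maxsize=32)
def _cached_filter(
    bounds_key: tuple, grid_step: float | None, nu: float, p: float
) -> RenewalFilter:
    return RenewalFilter(
        _cached_grid(bounds_key, grid_step), GammaSprinklingParams(nu, p)
    )


def _pattern_segments(pattern: GametePattern, grid_step: float | None):
    """Grid, filter lookup key and segment plan over the pattern's span.

    Segments are processed left to right; each is either a pattern interval
    (index j) or an inter-interval gap (always propagated freely).
    """
    bounds_key = tuple(sorted({b for iv in pattern.bounds for b in iv}))
    grid = _cached_grid(bounds_key, grid_step)
    pos_to_idx = {b: i for i, b in enumerate(bounds_key)}
    segments: list[tuple[str, int, int, int]] = []
    for j, (a, b) in enumerate(pattern.bounds):
        if j > 0:
            prev_end = pattern.bounds[j - 1][1]
            if a > prev_end:
                c0, c1 = grid.cell_range(
                    pos_to_idx[prev_end], pos_to_idx[a]
                )
                segments.append(("gap", -1, c0, c1))
        c0, c1 = grid.cell_range(pos_to_idx[a], pos_to_idx[b])
        segments.append(("iv", j, c0, c1))
    return bounds_key, grid, segments


@lru_cache(maxsize=128)
def _subset_gap_probs(
    bounds_key: tuple,
    segments_key: tuple,
    grid_step: float | None,
    nu: float,
    p: float,
) -> dict:
    """P1 gap probability for every subset of a partition's intervals.

    Keyed by subset bitmask; shared by all parity patterns on the same
    partition, so inclusion-exclusion over many patterns reuses one table.
    """
    filt = _cached_filter(bounds_key, grid_step, nu, p)
    n_iv = sum(1 for s in segments_key if s[0] == "iv")
    out = {}
    for mask in range(2**n_iv):
        psi, o = filt.initial_state(0)
        for kind, j, c0, c1 in segments_key:
            if kind == "iv" and (mask >> j) & 1:
                psi, o = filt.apply_empty(psi, o, c0, c1)
            else:
                psi, o = filt.apply_free(psi, o, c0, c1)
        out[mask] = float(filt.close(psi, o))
    return out


def pattern_prob_ie(
    pattern: GametePattern,
    params: GammaSprinklingParams,
    grid_step: float | None = None,
) -> float:
    """Pattern probability by inclusion-exclusion over interval subsets.

    Exponential in the number of intervals; limited to M <= 12.  Every gap
    probability is evaluated on the same grid as :func:`pattern_prob_dp`.
    """
    M = pattern.M
    if M > _IE_MAX_INTERVALS:
        raise ValueError(
            f"M={M} > {_IE_MAX_INTERVALS}: use pattern_prob_dp instead"
        )
    bounds_key, _, segments = _pattern_segments(pattern, grid_step)
    z_p1 = _subset_gap_probs(
        bounds_key, tuple(segments), grid_step, params.nu, params.p
    )
    lengths = pattern.lengths
    lam2 = params.intensity_p2
    R = np.array(pattern.parity)
    total = 0.0
    for mask in range(2**M):
        members = [(mask >> j) & 1 for j in range(M)]
        blen = float(np.dot(members, lengths))
        sign = (-1) ** int(np.dot(members, R))
        total += sign * z_p1[mask] * np.exp(-lam2 * blen)
    return float(total / 2**M)


def pattern_prob_dp(
    pattern: GametePattern,
    params: GammaSprinklingParams,
    grid_step: float | None = None,
) -> float:
    """Pattern probability via the signed transfer operator, linear in M.

    Per interval j the state update is
    ``O_j = 1/2 * T_free + (1{r_j = 0} - 1/2) * exp(-2p g_j) * T_empty``,
    which expands to exactly the inclusion-exclusion sum of
    :func:`pattern_prob_ie`.
    """
    if grid_step is not None and grid_step <= 0:
        raise ValueError("grid_step must be positive")
    bounds_key, _, segments = _pattern_segments(pattern, grid_step)
    filt = _cached_filter(bounds_key, grid_step, params.nu, params.p)
    lam2 = params.intensity_p2
    psi, o = filt.initial_state(0)
    for kind, j, c0, c1 in segments:
        if kind == "gap":
            psi, o = filt.apply_free(psi, o, c0, c1)
            continue
        a, b = pattern.bounds[j]
        sign = 1.0 if pattern.parity[j] == 0 else -1.0
        w = sign * 0.5 * np.exp(-lam2 * (b - a))
        psi_f, o_f = filt.apply_free(psi, o, c0, c1)
        psi_e, o_e = filt.apply_empty(psi, o, c0, c1)
        psi = 0.5 * psi_f + w * psi_e
        o = 0.5 * o_f + w * o_e
    return float(filt.close(psi, o))


# ---------------------------------------------------------------------------
# Dataset log-likelihood
# ---------------------------------------------------------------------------


def _gamete_dataset_loglik(
    data: GameteDataset,
    params: GammaSprinklingParams,
    grid_step: float | None,
) -> float:
    """Batched transfer-operator likelihood over a gamete dataset.

    Gametes are grouped into unique patterns and the patterns into a prefix
    trie whose nodes hold filter states; each trie edge applies the signed
    two-branch operator once, batched over all states that share the same
    marker interval.  States are propagated on one global grid built from
    the marker map, so gametes with different missing-data partitions share
    all parameter-dependent precomputations.
    """
    gmap = data.require_map()
    positions = gmap.positions_morgans
    grid = _cached_grid(tuple(positions), grid_step)
    filt = RenewalFilter(grid, params)
    lam2 = params.intensity_p2

    trie = _pattern_trie(data, grid_step)
    if trie is None:
        return 0.0
    n_nodes, roots, edge_groups, leaves = trie

    psi = np.zeros((n_nodes, grid.n_cells))
    o = np.zeros(n_nodes)
    for nid, start in roots:
        psi[nid], o[nid] = filt.initial_state(start_boundary=start)

    for (i, j), group, uniq_parents, inv in edge_groups:
        c0, c1 = grid.cell_range(i, j)
        psi_f, o_f = filt.apply_free(psi[uniq_parents], o[uniq_parents], c0, c1)
        w_empty = 0.5 * np.exp(-lam2 * (positions[j] - positions[i]))
        for gidx, (pid, parity, cid) in enumerate(group):
            u = inv[gidx]
            w = w_empty if parity == 0 else -w_empty
            psi_e = psi[pid].copy()
            psi_e[c0:c1] = 0.0
            psi[cid] = 0.5 * psi_f[u] + w * psi_e
            o[cid] = 0.5 * o_f[u] + w * o[pid]

    ll = 0.0
    for nid, end_boundary, count in leaves:
        c_end = grid.cstart[end_boundary]
        prob = float(filt.close(psi[nid], o[nid], c_end=c_end))
        ll += count * float(np.log(max(prob, defaults.PROB_FLOOR)))
    return float(ll)


def _pattern_trie(data: GameteDataset, grid_step: float | None):
    """Prefix trie over the dataset's unique gamete patterns (cached).

    The trie depends only on the data and grid geometry, so it is shared by
    every likelihood evaluation during a fit.  Returns ``(n_nodes, roots,
    edge_groups, leaves)`` where edge groups are sorted left to right and
    carry precomputed unique-parent indexing for batched propagation.
    """
    cache = getattr(data, "_trie_cache", None)
    if cache is not None and cache[0] == grid_step:
        return cache[1]
    pattern_counts: dict[tuple, int] = {}
    for tokens in data.partitions():
        if not tokens:
            continue  # all markers missing: contributes nothing
        key = tuple(tokens)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    if not pattern_counts:
        trie = None
    else:
        nodes: dict[tuple, int] = {}
        edges: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
        roots: list[tuple[int, int]] = []
        leaves: list[tuple[int, int, int]] = []
        for key, count in pattern_counts.items():
            root = ("root", key[0][0])
            if root not in nodes:
                nodes[root] = len(nodes)
                roots.append((nodes[root], key[0][0]))
            prefix = root
            for tok in key:
                child = prefix + (tok,)
                if child not in nodes:
                    nodes[child] = len(nodes)
                    i, j, parity = tok
                    edges.setdefault((i, j), []).append(
                        (nodes[prefix], parity, nodes[child])
                    )
                prefix = child
            leaves.append((nodes[prefix], key[-1][1], count))
        edge_groups = []
        for span in sorted(edges):
            group = edges[span]
            parents = np.array([g[0] for g in group])
            uniq_parents, inv = np.unique(parents, return_inverse=True)
            edge_groups.append((span, group, uniq_parents, inv))
        trie = (len(nodes), roots, edge_groups, leaves)
    data._trie_cache = (grid_step, trie)
    return trie


def dataset_loglik(
    data,
    params: GammaSprinklingParams,
    grid_step: float | None = None,
) -> float:
    """Log-likelihood of a bivalent or gamete dataset under the model.

    Bivalent datasets sum :func:`bivalent_loglik` over cells; gamete
    datasets sum the log pattern probability over gametes (gametes whose
    markers are all missing contribute nothing).
    """
    if isinstance(data, BivalentDataset):
        if data.n_cells == 0:
            raise ValueError("empty dataset")
        if data.frame.source_units != "morgan":
            raise ValueError(
                "bivalent data must be converted to genetic space first"
            )
        return _bivalent_dataset_loglik(data, params)
    if isinstance(data, GameteDataset):
        if data.n_gametes == 0:
            raise ValueError("empty dataset")
        return _gamete_dataset_loglik(data, params, grid_step)
    raise TypeError(f"unsupported dataset type: {type(data).__name__}")
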