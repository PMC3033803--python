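"""Stationary gamma renewal process with a superposed Poisson pathway.

The interfering crossover pathway (P1) is modelled as a stationary renewal
process whose inter-crossover distances follow a gamma distribution with
shape ``nu`` (interference strength) and rate ``2*nu*(1-p)`` per Morgan, so
that P1 contributes intensity ``2*(1-p)`` crossovers per Morgan on the
bivalent.  The non-interfering pathway (P2) is a homogeneous Poisson process
of intensity ``2*p``; "sprinkling" its points onto P1 keeps the total
bivalent intensity at exactly 2 per Morgan.

``nu = 1`` collapses P1 to a Poisson process, making ``p`` unidentifiable;
``p = 0`` removes the second pathway.

Besides closed-form densities, this module provides the numerical engine
(:class:`RenewalGrid` / :class:`RenewalFilter`) that propagates the
distribution of the next P1 renewal position across a partitioned segment.
The engine underlies both gap ("avoidance") probabilities and the gamete
pattern likelihoods in :mod:`xofit.likelihood`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import defaults

__all__ = [
    "GammaSprinklingParams",
    "interarrival_density",
    "interarrival_cdf",
    "stationary_first_density",
    "integrated_survival",
    "avoidance_probability",
    "count_distribution",
    "RenewalGrid",
    "RenewalFilter",
]


@dataclass(frozen=True)
class GammaSprinklingParams:
    """Parameters of the gamma / gamma-sprinkling model.

    Parameters
    ----------
    nu
        Gamma shape, the interference strength ("parameter 1").  Must lie in
        ``[NU_MIN, NU_MAX]``.  ``nu = 1`` is no interference.
    p
        Proportion of crossovers from the non-interfering pathway P2
        ("parameter 2"), in ``[0, 1]``.
    """

    nu: float
    p: float = 0.0

    def __post_init__(self) -> None:
        if not (defaults.NU_MIN <= self.nu <= defaults.NU_MAX):
            raise ValueError(
                f"nu={self.nu} outside admissible range "
                f"[{defaults.NU_MIN}, {defaults.NU_MAX}]"
            )
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p={self.p} outside [0, 1]")

    @property
    def intensity_p1(self) -> float:
        """P1 crossovers per Morgan on the bivalent: ``2*(1-p)``."""
        return defaults.BIVALENT_INTENSITY * (1.0 - self.p)

    @property
    def intensity_p2(self) -> float:
        """P2 crossovers per Morgan on the bivalent: ``2*p``."""
        return defaults.BIVALENT_INTENSITY * self.p

    @property
    def rate(self) -> float:
        """Rate of the gamma inter-arrival law: ``2*nu*(1-p)``."""
        return self.nu * self.intensity_p1

    def _check_p1(self) -> None:
        if self.p >= 1.0:
            raise ValueError(
                "p = 1 leaves no interfering pathway; use the pure-Poisson "
                "branch instead of the gamma inter-arrival law"
            )


def _gamma(params: GammaSprinklingParams, shape_mult: float = 1.0):
    return stats.gamma(a=params.nu * shape_mult, scale=1.0 / params.rate)


def interarrival_density(x, params: GammaSprinklingParams):
    """Density of the distance between successive P1 crossovers.

    Gamma with shape ``nu`` and rate ``2*nu*(1-p)``; the mean distance is
    ``1 / (2*(1-p))`` Morgans.  Zero for negative ``x``.
    """
    params._check_p1()
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, _gamma(params).pdf(np.clip(x, 0.0, None)), 0.0)
    return out if out.ndim else float(out)


def interarrival_cdf(x, params: GammaSprinklingParams):
    """CDF of the P1 inter-arrival distance (0 for ``x < 0``)."""
    params._check_p1()
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, _gamma(params).cdf(np.clip(x, 0.0, None)), 0.0)
    return out if out.ndim else float(out)


def stationary_first_density(x, params: GammaSprinklingParams):
    """Equilibrium (forward-recurrence) density of the first P1 point.

    ``f_e(x) = 2*(1-p) * (1 - F(x))`` for ``x >= 0``, where ``F`` is the
    inter-arrival CDF.  ``f_e(0)`` equals the P1 intensity and the density
    integrates to 1.
    """
    params._check_p1()
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0.0,
        params.intensity_p1 * _gamma(params).sf(np.clip(x, 0.0, None)),
        0.0,
    )
    return out if out.ndim else float(out)


def integrated_survival(x, params: GammaSprinklingParams):
    """``int_0^x (1 - F(t)) dt`` for the gamma inter-arrival law, exactly.

    Uses the identity ``int_0^x S = x*S(x) + (nu/rate) * F_{nu+1}(x)`` where
    ``F_{nu+1}`` is the CDF of the gamma law with shape ``nu + 1`` and the
    same rate.  This is the building block of gap probabilities; note
    ``int_0^inf S`` equals the mean inter-arrival distance ``1/(2*(1-p))``.
    """
    from scipy.special import gammainc, gammaincc

    params._check_p1()
    x = np.asarray(x, dtype=float)
    xp = np.clip(x, 0.0, None)
    a, rate = params.nu, params.rate
    val = xp * gammaincc(a, rate * xp) + (a / rate) * gammainc(
        a + 1.0, rate * xp
    )
    val = np.where(x > 0.0, val, 0.0)
    return val if val.ndim else float(val)


# ---------------------------------------------------------------------------
# Forward propagation engine
# ---------------------------------------------------------------------------


class RenewalGrid:
    """Discretization of a partitioned segment for renewal propagation.

    The segment is split at ``boundaries`` (sorted positions in Morgans);
    each base interval is further divided into cells of width close to
    ``grid_step``.  The grid is geometry only: all parameter-dependent
    quantities live in :class:`RenewalFilter`.
    """

    def __init__(self, boundaries, grid_step: float | None = None):
        b = np.asarray(boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two boundaries")
        if np.any(np.diff(b) < 0):
            raise ValueError("boundaries must be sorted")
        self.boundaries = b
        span = b[-1] - b[0]
        if span <= 0:
            raise ValueError("zero-length segment")
        if grid_step is None:
            grid_step = span / defaults.GRID_CELLS
        if grid_step <= 0:
            raise ValueError("grid_step must be positive")
        self.grid_step = grid_step

        edges: list[np.ndarray] = []
        cstart = [0]
        for j in range(b.size - 1):
            g = b[j + 1] - b[j]
            if g <= 0:
                cstart.append(cstart[-1])
                continue
            n_j = max(2, int(np.ceil(g / grid_step)))
            edges.append(np.linspace(b[j], b[j + 1], n_j + 1)[:-1])
            cstart.append(cstart[-1] + n_j)
        self.le = np.concatenate(edges) if edges else np.empty(0)
        self.re = np.append(self.le[1:], b[-1])
        self.mid = 0.5 * (self.le + self.re)
        #: first cell index of each base interval; cstart[-1] == n_cells
        self.cstart = np.asarray(cstart, dtype=int)
        self.n_cells = self.le.size
        self.origin = float(b[0])
        self.end = float(b[-1])

    def cell_range(self, j0: int, j1: int) -> tuple[int, int]:
        """Cells covered by base intervals ``j0 .. j1-1``."""
        return int(self.cstart[j0]), int(self.cstart[j1])


class RenewalFilter:
    """Forward filter over the position of the next P1 renewal.

    The state is the sub-probability mass of the event "constraints imposed
    so far all hold and the next P1 renewal falls in cell c", together with
    an overflow mass ``o`` for "constraints hold and no renewal occurs before
    the right end of the grid".  Two linear operators act on this state:

    * ``free``  -- propagate renewals across a cell range without constraint;
    * ``empty`` -- forbid renewals in the range (P1 gap condition).

    Both are exact in the inter-arrival law (masses are gamma-CDF
    differences) and piecewise-constant (midpoint) in the state, giving
    O(h^2) accuracy with no trouble from the density singularity at 0 when
    ``nu < 1``.
    """

    def __init__(self, grid: RenewalGrid, params: GammaSprinklingParams):
        self.grid = grid
        self.params = params
        self.degenerate = params.p >= 1.0  # no P1 pathway at all
        n = grid.n_cells
        if self.degenerate or n == 0:
            self.M2 = np.zeros((n, n))
            self.sfG = np.zeros(n)
            return
        # M2[s, c]: probability that a renewal at the midpoint of cell c is
        # followed by its next renewal inside cell s (zero below the diagonal
        # since the inter-arrival CDF vanishes on negatives; the CDF is only
        # evaluated on the positive entries).
        from scipy.special import gammainc, gammaincc

        a, rate = params.nu, params.rate
        dre = grid.re[:, None] - grid.mid[None, :]
        dle = grid.le[:, None] - grid.mid[None, :]
        Fre = np.zeros_like(dre)
        m = dre > 0.0
        Fre[m] = gammainc(a, rate * dre[m])
        Fle = np.zeros_like(dle)
        m = dle > 0.0
        Fle[m] = gammainc(a, rate * dle[m])
        self.M2 = Fre - Fle
        self.sfG = gammaincc(a, rate * (grid.end - grid.mid))

    # -- state construction -------------------------------------------------

    def initial_state(self, start_boundary: int = 0) -> tuple[np.ndarray, float]:
        """Stationary state entered at base boundary ``start_boundary``.

        Returns ``(psi, o)`` where ``psi[c]`` is the mass of "first renewal
        at or beyond the start falls in cell c" (exact equilibrium masses)
        and ``o`` the mass of "no renewal before the grid end".
        """
        g = self.grid
        psi = np.zeros(g.n_cells)
        if self.degenerate:
            return psi, 1.0
        t0 = g.boundaries[start_boundary]
        c0 = g.cstart[start_boundary]
        lam1 = self.params.intensity_p1
        isf_re = integrated_survival(g.re[c0:] - t0, self.params)
        isf_le = integrated_survival(g.le[c0:] - t0, self.params)
        psi[c0:] = lam1 * (isf_re - isf_le)
        o = 1.0 - lam1 * integrated_survival(g.end - t0, self.params)
        return psi, float(o)

    # -- operators (batched over leading axis) ------------------------------

    def volterra(self, psi: np.ndarray, c0: int, c1: int) -> np.ndarray:
        """Renewal masses in cells ``c0..c1-1`` fed by state ``psi``.

        Solves the discrete renewal (Volterra) recursion: a renewal in cell c
        is either the next-renewal mass already there, or the successor of a
        renewal in an earlier cell of the range.
        """
        m = c1 - c0
        a = np.zeros(psi.shape[:-1] + (m,))
        if self.degenerate or m == 0:
            return a
        Mloc = self.M2[c0:c1, c0:c1]
        diag = np.diag(Mloc)
        for i in range(m):
            acc = psi[..., c0 + i] + a[..., :i] @ Mloc[i, :i]
            a[..., i] = acc / (1.0 - diag[i])
        return a

    def apply_free(self, psi, o, c0: int, c1: int):
        """Propagate renewals freely across cells ``[c0, c1)``."""
        a = self.volterra(psi, c0, c1)
        psi = psi.copy()
        if not self.degenerate and c1 > c0:
            psi[..., c1:] = psi[..., c1:] + a @ self.M2[c1:, c0:c1].T
            o = o + a @ self.sfG[c0:c1]
        psi[..., c0:c1] = 0.0
        return psi, o

    def apply_empty(self, psi, o, c0: int, c1: int):
        """Forbid P1 renewals in cells ``[c0, c1)``."""
        psi = psi.copy()
        psi[..., c0:c1] = 0.0
        return psi, o

    def close(self, psi, o, c_end: int | None = None):
        """Total mass of histories satisfying all imposed constraints."""
        if c_end is None:
            c_end = self.grid.n_cells
        return o + psi[..., c_end:].sum(axis=-1)


# ---------------------------------------------------------------------------
# Gap probability and count distribution
# ---------------------------------------------------------------------------


def _validate_intervals(intervals) -> np.ndarray:
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0:
        return iv.reshape(0, 2)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("intervals must be an (m, 2) array of (start, end)")
    if np.any(iv[:, 1] <= iv[:, 0]):
        raise ValueError("intervals must have positive length")
    if np.any(iv[1:, 0] < iv[:-1, 1]):
        raise ValueError("intervals must be disjoint and ordered")
    return iv


def avoidance_probability(
    intervals,
    params: GammaSprinklingParams,
    grid_step: float | None = None,
) -> float:
    """Probability that no crossover (either pathway) falls in ``intervals``.

    ``Z(B) = Z_P1(B) * exp(-2p * |B|)`` where ``Z_P1`` is the gap probability
    of the stationary P1 renewal process.  A single interval uses the closed
    form ``1 - 2(1-p) * int_0^l (1-F)``; several intervals are handled by
    renewal propagation across the allowed gaps.  ``Z(empty set) = 1``.
    """
    iv = _validate_intervals(intervals)
    if iv.shape[0] == 0:
        return 1.0
    total = float(np.sum(iv[:, 1] - iv[:, 0]))
    poisson_factor = float(np.exp(-params.intensity_p2 * total))
    if params.p >= 1.0:
        return poisson_factor
    if iv.shape[0] == 1:
        length = float(iv[0, 1] - iv[0, 0])
        z1 = 1.0 - params.intensity_p1 * integrated_survival(length, params)
        return float(z1) * poisson_factor
    bounds = np.unique(iv.ravel())
    grid = RenewalGrid(bounds, grid_step=grid_step)
    filt = RenewalFilter(grid, params)
    psi, o = filt.initial_state(0)
    starts = {float(s): True for s in iv[:, 0]}
    for j in range(bounds.size - 1):
        c0, c1 = grid.cell_range(j, j + 1)
        if float(bounds[j]) in starts:
            psi, o = filt.apply_empty(psi, o, c0, c1)
        else:
            psi, o = filt.apply_free(psi, o, c0, c1)
    return float(filt.close(psi, o)) * poisson_factor


def count_distribution(
    params: GammaSprinklingParams,
    L: float,
    kmax: int = defaults.HIST_KMAX,
) -> np.ndarray:
    """Distribution of the bivalent crossover count on ``[0, L]``.

    The P1 count law of the stationary renewal process (obtained from exact
    gamma convolutions: the sum of ``k`` inter-arrival gaps is gamma with
    shape ``k*nu``) is convolved with the Poisson(``2*p*L``) count of P2.
    Raises if more than ``COUNT_TAIL_TOL`` probability lies beyond ``kmax``.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if params.p >= 1.0:
        p1 = np.zeros(kmax + 1)
        p1[0] = 1.0
    else:
        lam1 = params.intensity_p1
        # H_k = P(at least k P1 points in [0, L]); H_1 has a closed form,
        # higher k integrate the equilibrium first-point density against the
        # CDF of (k-1) further gaps.
        H = np.zeros(kmax + 2)
        H[1] = lam1 * integrated_survival(L, params)
        nodes, weights = np.polynomial.legendre.leggauss(
            defaults.COUNT_QUAD_NODES
        )
        y = 0.5 * L * (nodes + 1.0)
        w = 0.5 * L * weights
        fe = stationary_first_density(y, params)
        ks = np.arange(2, kmax + 2)
        shapes = (ks - 1) * params.nu
        cdfs = stats.gamma.cdf(
            (L - y)[None, :], a=shapes[:, None], scale=1.0 / params.rate
        )
        H[2:] = cdfs @ (fe * w)
        p1 = np.empty(kmax + 1)
        p1[0] = 1.0 - H[1]
        p1[1:] = H[1:-1] - H[2:]
    tail = 1.0 - p1.sum()
    if tail >= defaults.COUNT_TAIL_TOL:
        raise ValueError(
            f"tail mass {tail:.2e} beyond kmax={kmax}; increase kmax"
        )
    if params.p > 0.0:
        pois = stats.poisson.pmf(np.arange(kmax + 1), params.intensity_p2 * L)
        out = np.convolve(p1, pois)[: kmax + 1]
    else:
        out = p1
    tail = 1.0 - out.sum()
    if tail >= defaults.COUNT_TAIL_TOL:
        raise ValueError(
            f"tail mass {tail:.2e} beyond kmax={kmax}; increase kmax"
        )
    return out
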