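import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xofit.io_data import ChromosomeFrame, GameteDataset, GeneticMap
from xofit.likelihood import (
    GametePattern,
    bivalent_loglik,
    dataset_loglik,
    pattern_prob_dp,
    pattern_prob_ie,
)
from xofit.renewal import GammaSprinklingParams
from xofit.synthetic import genotype_gametes, simulate_gamma_bivalents, thin_to_gametes

P = GammaSprinklingParams
FRAME = ChromosomeFrame(1.0, "morgan")


def _pattern(bounds, parity):
    return GametePattern(tuple(map(tuple, bounds)), tuple(parity))


class TestBivalentLoglik:
    def test_empty_cell_poisson(self):
        assert bivalent_loglik([], FRAME, P(1.0, 0.0)) == pytest.approx(
            -2.0, abs=1e-9
        )

    def test_single_point_poisson_any_p(self):
        ref = np.log(2 * np.exp(-2))
        for p in (0.0, 0.5, 0.9):
            assert bivalent_loglik([0.4], FRAME, P(1.0, p)) == pytest.approx(
                ref, abs=1e-9
            )

    def test_out_of_window_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            bivalent_loglik([1.2], FRAME, P(1.0))

    def test_pure_p2(self):
        ll = bivalent_loglik([0.1, 0.6], FRAME, P(2.0, 1.0))
        assert ll == pytest.approx(2 * np.log(2.0) - 2.0, abs=1e-12)

    def test_assignment_sum_brute_force(self):
        """O(k^2) dynamic program equals explicit enumeration of the 2^k
        pathway assignments."""
        pars = P(3.0, 0.3)
        x = np.array([0.15, 0.4, 0.55, 0.9])
        L = 1.0
        lam1, lam2 = pars.intensity_p1, pars.intensity_p2
        dist = stats.gamma(a=pars.nu, scale=1 / pars.rate)
        from xofit.renewal import integrated_survival

        z_p1 = 1 - lam1 * integrated_survival(L, pars)
        total = 0.0
        for mask in itertools.product([0, 1], repeat=4):
            sel = x[np.array(mask, dtype=bool)]
            if sel.size:
                dens = lam1 * dist.sf(sel[0])
                dens *= np.prod(dist.pdf(np.diff(sel)))
                dens *= dist.sf(L - sel[-1])
            else:
                dens = z_p1
            total += dens * lam2 ** (4 - sel.size)
        ref = np.log(total) - lam2 * L
        assert bivalent_loglik(x, FRAME, pars) == pytest.approx(ref, rel=1e-10)

    def test_dataset_additivity_and_duplicates(self, small_bivalents):
        pars = P(2.0, 0.1)
        total = dataset_loglik(small_bivalents, pars)
        parts = sum(
            bivalent_loglik(c, small_bivalents.frame, pars)
            for c in small_bivalents.cells
        )
        assert total == pytest.approx(parts, rel=1e-10)

    def test_physical_units_rejected(self):
        from xofit.io_data import BivalentDataset

        data = BivalentDataset([[1.0]], ChromosomeFrame(10.0, "um"))
        with pytest.raises(ValueError, match="genetic space"):
            dataset_loglik(data, P(2.0))


class TestPatternProbabilities:
    def test_haldane_single_interval(self):
        pat = _pattern([(0.0, 0.5)], [1])
        ref = (1 - np.exp(-1)) / 2
        assert pattern_prob_ie(pat, P(1.0)) == pytest.approx(ref, abs=1e-9)
        assert pattern_prob_dp(pat, P(1.0)) == pytest.approx(ref, abs=1e-9)

    def test_poisson_interval_independence(self):
        """nu=1: the two-interval double recombinant factorizes into the
        product of single-interval recombination fractions."""
        bounds = [(0.0, 0.3), (0.3, 0.8)]
        prob = pattern_prob_ie(_pattern(bounds, [1, 1]), P(1.0))
        ref = np.prod([(1 - np.exp(-2 * (b - a))) / 2 for a, b in bounds])
        assert prob == pytest.approx(ref, abs=1e-9)

    def test_poisson_collapse_independent_of_p(self):
        bounds = [(0.0, 0.3), (0.3, 0.7), (0.7, 1.0)]
        for parity in [(0, 0, 0), (1, 0, 1), (1, 1, 1)]:
            ref = pattern_prob_dp(_pattern(bounds, parity), P(1.0, 0.0))
            for p in (0.3, 0.8, 1.0):
                val = pattern_prob_dp(_pattern(bounds, parity), P(1.0, p))
                assert val == pytest.approx(ref, abs=1e-6)

    @pytest.mark.parametrize("nu", [1.0, 2.5, 5.0])
    @pytest.mark.parametrize("p", [0.0, 0.2])
    def test_dp_equals_ie_all_patterns(self, nu, p):
        bounds = [(0.0, 0.2), (0.2, 0.5), (0.5, 0.6), (0.6, 1.0)]
        for parity in itertools.product([0, 1], repeat=4):
            pat = _pattern(bounds, parity)
            ie = pattern_prob_ie(pat, P(nu, p))
            dp = pattern_prob_dp(pat, P(nu, p))
            assert dp == pytest.approx(ie, rel=1e-6)

    def test_normalization(self):
        bounds = [(0.0, 0.3), (0.3, 0.7), (0.7, 1.0)]
        total = sum(
            pattern_prob_dp(_pattern(bounds, parity), P(5.0, 0.2))
            for parity in itertools.product([0, 1], repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_vanishing_interval(self):
        pat = _pattern([(0.0, 1e-7)], [0])
        assert pattern_prob_dp(pat, P(3.0, 0.1)) == pytest.approx(1.0, abs=1e-4)

    def test_ie_interval_limit(self):
        bounds = [(0.1 * j, 0.1 * j + 0.05) for j in range(13)]
        pat = _pattern(bounds, [0] * 13)
        with pytest.raises(ValueError, match="pattern_prob_dp"):
            pattern_prob_ie(pat, P(2.0))

    def test_monte_carlo_frequency(self, rng):
        """Pattern probabilities match simulated gamete frequencies."""
        gmap = GeneticMap(("a", "b", "c"), np.array([0.0, 0.4, 1.0]))
        pars = P(4.0, 0.2)
        n = 50_000
        biv = simulate_gamma_bivalents(pars, 1.0, n, rng)
        gametes = thin_to_gametes(biv, rng)
        gd = genotype_gametes(gametes, gmap, 0.0, rng)
        tokens = gd.partitions()
        freq = {}
        for t in tokens:
            key = tuple(r for _, _, r in t)
            freq[key] = freq.get(key, 0) + 1
        bounds = [(0.0, 0.4), (0.4, 1.0)]
        for parity in itertools.product([0, 1], repeat=2):
            prob = pattern_prob_dp(_pattern(bounds, parity), pars)
            obs = freq.get(parity, 0) / n
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(obs - prob) < 4 * se


class TestGameteDatasetLoglik:
    def test_batched_matches_per_pattern(self, tiny_gametes):
        pars = P(3.0, 0.2)
        pos = tiny_gametes.map.positions_morgans
        total = dataset_loglik(tiny_gametes, pars, grid_step=1 / 2000)
        ref = 0.0
        for tokens in tiny_gametes.partitions():
            bounds = tuple((pos[i], pos[j]) for i, j, _ in tokens)
            parity = tuple(r for _, _, r in tokens)
            ref += np.log(
                pattern_prob_dp(
                    GametePattern(bounds, parity), pars, grid_step=1 / 2000
                )
            )
        assert total == pytest.approx(ref, rel=1e-8)

    def test_duplicated_gamete_doubles_its_term(self, small_map):
        row = [["A", "A", "B", "B"]]
        one = GameteDataset(
            pd.DataFrame(row, columns=list(small_map.names)), small_map
        )
        two = GameteDataset(
            pd.DataFrame(row * 2, columns=list(small_map.names)), small_map
        )
        pars = P(2.0, 0.1)
        assert dataset_loglik(two, pars) == pytest.approx(
            2 * dataset_loglik(one, pars), rel=1e-12
        )

    def test_all_missing_gametes_contribute_zero(self, small_map):
        geno = pd.DataFrame(
            [[np.nan] * 4, [np.nan] * 4], columns=list(small_map.names)
        )
        data = GameteDataset(geno, small_map)
        assert dataset_loglik(data, P(2.0)) == 0.0

    def test_empty_dataset_rejected(self, small_map):
        geno = pd.DataFrame(columns=list(small_map.names))
        with pytest.raises(ValueError, match="empty"):
            dataset_loglik(GameteDataset(geno, small_map), P(2.0))

    def test_unsupported_type_rejected(self):
        with pytest.raises(TypeError):
            dataset_loglik([1, 2, 3], P(2.0))

    def test_truth_beats_null_on_interfering_data(self, rng):
        """On data simulated with strong interference the likelihood at the
        truth exceeds the no-interference point (1, 0)."""
        gmap = GeneticMap(
            tuple(f"m{i}" for i in range(8)), np.linspace(0.0, 1.2, 8)
        )
        truth = P(5.0, 0.2)
        biv = simulate_gamma_bivalents(truth, 1.2, 600, rng)
        gd = genotype_gametes(thin_to_gametes(biv, rng), gmap, 0.0, rng)
        assert dataset_loglik(gd, truth) > dataset_loglik(gd, P(1.0, 0.0))
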