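import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xofit.io_data import BivalentDataset, ChromosomeFrame
from xofit.models import ModelSpec
from xofit.score import (
    Histogram,
    HistogramBins,
    ScoreSettings,
    build_histograms,
    model_histograms,
    projected_likelihood_score,
)


class TestBuildHistograms:
    def test_count_and_distance_definitions(self):
        frame = ChromosomeFrame(1.0, "morgan")
        data = BivalentDataset([[0.5], [0.1, 0.4, 0.9]], frame)
        hs = build_histograms(data)
        assert hs.count.counts[1] == 1 and hs.count.counts[3] == 1
        assert hs.distance.total == 2  # only the 3-CO cell contributes
        assert hs.n_records == 2

    def test_single_co_cells_contribute_no_distances(self):
        frame = ChromosomeFrame(1.0, "morgan")
        data = BivalentDataset([[0.5], [0.2]], frame)
        hs = build_histograms(data)
        assert hs.distance.total == 0

    def test_clopper_pearson_zero_bin_closed_form(self):
        frame = ChromosomeFrame(1.0, "morgan")
        n = 40
        data = BivalentDataset([[0.5]] * n, frame)
        hs = build_histograms(data)
        # a count bin with zero hits has CI [0, 1 - 0.025^(1/N)]
        assert hs.count.counts[0] == 0
        assert hs.count.ci_low[0] == 0.0
        assert hs.count.ci_high[0] == pytest.approx(
            1 - 0.025 ** (1 / n), rel=1e-9
        )
        # the full bin is the mirror image
        assert hs.count.ci_low[1] == pytest.approx(0.025 ** (1 / n), rel=1e-9)
        assert hs.count.ci_high[1] == 1.0

    def test_ci_contains_point_estimate(self, rng):
        frame = ChromosomeFrame(1.0, "morgan")
        cells = [rng.random(rng.poisson(2)) for _ in range(300)]
        hs = build_histograms(BivalentDataset(cells, frame))
        for h in (hs.count, hs.position, hs.distance):
            props = h.proportions
            assert np.all(h.ci_low <= props + 1e-12)
            assert np.all(h.ci_high >= props - 1e-12)

    def test_gamete_positions_are_recombinant_midpoints(self, tiny_gametes):
        hs = build_histograms(tiny_gametes)
        # g1 recombines in (0.3,0.7); g2 nowhere; g3 in merged (0,0.7);
        # g4 in both (0.3,0.7) and (0.7,1.0)
        assert hs.count.counts[0] == 1  # g2
        assert hs.count.counts[1] == 2  # g1, g3
        assert hs.count.counts[2] == 1  # g4
        assert hs.position.total == 4
        assert hs.distance.total == 1  # only g4 has successive events

    def test_empty_dataset_rejected(self):
        frame = ChromosomeFrame(1.0, "morgan")
        with pytest.raises(ValueError, match="empty"):
            build_histograms(BivalentDataset([], frame))


class TestModelHistograms:
    def test_poisson_counts_within_monte_carlo_error(self, small_bivalents):
        settings = ScoreSettings(n_sim=20_000, seed=3)
        hs = model_histograms(
            ModelSpec("gamma", 1.0), small_bivalents, settings
        )
        pk = stats.poisson.pmf(np.arange(hs.count.counts.size), 2.0)
        props = hs.count.proportions
        for k in range(6):
            se = np.sqrt(pk[k] * (1 - pk[k]) / settings.n_sim)
            assert abs(props[k] - pk[k]) < 4 * se

    def test_seeded_determinism(self, small_bivalents):
        settings = ScoreSettings(n_sim=10**4, seed=5)
        h1 = model_histograms(ModelSpec("gs", 3.0, 0.2), small_bivalents, settings)
        h2 = model_histograms(ModelSpec("gs", 3.0, 0.2), small_bivalents, settings)
        np.testing.assert_array_equal(h1.count.counts, h2.count.counts)
        np.testing.assert_array_equal(h1.distance.counts, h2.distance.counts)

    def test_gametic_design_mirrors_missing_pattern(self, tiny_gametes):
        settings = ScoreSettings(n_sim=10**4, seed=1)
        hs = model_histograms(ModelSpec("gamma", 2.0), tiny_gametes, settings)
        assert hs.n_records == settings.n_sim
        assert hs.L == pytest.approx(tiny_gametes.map.span)

    def test_unknown_family_rejected(self, small_bivalents):
        with pytest.raises(ValueError):
            ModelSpec("weibull", 2.0)


class TestProjectedLikelihoodScore:
    def _hist_pair(self, obs_counts, sim_props, n_sim=10**4):
        edges = np.arange(len(obs_counts) + 1) - 0.5
        obs = Histogram(edges, np.asarray(obs_counts), int(np.sum(obs_counts)))
        sim_counts = np.round(np.asarray(sim_props) * n_sim).astype(int)
        sim = Histogram(edges, sim_counts, int(sim_counts.sum()))
        return obs, sim

    def _score(self, obs, sim, **kw):
        from xofit.score import HistogramSet

        def wrap(h):
            return HistogramSet(
                count=h[0], position=h[0], distance=h[1], n_records=1, L=1.0
            )

        settings = ScoreSettings(n_sim=10**4, **kw)
        return projected_likelihood_score(
            wrap((obs[0], obs[1])), wrap((sim[0], sim[1])), settings
        )

    def test_matching_proportions_attain_multinomial_maximum(self):
        counts = np.array([10, 30, 60])
        obs, sim = self._hist_pair(counts, counts / counts.sum())
        res = self._score((obs, obs), (sim, sim), score_type="counts")
        ref = float(np.sum(counts * np.log(counts / counts.sum())))
        assert res.score == pytest.approx(ref, abs=1e-6)

    def test_zero_simulated_bin_floored(self):
        obs, sim = self._hist_pair([5, 5], [1.0, 0.0])
        res = self._score((obs, obs), (sim, sim), score_type="counts")
        assert np.isfinite(res.score)
        eps = ScoreSettings(n_sim=10**4).eps
        assert res.score == pytest.approx(5 * np.log(1.0) + 5 * np.log(eps))

    def test_score_type_counts_ignores_distances(self):
        obs_c, sim_c = self._hist_pair([10, 20], [0.4, 0.6])
        obs_d, sim_d = self._hist_pair([3, 7], [0.9, 0.1])
        res = self._score((obs_c, obs_d), (sim_c, sim_d), score_type="counts")
        assert res.score == pytest.approx(res.components["counts"])
        combined = self._score(
            (obs_c, obs_d), (sim_c, sim_d), score_type="combined"
        )
        assert combined.score == pytest.approx(
            combined.components["counts"] + combined.components["distances"]
        )

    def test_bin_mismatch_rejected(self):
        obs, _ = self._hist_pair([1, 2], [0.5, 0.5])
        _, sim = self._hist_pair([1, 2, 3], [0.2, 0.3, 0.5])
        with pytest.raises(ValueError, match="bins"):
            self._score((obs, obs), (sim, sim))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=3, max_size=8),
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8),
    )
    def test_gibbs_inequality(self, obs_counts, sim_weights):
        """No simulated distribution scores higher than the observed
        proportions themselves."""
        n = min(len(obs_counts), len(sim_weights))
        obs_counts = np.array(obs_counts[:n])
        if obs_counts.sum() == 0:
            obs_counts[0] = 1
        sim_props = np.array(sim_weights[:n])
        sim_props /= sim_props.sum()
        obs, sim = self._hist_pair(obs_counts, sim_props)
        at_sim = self._score((obs, obs), (sim, sim), score_type="counts").score
        obs_as_sim = Histogram(obs.edges, obs.counts, obs.total)
        at_obs = self._score(
            (obs, obs), (obs_as_sim, obs_as_sim), score_type="counts"
        ).score
        assert at_obs >= at_sim - 1e-9
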