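import json

import numpy as np
import pytest
from scipy import stats

from xofit.io_data import (
    GeneticMap,
    read_bivalent_positions,
    read_segregation,
)
from xofit.renewal import GammaSprinklingParams
from xofit.synthetic import (
    PRESETS,
    FixtureSpec,
    genotype_gametes,
    make_fixture,
    simulate_gamma_bivalents,
    thin_to_gametes,
)

P = GammaSprinklingParams


class TestSimulateGammaBivalents:
    def test_poisson_counts_at_nu_1(self, rng):
        data = simulate_gamma_bivalents(P(1.0), 1.0, 10**5, rng)
        counts = data.counts()
        kmax = 8
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pk = stats.poisson.pmf(np.arange(kmax + 1), 2.0)
        exp = np.append(pk[:kmax], 1 - pk[:kmax].sum()) * counts.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=kmax) > 0.01

    def test_integer_nu_matches_thinned_poisson_construction(self, rng):
        nu, L, n = 2, 1.0, 10**5
        data = simulate_gamma_bivalents(P(float(nu)), L, n, rng)
        counts = data.counts()
        lam = 2 * nu
        pts = np.cumsum(rng.exponential(1 / lam, size=(n, 30)), axis=1)
        phase = rng.integers(0, nu, size=n)
        kept = (np.arange(30)[None, :] % nu) == phase[:, None]
        ref = ((pts <= L) & kept).sum(axis=1)
        kmax = 7
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp_counts = np.bincount(np.minimum(ref, kmax), minlength=kmax + 1)
        table = np.stack([obs, exp_counts])
        _, pval, _, _ = stats.chi2_contingency(table[:, table.sum(0) > 0])
        assert pval > 0.01

    def test_pooled_positions_uniform(self, rng):
        data = simulate_gamma_bivalents(P(5.0, 0.2), 1.5, 20_000, rng)
        pooled = data.pooled_positions()
        hist, _ = np.histogram(pooled, bins=15, range=(0, 1.5))
        exp = pooled.size / 15
        chi2 = ((hist - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=14) > 0.01

    def test_intensity(self, rng):
        data = simulate_gamma_bivalents(P(5.0, 0.2), 1.5, 50_000, rng)
        assert data.counts().mean() == pytest.approx(3.0, abs=0.05)


class TestThinning:
    def test_half_intensity(self, rng):
        biv = simulate_gamma_bivalents(P(2.0), 1.0, 50_000, rng)
        gam = thin_to_gametes(biv, rng)
        ratio = gam.counts().mean() / biv.counts().mean()
        se = 0.5 / np.sqrt(biv.counts().sum())
        assert abs(ratio - 0.5) < 4 * se

    def test_two_co_bivalent_subsets_equally_likely(self, rng):
        from xofit.io_data import BivalentDataset, ChromosomeFrame

        frame = ChromosomeFrame(1.0, "morgan")
        biv = BivalentDataset([[0.2, 0.7]] * 4000, frame)
        gam = thin_to_gametes(biv, rng)
        keys = ["".join(f"{x:.1f}" for x in c) for c in gam.cells]
        obs = np.array([keys.count(k) for k in ("", "0.2", "0.7", "0.20.7")])
        chi2 = ((obs - 1000) ** 2 / 1000).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_empty_bivalent_stays_empty(self, rng):
        from xofit.io_data import BivalentDataset, ChromosomeFrame

        biv = BivalentDataset([[]], ChromosomeFrame(1.0, "morgan"))
        assert thin_to_gametes(biv, rng).cells[0].size == 0


class TestGenotyping:
    def test_alleles_flip_across_crossover(self, rng):
        from xofit.io_data import BivalentDataset, ChromosomeFrame

        gmap = GeneticMap(("m1", "m2"), np.array([0.1, 0.5]))
        gam = BivalentDataset([[0.3]], ChromosomeFrame(1.0, "morgan"))
        gd = genotype_gametes(gam, gmap, 0.0, rng)
        row = gd.genotypes.iloc[0]
        assert row["m1"] != row["m2"]

    def test_no_crossover_constant_genotype(self, rng):
        from xofit.io_data import BivalentDataset, ChromosomeFrame

        gmap = GeneticMap(("m1", "m2", "m3"), np.array([0.1, 0.5, 0.9]))
        gam = BivalentDataset([[]], ChromosomeFrame(1.0, "morgan"))
        gd = genotype_gametes(gam, gmap, 0.0, rng)
        assert gd.genotypes.iloc[0].nunique() == 1

    def test_full_missing_rate_masks_everything(self, rng):
        from xofit.io_data import BivalentDataset, ChromosomeFrame

        gmap = GeneticMap(("m1", "m2"), np.array([0.1, 0.5]))
        gam = BivalentDataset([[0.3]] * 5, ChromosomeFrame(1.0, "morgan"))
        gd = genotype_gametes(gam, gmap, 1.0, rng)
        assert gd.genotypes.isna().all().all()


class TestFixtures:
    def test_round_trip_exact(self, tmp_path):
        spec = FixtureSpec(model=P(4.0, 0.1), seed=9, kind="bivalent",
                           n_cells=50, L=1.2)
        make_fixture(spec, tmp_path / "fx")
        data = read_bivalent_positions(tmp_path / "fx" / "positions.txt")
        assert data.n_cells == 50
        assert data.frame.length_morgans == pytest.approx(1.2)

    def test_same_seed_byte_identical(self, tmp_path):
        spec = FixtureSpec(model=P(4.0, 0.1), seed=9, kind="gamete",
                           n_cells=30, L=1.0, n_markers=6, missing_rate=0.1)
        make_fixture(spec, tmp_path / "a")
        make_fixture(spec, tmp_path / "b")
        for name in ("genotypes.tsv", "map.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_gamete_fixture_reads_back(self, tmp_path):
        spec = FixtureSpec(model=P(4.0, 0.1), seed=2, kind="gamete",
                           n_cells=40, L=1.0, n_markers=6)
        make_fixture(spec, tmp_path / "fx")
        gd = read_segregation(
            tmp_path / "fx" / "genotypes.tsv", tmp_path / "fx" / "map.tsv"
        )
        assert gd.n_gametes == 40
        assert gd.map.span == pytest.approx(1.0)

    def test_backcross_recombination_rate_matches_map_length(self, tmp_path):
        """A gamete carries on average (map length in Morgans) crossovers."""
        spec = FixtureSpec(model=P(6.0, 0.1), seed=5, kind="gamete",
                           n_cells=2000, L=0.8, n_markers=12)
        make_fixture(spec, tmp_path / "fx")
        gd = read_segregation(
            tmp_path / "fx" / "genotypes.tsv", tmp_path / "fx" / "map.tsv"
        )
        rec_counts = [
            sum(r for _, _, r in tokens) for tokens in gd.partitions()
        ]
        # parity undercounts double crossovers slightly; generous bound
        assert np.mean(rec_counts) == pytest.approx(0.8, abs=0.08)

    def test_mouse_preset_structure(self, tmp_path):
        manifest = PRESETS["mouse_backcross"](3, tmp_path / "mouse")
        assert len(manifest["chromosomes"]) == 20
        chr1 = json.loads(
            (tmp_path / "mouse" / "chr01" / "manifest.json").read_text()
        )
        assert chr1["n_cells"] == 200
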