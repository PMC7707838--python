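"""Generator behavior: meiosis statistics, trait model, sorting, sequencing."""

import numpy as np
import pandas as pd
import pytest

from dualqtl.synthetic_cross import (
    CrossConfig,
    DepthModel,
    GenotypeMatrix,
    PlantedQTL,
    SortConfig,
    TraitModel,
    default_config,
    default_trait_model,
    expected_delta_af,
    sequence_pool,
    simulate_phenotypes,
    simulate_segregants,
    sort_pools,
)


def _two_marker_config(distance_bp, n, seed=0):
    return CrossConfig(
        chromosomes={"chrI": 10_000_000},
        markers={"chrI": np.array([1000, 1000 + distance_bp])},
        n_segregants=n,
        seed=seed,
    )


class TestSimulateSegregants:
    def test_zero_distance_means_identical_columns(self):
        # positions must strictly increase, so zero recombination is reached
        # via an explicit r=0 equivalent: 1 bp apart => r ~ 4.5e-6
        cfg = _two_marker_config(1, 2000, seed=3)
        g = simulate_segregants(cfg)
        switch_fraction = (g.alleles[:, 0] != g.alleles[:, 1]).mean()
        assert switch_fraction < 0.005

    def test_switch_fraction_matches_map_scale(self):
        # 2,200 bp = 1 cM => recombination fraction 0.01
        n = 10_000
        g = simulate_segregants(_two_marker_config(2200, n, seed=4))
        observed = (g.alleles[:, 0] != g.alleles[:, 1]).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(observed - 0.01) < 3 * se

    def test_allele_frequency_is_half(self):
        n = 10_000
        g = simulate_segregants(_two_marker_config(2200, n, seed=5))
        af = g.by_frequency()
        assert np.all(np.abs(af - 0.5) < 3 * np.sqrt(0.25 / n))

    def test_deterministic_given_seed(self):
        a = simulate_segregants(_two_marker_config(5000, 500, seed=9))
        b = simulate_segregants(_two_marker_config(5000, 500, seed=9))
        np.testing.assert_array_equal(a.alleles, b.alleles)

    def test_unlinked_chromosomes_and_long_gaps_cap_at_half(self):
        cfg = _two_marker_config(1_000_000, 20_000, seed=6)  # r capped at 0.5
        g = simulate_segregants(cfg)
        observed = (g.alleles[:, 0] != g.alleles[:, 1]).mean()
        assert abs(observed - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_chromosome_without_markers_is_skipped_with_warning(self):
        cfg = CrossConfig(
            chromosomes={"chrI": 1000, "chrII": 1000},
            markers={"chrI": np.array([10, 500]), "chrII": np.array([], dtype=int)},
            n_segregants=10,
        )
        with pytest.warns(UserWarning, match="chrII"):
            g = simulate_segregants(cfg)
        assert set(g.markers["chrom"]) == {"chrI"}

    def test_nonincreasing_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increase"):
            CrossConfig(
                chromosomes={"chrI": 1000},
                markers={"chrI": np.array([100, 100])},
                n_segregants=5,
            )


class TestSimulatePhenotypes:
    def _genotypes(self, n=1000, seed=0):
        cfg = _two_marker_config(500_000, n, seed=seed)
        return simulate_segregants(cfg)

    def test_no_effects_no_noise_gives_constant_signal(self):
        g = self._genotypes()
        model = TraitModel(
            a=np.zeros(2), b=np.zeros(2), sigma_r=0, sigma_g=0, gamma=0
        )
        ph = simulate_phenotypes(g, model, seed=1)
        assert np.ptp(ph.R) == 0 and np.ptp(ph.G) == 0

    def test_concordant_locus_perfectly_couples_channels(self):
        g = self._genotypes()
        model = TraitModel(
            a=np.array([1.0, 0.0]), b=np.zeros(2), kappa=1.0,
            sigma_r=0, sigma_g=0, gamma=0,
        )
        ph = simulate_phenotypes(g, model, seed=1)
        assert np.corrcoef(ph.R, ph.G)[0, 1] == pytest.approx(1.0)
        # BY (0) allele should carry the higher value: +a/2
        assert set(np.round(ph.R, 9)) == {0.5, -0.5}
        assert np.all(ph.R[g.alleles[:, 0] == 0] == 0.5)

    def test_buffered_locus_cancels_in_protein_channel(self):
        g = self._genotypes(n=50_000, seed=2)
        model = TraitModel(
            a=np.array([1.0, 0.0]), b=np.array([-1.0, 0.0]), kappa=1.0,
            sigma_r=0.5, sigma_g=0.5, gamma=0,
        )
        ph = simulate_phenotypes(g, model, seed=3)
        x = g.alleles[:, 0]
        assert abs(np.corrcoef(ph.G, x)[0, 1]) < 0.02
        # RM allele (1) decreases the mRNA signal
        assert np.corrcoef(ph.R, x)[0, 1] < -0.5

    def test_mismatched_effect_length_raises(self):
        g = self._genotypes()
        with pytest.raises(ValueError, match="markers"):
            simulate_phenotypes(g, TraitModel(a=np.zeros(5), b=np.zeros(5)), 0)


class TestSortPools:
    def _phenotypes(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, n)
        from dualqtl.synthetic_cross import CellPhenotypes

        return CellPhenotypes(
            R=vals, G=vals.copy(), FSC=np.full(n, 100.0), t=vals, s=np.zeros(n)
        )

    def test_exact_tails_selected(self):
        ph = self._phenotypes(1000)
        sort = SortConfig(q=0.1, pool_size=100, fsc_band=(0.0, 1.0))
        mem = sort_pools(ph, sort, "mRNA", seed=1)
        assert len(mem.high) == 100 and len(mem.low) == 100
        order = np.argsort(ph.R)
        assert set(mem.low) == set(order[:100])
        assert set(mem.high) == set(order[-100:])

    def test_high_pool_dominates_low_pool(self):
        ph = self._phenotypes(5000, seed=2)
        mem = sort_pools(ph, SortConfig(q=0.05, pool_size=50), "protein", seed=1)
        assert ph.G[mem.high].min() >= ph.G[mem.low].max()

    def test_pools_are_disjoint(self):
        ph = self._phenotypes(5000, seed=3)
        mem = sort_pools(ph, SortConfig(q=0.05, pool_size=500), "mRNA", seed=1)
        pools = [set(mem.high), set(mem.low), set(mem.unsorted)]
        assert not (pools[0] & pools[1]) and not (pools[0] | pools[1]) & pools[2]

    def test_concordant_qtl_enriches_by_allele_in_high_pool(self):
        cfg = _two_marker_config(500_000, 20_000, seed=7)
        g = simulate_segregants(cfg)
        model = TraitModel(
            a=np.array([1.0, 0.0]), b=np.zeros(2), sigma_r=1.0, sigma_g=1.0, gamma=0
        )
        ph = simulate_phenotypes(g, model, seed=8)
        mem = sort_pools(ph, SortConfig(), "mRNA", seed=9)
        af = g.by_frequency(mem.high)[0]
        assert af > 0.5
        assert g.by_frequency(mem.low)[0] < 0.5

    def test_too_few_cells_errors_with_requirement(self):
        ph = self._phenotypes(20)
        with pytest.raises(ValueError, match="34"):
            sort_pools(ph, SortConfig(q=0.03, fsc_band=(0.0, 1.0)), "mRNA")


class TestSequencePool:
    def _simple_genotypes(self, alleles):
        m = alleles.shape[1]
        return GenotypeMatrix(
            alleles,
            pd.DataFrame({"chrom": "chrI", "pos": np.arange(1, m + 1) * 100}),
        )

    def test_zero_depth_model(self):
        g = self._simple_genotypes(np.zeros((4, 6), dtype=np.int8))
        counts = sequence_pool(g, np.arange(4), DepthModel(mean_depth=0), seed=1)
        assert (counts.depth == 0).all()

    def test_pure_by_pool_without_error_gives_only_reference_reads(self):
        g = self._simple_genotypes(np.zeros((10, 8), dtype=np.int8))
        counts = sequence_pool(
            g, np.arange(10), DepthModel(mean_depth=20, error_rate=0), seed=2
        )
        assert (counts.alt == 0).all() and counts.depth.sum() > 0

    def test_balanced_pool_frequency_within_binomial_error(self):
        alleles = np.array([[0] * 10, [1] * 10], dtype=np.int8)
        g = self._simple_genotypes(alleles)
        counts = sequence_pool(
            g, np.array([0, 1]), DepthModel(mean_depth=1000, error_rate=0), seed=3
        )
        frac = counts.ref / counts.depth
        assert np.all(np.abs(frac - 0.5) < 3 * np.sqrt(0.25 / counts.depth))

    def test_empty_pool_rejected(self):
        g = self._simple_genotypes(np.zeros((2, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="no members"):
            sequence_pool(g, np.array([], dtype=int), DepthModel(), seed=0)


class TestTruthModel:
    def test_expected_delta_af_sign_and_monotonicity(self):
        small = expected_delta_af(0.2, 1.0, q=0.03)
        large = expected_delta_af(0.5, 1.0, q=0.03)
        assert 0 < small < large < 1
        assert expected_delta_af(-0.2, 1.0, q=0.03) == pytest.approx(-small)
        assert expected_delta_af(0.0, 1.0) == 0.0

    def test_default_model_plants_all_four_classes(self):
        cfg = default_config(n_segregants=100)
        model = default_trait_model(cfg)
        classes = {q.qtl_class for q in model.planted}
        assert classes == {
            "concordant",
            "protein_specific",
            "mrna_specific",
            "discordant",
        }
        for q in model.planted:
            if q.qtl_class == "mrna_specific":
                assert model.channel_effect(q, "protein") == pytest.approx(0.0)
            if q.qtl_class == "discordant":
                assert (
                    np.sign(model.channel_effect(q, "protein"))
                    == -np.sign(model.channel_effect(q, "mRNA"))
                )

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            PlantedQTL("chrI", 100, "mystery", a=1.0, b=0.0)
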