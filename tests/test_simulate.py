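"""Founder drawing, meiosis, pedigree assembly and switch-error injection."""

import numpy as np
import pytest

import crossphase as cp
from crossphase.simulate import meiosis, simulate_founders, simulate_genetic_map


class TestFounders:
    def test_law_of_large_numbers(self, rng):
        freqs = np.full(5000, 0.5)
        haps = simulate_founders(rng, freqs, 1)
        assert abs(haps.mean() - 0.5) < 0.02

    def test_configured_frequencies_recovered(self, rng):
        freqs = rng.uniform(0.05, 0.5, 400)
        haps = simulate_founders(rng, freqs, 500)
        emp = haps.mean(axis=(0, 1))
        assert np.abs(emp - freqs).max() < 0.08

    def test_seeded_determinism(self):
        cfg = cp.SimulationConfig(
            seed=3, n_unrelated=20, n_focal=1, n_focal_no_relatives=0,
            n_chromosomes=2, snps_per_chromosome=100,
        )
        a, b = cp.build_cohort(cfg), cp.build_cohort(cfg)
        assert a.cohort.sample_ids == b.cohort.sample_ids
        for chrom in a.cohort.chromosomes:
            np.testing.assert_array_equal(
                a.cohort.haplotypes[chrom], b.cohort.haplotypes[chrom]
            )
            np.testing.assert_array_equal(
                a.truth[a.focal_ids[0]].origin[chrom], b.truth[b.focal_ids[0]].origin[chrom]
            )


class TestMeiosis:
    def test_zero_crossovers_copies_one_parent(self, rng):
        pos = np.linspace(0, 0.001, 50)  # ~Poisson(1e-5): no crossover
        a = rng.integers(0, 2, 50).astype(np.uint8)
        b = 1 - a
        gamete, xpos = meiosis(a, b, pos, 0.001, rng)
        assert len(xpos) == 0
        assert np.array_equal(gamete, a) or np.array_equal(gamete, b)

    def test_mean_crossover_count_is_length_in_morgans(self, rng):
        pos = np.linspace(0, 100, 10)
        a = np.zeros(10, np.uint8)
        counts = [len(meiosis(a, a, pos, 100.0, rng)[1]) for _ in range(2000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.08)

    def test_gamete_alternates_at_crossovers(self, rng):
        pos = np.linspace(0, 100, 1000)
        a = np.zeros(1000, np.uint8)
        b = np.ones(1000, np.uint8)
        for _ in range(20):
            gamete, xpos = meiosis(a, b, pos, 100.0, rng)
            switches = int((np.diff(gamete.astype(int)) != 0).sum())
            assert switches == len(np.unique(np.searchsorted(pos, xpos))) or switches <= len(xpos)


class TestBuildCohort:
    def test_mendelian_consistency_of_every_trio(self, tiny_sim):
        for fid in tiny_sim.focal_ids:
            f = tiny_sim.cohort.sample_index(fid)
            p1, p2 = tiny_sim.parents[fid]
            for chrom in tiny_sim.cohort.chromosomes:
                child = tiny_sim.cohort.diploid(chrom)[f]
                g1 = tiny_sim.parent_genotypes[p1][chrom]
                g2 = tiny_sim.parent_genotypes[p2][chrom]
                lo = (g1 == 2).astype(int) + (g2 == 2).astype(int)
                hi = (g1 > 0).astype(int) + (g2 > 0).astype(int)
                assert ((child >= lo) & (child <= hi)).all()

    def test_truth_matches_transmitted_alleles(self, tiny_sim):
        """At every heterozygous focal site, the recorded parent-1 allele is
        one of the two alleles the focal actually carries."""
        for fid in tiny_sim.focal_ids:
            f = tiny_sim.cohort.sample_index(fid)
            for chrom in tiny_sim.cohort.chromosomes:
                o = tiny_sim.truth[fid].origin[chrom]
                res = (o == 0) | (o == 1)
                het = tiny_sim.cohort.diploid(chrom)[f] == 1
                np.testing.assert_array_equal(res, het)  # every het site resolved

    def test_planted_relationship_kinship(self):
        sim = cp.build_cohort(
            cp.SimulationConfig(
                seed=21, n_unrelated=60, n_focal=2, n_focal_no_relatives=0,
                relative_degrees=(2,), n_chromosomes=5, snps_per_chromosome=2000,
                chromosome_length_cM=100.0,
            )
        )
        cohort = cp.qc_filter(sim.cohort)
        for fid in sim.focal_ids:
            ph = cp.pihat_to_all(cohort, fid)
            uncle = sim.relatives[fid][0][0]
            assert 0.1 < ph[cohort.sample_index(uncle)] < 0.4

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cp.SimulationConfig(switch_error_rate=1.5)
        with pytest.raises(ValueError):
            cp.SimulationConfig(relative_degrees=(7,))


class TestSwitchErrors:
    def test_rate_zero_is_identity(self, tiny_sim):
        out = cp.inject_switch_errors(tiny_sim, 0.0, seed=9)
        for chrom in tiny_sim.cohort.chromosomes:
            np.testing.assert_array_equal(
                out.cohort.haplotypes[chrom], tiny_sim.cohort.haplotypes[chrom]
            )
        assert out.switch_positions == {}

    def test_expected_switch_count(self, tiny_sim):
        rate = 0.02
        out = cp.inject_switch_errors(tiny_sim, rate, seed=9)
        n_het = sum(
            int((tiny_sim.cohort.diploid(c) == 1).sum())
            for c in tiny_sim.cohort.chromosomes
        )
        n_switch = sum(len(v) for v in out.switch_positions.values())
        expect = rate * n_het
        assert abs(n_switch - expect) < 4 * np.sqrt(expect)

    def test_recounted_switch_rate(self, tiny_sim):
        """An independent switch counter recovers the injected positions."""
        rate = 0.05
        out = cp.inject_switch_errors(tiny_sim, rate, seed=13)
        s = tiny_sim.cohort.sample_ids[0]
        i = tiny_sim.cohort.sample_index(s)
        for chrom in tiny_sim.cohort.chromosomes:
            before = tiny_sim.cohort.haplotypes[chrom][:, i, :]
            after = out.cohort.haplotypes[chrom][:, i, :]
            het = (before[0] != before[1])
            phase = (after[0] != before[0])[het]  # True where slots are swapped
            recount = int((np.diff(phase.astype(int)) != 0).sum()) + int(phase[0] if len(phase) else 0)
            injected = len(out.switch_positions.get((s, chrom), []))
            assert recount == injected

    def test_genotypes_unchanged(self, tiny_sim):
        out = cp.inject_switch_errors(tiny_sim, 0.1, seed=5)
        for chrom in tiny_sim.cohort.chromosomes:
            np.testing.assert_array_equal(
                out.cohort.diploid(chrom), tiny_sim.cohort.diploid(chrom)
            )


class TestSubpopulations:
    def test_allele_frequency_divergence_scales_with_fst(self, rng):
        anchors = simulate_genetic_map(rng, 80.0, 10**7)
        assert (np.diff(anchors["cM"]) >= 0).all()
        sim = cp.build_cohort(
            cp.SimulationConfig(
                seed=8, n_unrelated=400, n_focal=0, n_focal_no_relatives=0,
                relative_degrees=(), n_chromosomes=2, snps_per_chromosome=800,
                subpopulations=cp.SubpopulationConfig(fst=0.1),
            )
        )
        pops = {0: [], 1: []}
        for u, s in enumerate(sim.cohort.sample_ids):
            pops[u % 2].append(s)
        chrom = sim.cohort.chromosomes[0]
        idx0 = [sim.cohort.sample_index(s) for s in pops[0]]
        idx1 = [sim.cohort.sample_index(s) for s in pops[1]]
        hap = sim.cohort.haplotypes[chrom]
        f0 = hap[:, idx0, :].mean(axis=(0, 1))
        f1 = hap[:, idx1, :].mean(axis=(0, 1))
        p = (f0 + f1) / 2
        ok = (p > 0.05) & (p < 0.95)
        fst_emp = np.mean(((f0 - f1) ** 2 / (4 * p * (1 - p)))[ok]) - 1 / (2 * len(idx0))
        assert 0.03 < fst_emp < 0.25
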