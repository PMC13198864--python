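"""Diploid relatedness, windowed haploid similarity and the psi-star tensor."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crossphase as cp
from crossphase._kernels import best_run_sums
from crossphase.similarity import psi_window


def psi_brute(focal_hap, other_hap, het_mask, maf, exponent=0.2):
    """Oracle: scan every contiguous run of the het-restricted haplotypes."""
    fh = np.asarray(focal_hap)[het_mask]
    oh = np.asarray(other_hap)[het_mask]
    p = np.asarray(maf, dtype=float)[het_mask]
    L = len(fh)
    best_len, best_sum = 0, 0.0
    for a in range(L):
        for b in range(a + 1, L + 1):
            if np.all(fh[a:b] == oh[a:b]):
                s = float((((fh[a:b] - p[a:b]) ** 2 / (p[a:b] * (1 - p[a:b]))) ** exponent).sum())
                if (b - a) > best_len or ((b - a) == best_len and s > best_sum):
                    best_len, best_sum = b - a, s
    return best_sum


def random_case(rng, max_sites=50):
    m = int(rng.integers(1, max_sites + 1))
    fh = rng.integers(0, 2, m).astype(np.uint8)
    oh = np.where(rng.random(m) < 0.6, fh, 1 - fh).astype(np.uint8)
    het = rng.random(m) < 0.7
    p = rng.uniform(0.05, 0.5, m)
    return fh, oh, het, p


class TestPihat:
    def test_single_snp_identical_homozygotes(self):
        assert cp.pihat([2], [2], [0.5]) == pytest.approx(2.0)

    def test_single_snp_opposite_homozygotes(self):
        assert cp.pihat([2], [0], [0.5]) == pytest.approx(-2.0)

    def test_length_mismatch_and_bad_maf_raise(self):
        with pytest.raises(ValueError):
            cp.pihat([1, 2], [1], [0.5, 0.5])
        with pytest.raises(ValueError):
            cp.pihat([1], [1], [0.0])

    def test_matrix_matches_pairwise_definition(self, tiny_prepared):
        _, cohort, _ = tiny_prepared
        s0, s5 = cohort.sample_ids[0], cohort.sample_ids[5]
        g = cohort.diploid_genome()
        direct = cp.pihat(g[0], g[5], cohort.maf_genome())
        assert cp.pihat_to_all(cohort, s0)[5] == pytest.approx(direct, abs=1e-4)


class TestExcludeCloseRelatives:
    def test_parents_excluded_uncle_retained(self):
        sim = cp.build_cohort(
            cp.SimulationConfig(
                seed=5, n_unrelated=40, n_focal=1, n_focal_no_relatives=0,
                relative_degrees=(2,), n_chromosomes=4, snps_per_chromosome=2500,
                include_parents=True,
            )
        )
        cohort = cp.qc_filter(sim.cohort)
        fid = sim.focal_ids[0]
        partners, excluded = cp.exclude_close_relatives(cohort, fid)
        p1, p2 = sim.parents[fid]
        assert p1 in excluded and p2 in excluded
        uncle = sim.relatives[fid][0][0]
        assert uncle in partners

    def test_unrelated_cohort_nobody_excluded(self, tiny_prepared):
        tiny, cohort, _ = tiny_prepared
        unrel = [s for s in cohort.sample_ids if s.startswith("unrel")]
        partners, excluded = cp.exclude_close_relatives(cohort, unrel[0])
        assert excluded == []

    def test_threshold_above_two_is_noop(self, tiny_prepared):
        _, cohort, _ = tiny_prepared
        partners, excluded = cp.exclude_close_relatives(cohort, cohort.sample_ids[0], 2.5)
        assert len(partners) == cohort.n - 1 and excluded == []


class TestPsiWindow:
    def test_three_identical_minor_sites_at_half(self):
        fh = np.array([1, 1, 1], dtype=np.uint8)
        het = np.ones(3, dtype=bool)
        p = np.full(3, 0.5)
        assert psi_window(fh, fh.copy(), het, p) == pytest.approx(3.0)

    def test_all_mismatch_gives_zero(self):
        fh = np.array([1, 0, 1], dtype=np.uint8)
        assert psi_window(fh, 1 - fh, np.ones(3, bool), np.full(3, 0.5)) == 0.0

    def test_longest_run_not_total(self):
        # match pattern (m, m, x, m, m, m): run of 3 wins over run of 2
        fh = np.array([1, 1, 0, 1, 1, 1], dtype=np.uint8)
        oh = np.array([1, 1, 1, 1, 1, 1], dtype=np.uint8)
        psi = psi_window(fh, oh, np.ones(6, bool), np.full(6, 0.5))
        assert psi == pytest.approx(3.0)

    def test_no_het_site_returns_zero(self):
        fh = np.array([1, 1], dtype=np.uint8)
        assert psi_window(fh, fh, np.zeros(2, bool), np.full(2, 0.5)) == 0.0

    def test_rare_match_weighting_is_damped(self):
        """A minor match at p=0.05 outweighs one at p=0.5, but < 5-fold."""
        het = np.ones(1, bool)
        one = np.array([1], dtype=np.uint8)
        rare = psi_window(one, one, het, np.array([0.05]))
        common = psi_window(one, one, het, np.array([0.5]))
        assert common == pytest.approx(1.0)
        assert 1.0 < rare < 5.0

    @given(st.integers(0, 10_000))
    def test_brute_force_equivalence(self, case_seed):
        rng = np.random.default_rng(case_seed)
        fh, oh, het, p = random_case(rng)
        expect = psi_brute(fh, oh, het, p)
        assert psi_window(fh, oh, het, p) == pytest.approx(expect)
        # the JIT kernel used for cohort-scale tensors agrees too
        terms = ((fh[het].astype(float) - p[het]) ** 2 / (p[het] * (1 - p[het]))) ** 0.2
        got = best_run_sums((oh[het] == fh[het])[None, :], terms)[0]
        assert got == pytest.approx(expect)


class TestPsiStar:
    def test_max_then_power(self, tiny_prepared):
        _, cohort, windows = tiny_prepared
        w = windows[0]
        f, i = cohort.sample_ids[0], cohort.sample_ids[1]
        sl = slice(w.snp_start, w.snp_stop)
        fidx = cohort.sample_index(f)
        het = cohort.diploid(w.chrom)[fidx, sl] == 1
        maf = cohort.variants[w.chrom]["maf"].to_numpy(float)[sl]
        hap = cohort.haplotypes[w.chrom]
        vals = [
            psi_window(hap[0, fidx, sl], hap[s, cohort.sample_index(i), sl], het, maf)
            for s in (0, 1)
        ]
        assert cp.psi_star(0, f, i, w, cohort) == pytest.approx(max(vals) ** 2)

    def test_partner_slot_swap_invariance(self, tiny_prepared):
        _, cohort, windows = tiny_prepared
        w = windows[1]
        f, i = cohort.sample_ids[0], cohort.sample_ids[2]
        before = cp.psi_star(1, f, i, w, cohort)
        swapped = cohort.copy()
        j = swapped.sample_index(i)
        hap = swapped.haplotypes[w.chrom]
        a = hap[0, j].copy()
        hap[0, j] = hap[1, j]
        hap[1, j] = a
        assert cp.psi_star(1, f, i, w, swapped) == pytest.approx(before)


class TestPsiStarTensor:
    def test_shape_sign_and_partner_axis(self, tiny_prepared):
        tiny, cohort, windows = tiny_prepared
        fid = tiny.focal_ids[0]
        t = cp.build_psi_star_tensor(cohort, fid, windows)
        assert t.values.shape == (2, len(windows), len(t.partner_ids))
        assert (t.values >= 0).all()
        assert fid not in t.partner_ids

    def test_partner_permutation_equivariance(self, tiny_prepared):
        tiny, cohort, windows = tiny_prepared
        fid = tiny.focal_ids[0]
        partners, _ = cp.exclude_close_relatives(cohort, fid)
        t1 = cp.build_psi_star_tensor(cohort, fid, windows, partners=partners[:40])
        perm = partners[:40][::-1]
        t2 = cp.build_psi_star_tensor(cohort, fid, windows, partners=perm)
        np.testing.assert_allclose(t1.values, t2.values[:, :, ::-1])

    def test_partner_window_label_flip_changes_nothing(self, tiny_prepared):
        """Flipping a partner's haplotype labels inside one window leaves
        every psi-star value unchanged (robustness to partner switch errors)."""
        tiny, cohort, windows = tiny_prepared
        fid = tiny.focal_ids[0]
        partners, _ = cp.exclude_close_relatives(cohort, fid)
        sub = partners[:30]
        t1 = cp.build_psi_star_tensor(cohort, fid, windows, partners=sub)
        mod = cohort.copy()
        w = windows[2]
        j = mod.sample_index(sub[7])
        hap = mod.haplotypes[w.chrom]
        sl = slice(w.snp_start, w.snp_stop)
        a = hap[0, j, sl].copy()
        hap[0, j, sl] = hap[1, j, sl]
        hap[1, j, sl] = a
        t2 = cp.build_psi_star_tensor(mod, fid, windows, partners=sub)
        np.testing.assert_allclose(t1.values, t2.values)

    def test_planted_shared_segment_is_outlier(self, tiny_prepared):
        tiny, cohort, windows = tiny_prepared
        fid = tiny.focal_ids[0]
        partners, _ = cp.exclude_close_relatives(cohort, fid)
        sub = list(partners[:30])
        mod = cohort.copy()
        w = windows[0]
        f = mod.sample_index(fid)
        j = mod.sample_index(sub[4])
        sl = slice(w.snp_start, w.snp_stop)
        # copy a long stretch of the focal's A haplotype into the partner
        mod.haplotypes[w.chrom][0, j, sl] = mod.haplotypes[w.chrom][0, f, sl]
        t = cp.build_psi_star_tensor(mod, fid, windows, partners=sub)
        vec = t.values[0, w.index]
        assert vec[4] > 20 * np.median(vec)
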