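import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popgenkit.core_stats import (
    bh_fdr,
    block_fst,
    compare_pi_ztest,
    d_prime_r2,
    ehh,
    fay_wu_h_norm,
    find_ld_block,
    fst_scan,
    h12,
    h12_scan,
    hudson_fst,
    nsl,
    nucleotide_diversity,
    pbs,
    select_core_region,
    tajimas_d,
)
from popgenkit.types import DiversityResult, HaplotypeMatrix, Region, SiteFreq

from conftest import random_matrix


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

class TestHudsonFst:
    def test_worked_example(self):
        # JPT n=208 T=131 vs CHB n=206 T=51
        rec = hudson_fst(SiteFreq(131, 208), SiteFreq(51, 206))
        assert round(rec.fst, 4) == 0.2547

    def test_identical_freqs_clamped_to_zero(self):
        rec = hudson_fst(SiteFreq(50, 100), SiteFreq(50, 100), clamp=True)
        assert rec.fst == 0.0
        assert rec.raw < 0  # finite-sample correction pushes it negative
        assert rec.clamped

    def test_algebraic_identity_1000_draws(self, rng):
        # FST == 1 - Hw/Hb with Hw, Hb as independent oracle expressions
        for _ in range(1000):
            n1, n2 = int(rng.integers(2, 500)), int(rng.integers(2, 500))
            c1, c2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            rec = hudson_fst(SiteFreq(c1, n1), SiteFreq(c2, n2))
            p1, p2 = c1 / n1, c2 / n2
            hw = p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)
            hb = p1 * (1 - p2) + p2 * (1 - p1)
            if hb == 0:
                assert not rec.defined
            else:
                assert rec.raw == pytest.approx(1 - hw / hb, abs=1e-12)

    def test_undefined_when_both_monomorphic(self):
        rec = hudson_fst(SiteFreq(0, 10), SiteFreq(0, 10))
        assert not rec.defined

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            hudson_fst(SiteFreq(1, 1), SiteFreq(1, 2))


class TestFstScan:
    def _pair(self, rng, n_sites=10):
        a = random_matrix(rng, 6, n_sites)
        b = HaplotypeMatrix(
            random_matrix(rng, 8, n_sites).alleles, a.positions, a.site_ids, None, a.chrom
        )
        return a, b

    def test_fixed_difference_gives_one(self, rng):
        a, b = self._pair(rng)
        a.alleles[:, 3] = 1
        b.alleles[:, 3] = 0
        scan = fst_scan(a, b)
        assert scan.loc[scan["site_id"] == a.site_ids[3], "fst"].iloc[0] == pytest.approx(1.0)

    def test_exclusion_region_dropped(self, rng):
        a, b = self._pair(rng)
        excl = Region(a.chrom, int(a.positions[2]), int(a.positions[4]))
        scan = fst_scan(a, b, exclusions=[excl])
        assert not scan["pos"].between(excl.start, excl.end).any()

    def test_sitewise_oracle(self, rng):
        a, b = self._pair(rng, n_sites=200)
        scan = fst_scan(a, b, clamp=False)
        for _, row in scan.sample(30, random_state=0).iterrows():
            j = a.site_ids.index(row["site_id"])
            rec = hudson_fst(
                SiteFreq(int(a.alleles[:, j].sum()), a.n_haplotypes),
                SiteFreq(int(b.alleles[:, j].sum()), b.n_haplotypes),
            )
            assert row["raw"] == pytest.approx(rec.raw, abs=1e-12)

    def test_mismatched_sites_rejected(self, rng):
        a = random_matrix(rng, 4, 5)
        b = random_matrix(rng, 4, 5)
        with pytest.raises(ValueError):
            fst_scan(a, b)


class TestBlockFst:
    def _scan_df(self, positions, fsts):
        import pandas as pd

        return pd.DataFrame(
            {"site_id": [f"s{i}" for i in range(len(positions))],
             "pos": positions, "fst": fsts, "raw": fsts,
             "defined": [True] * len(positions)}
        )

    def test_constant_scan(self):
        scan = self._scan_df(list(range(100, 1100, 100)), [0.1] * 10)
        out = block_fst(scan, window_bp=500)
        assert np.allclose(out["mean_fst"].dropna(), 0.1)

    def test_elevated_block_ranks_first(self):
        pos = list(range(100, 2100, 100))
        fst = [0.05] * 20
        for i in range(5, 10):
            fst[i] = 0.5
        out = block_fst(self._scan_df(pos, fst), window_bp=500, start=100)
        top = out.loc[out["rank"] == 1].iloc[0]
        assert top["start_bp"] <= pos[5] <= top["end_bp"]

    def test_empty_window_undefined(self):
        scan = self._scan_df([100, 2000], [0.1, 0.2])
        out = block_fst(scan, window_bp=500, start=100)
        assert math.isnan(out.loc[out["n_sites"] == 0, "mean_fst"].iloc[0])


# ---------------------------------------------------------------------------
# diversity + z-test
# ---------------------------------------------------------------------------

class TestNucleotideDiversity:
    def test_identical_haplotypes(self):
        m = HaplotypeMatrix(np.zeros((4, 10), dtype=np.int8), np.arange(1, 11))
        assert nucleotide_diversity(m).pi == 0.0

    def test_one_difference_in_100(self):
        alleles = np.zeros((2, 100), dtype=np.int8)
        alleles[0, 42] = 1
        m = HaplotypeMatrix(alleles, np.arange(1, 101))
        assert nucleotide_diversity(m).pi == pytest.approx(0.01)

    def test_brute_force_hamming_oracle(self, small_matrix):
        res = nucleotide_diversity(small_matrix)
        h = small_matrix.alleles
        n, L = h.shape
        total = sum(
            (h[i] != h[j]).sum() for i in range(n) for j in range(i + 1, n)
        )
        expected = total / (n * (n - 1) / 2) / L
        assert res.pi == pytest.approx(expected, rel=1e-12)

    def test_empty_span_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            nucleotide_diversity(small_matrix, Region("1", 10**9, 10**9 + 1))


class TestPiZtest:
    def test_equal_pi(self):
        a = DiversityResult(pi=0.01, var_pi=1e-6, n=10, L=100)
        z, p = compare_pi_ztest(a, a)
        assert (z, p) == (0.0, 1.0)

    def test_three_sigma(self):
        var = 1e-6
        a = DiversityResult(pi=0.01 + 3 * math.sqrt(var), var_pi=var, n=10, L=100)
        b = DiversityResult(pi=0.01, var_pi=0.0, n=10, L=100)
        _, p = compare_pi_ztest(a, b)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_antisymmetry(self):
        a = DiversityResult(pi=0.02, var_pi=1e-6, n=10, L=100)
        b = DiversityResult(pi=0.01, var_pi=2e-6, n=10, L=100)
        za, pa = compare_pi_ztest(a, b)
        zb, pb = compare_pi_ztest(b, a)
        assert za == -zb and pa == pb

    def test_zero_variance_unequal_pi(self):
        a = DiversityResult(pi=0.02, var_pi=0.0, n=10, L=100)
        b = DiversityResult(pi=0.01, var_pi=0.0, n=10, L=100)
        with pytest.raises(ValueError):
            compare_pi_ztest(a, b)


# ---------------------------------------------------------------------------
# SFS tests
# ---------------------------------------------------------------------------

def _tajima_oracle(m):
    """Textbook Tajima (1989) D, coded independently from pairwise diffs."""
    h = m.alleles
    n, _ = h.shape
    counts = h.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    k = np.mean(
        [(h[i] != h[j]).sum() for i in range(n) for j in range(i + 1, n)]
    )
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_singleton_excess_negative(self, rng):
        n = 30
        alleles = np.zeros((n, 25), dtype=np.int8)
        for j in range(25):
            alleles[j % n, j] = 1  # every site a singleton
        m = HaplotypeMatrix(alleles, np.arange(1, 26))
        res = tajimas_d(m, n_reps=50, seed=1)
        assert res.statistic < 0

    def test_matches_textbook_oracle(self, rng):
        m = random_matrix(rng, 5, 10)
        res = tajimas_d(m, n_reps=10, seed=1)
        assert res.statistic == pytest.approx(_tajima_oracle(m), rel=1e-10)

    def test_no_segregating_sites_undefined(self):
        m = HaplotypeMatrix(np.zeros((5, 4), dtype=np.int8), np.arange(1, 5))
        res = tajimas_d(m, n_reps=10, seed=1)
        assert math.isnan(res.statistic)

    def test_beta_approximation_runs(self, rng):
        m = random_matrix(rng, 10, 20)
        res = tajimas_d(m, method="beta")
        assert 0.0 <= res.p_value <= 1.0


def _theta_h_oracle(m):
    """Brute-force theta_H = sum 2 S_i i^2 / (n (n-1))."""
    n = m.n_haplotypes
    counts = m.alleles.sum(axis=0)
    counts = counts[(counts > 0) & (counts < n)]
    return sum(2 * c**2 for c in counts) / (n * (n - 1))


class TestFayWuH:
    def test_singletons_nonnegative(self):
        n = 20
        alleles = np.zeros((n, 15), dtype=np.int8)
        for j in range(15):
            alleles[j % n, j] = 1
        m = HaplotypeMatrix(alleles, np.arange(1, 16))
        res = fay_wu_h_norm(m, n_reps=50, seed=1)
        assert res.statistic >= 0

    def test_high_freq_derived_strongly_negative(self):
        n = 20
        alleles = np.ones((n, 15), dtype=np.int8)
        alleles[0, :] = 0  # derived at frequency (n-1)/n everywhere
        m = HaplotypeMatrix(alleles, np.arange(1, 16))
        res = fay_wu_h_norm(m, n_reps=50, seed=1)
        assert res.statistic < -2

    def test_matches_theta_h_oracle(self, rng):
        # normalized H * sd * 2 == theta_pi - theta_H (algebraic link)
        m = random_matrix(rng, 12, 30)
        n = m.n_haplotypes
        res = fay_wu_h_norm(m, n_reps=10, seed=1)
        h = m.alleles
        theta_pi = np.mean(
            [(h[i] != h[j]).sum() for i in range(n) for j in range(i + 1, n)]
        )
        theta_h = _theta_h_oracle(m)
        counts = h.sum(axis=0)
        S = int(((counts > 0) & (counts < n)).sum())
        a1 = sum(1 / i for i in range(1, n))
        b_n = sum(1 / i**2 for i in range(1, n))
        b_n1 = b_n + 1 / n**2
        theta_w = S / a1
        theta2 = S * (S - 1) / (a1**2 + b_n)
        var = theta_w * (n - 2) / (6 * (n - 1)) + theta2 * (
            18 * n**2 * (3 * n + 2) * b_n1 - (88 * n**3 + 9 * n**2 - 13 * n + 6)
        ) / (9 * n * (n - 1) ** 2)
        expected = ((theta_pi - theta_h) / 2) / math.sqrt(var)
        assert res.statistic == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------

class TestH12:
    def test_single_class(self):
        m = HaplotypeMatrix(np.zeros((6, 5), dtype=np.int8), np.arange(1, 6))
        assert h12(m) == 1.0

    def test_hand_example(self):
        # class frequencies 0.4 / 0.3 / 0.2 / 0.1 over 10 haplotypes
        patterns = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8
        )
        rows = np.repeat(patterns, [4, 3, 2, 1], axis=0)
        m = HaplotypeMatrix(rows, [1, 2])
        assert h12(m) == pytest.approx(0.49 + 0.04 + 0.01)

    def test_all_distinct_closed_form(self):
        n = 8
        alleles = np.eye(n, dtype=np.int8)
        m = HaplotypeMatrix(alleles, np.arange(1, n + 1))
        assert h12(m) == pytest.approx((2 / n) ** 2 + (n - 2) / n**2)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_relabeling_invariance_and_range(self, seed):
        r = np.random.default_rng(seed)
        m = random_matrix(r, 10, 6)
        val = h12(m)
        perm = m.take_haplotypes(r.permutation(10))
        assert h12(perm) == pytest.approx(val)
        assert 0 < val <= 1


class TestH12Scan:
    def test_full_window_equals_h12(self, small_matrix):
        track = h12_scan(small_matrix, window_snps=small_matrix.n_sites)
        assert len(track) == 1
        assert track["h12"].iloc[0] == pytest.approx(h12(small_matrix))

    def test_sweep_fixture_high_h12(self, rng):
        n = 20
        alleles = random_matrix(rng, n, 40).alleles
        alleles[:16, :] = alleles[0, :]  # one haplotype at 80%
        m = HaplotypeMatrix(alleles, np.arange(1, 41))
        track = h12_scan(m, window_snps=10, step=5)
        assert (track["h12"] >= 0.64).all()

    def test_bad_step(self, small_matrix):
        with pytest.raises(ValueError):
            h12_scan(small_matrix, window_snps=5, step=0)


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def _ehh_oracle(m, core_site, core_allele, pos, maf_min=0.0):
    """Brute force over all carrier pairs: identical on every site between
    core and pos (inclusive)."""
    freqs = m.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    core = m.site_index(core_site)
    keep = sorted(set(np.flatnonzero(maf >= maf_min)) | {core})
    sub = m.take_sites(keep)
    core = sub.site_ids.index(core_site)
    j = int(np.flatnonzero(sub.positions == pos)[0])
    lo, hi = min(core, j), max(core, j)
    carriers = np.flatnonzero(sub.alleles[:, core] == core_allele)
    n = carriers.size
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if np.array_equal(
                sub.alleles[carriers[a], lo : hi + 1], sub.alleles[carriers[b], lo : hi + 1]
            ):
                same += 1
    return same / (n * (n - 1) / 2)


class TestEhh:
    def test_identical_carriers(self):
        alleles = np.zeros((6, 9), dtype=np.int8)
        alleles[:3, 4] = 1  # core site; carriers otherwise identical
        m = HaplotypeMatrix(alleles, np.arange(1, 10))
        curve = ehh(m, m.site_ids[4], 1, maf_min=0.0)
        assert (curve["ehh"] == 1.0).all()

    def test_core_value_is_one(self, rng):
        m = random_matrix(rng, 12, 21)
        core = m.site_ids[10]
        curve = ehh(m, core, 1, maf_min=0.0)
        assert curve.loc[curve["site_id"] == core, "ehh"].eq(1.0).all()

    def test_matches_pair_enumeration(self, rng):
        m = random_matrix(rng, 10, 15)
        core = m.site_ids[7]
        curve = ehh(m, core, 1, maf_min=0.0)
        for _, row in curve.iterrows():
            assert row["ehh"] == pytest.approx(
                _ehh_oracle(m, core, 1, row["pos"]), abs=1e-12
            )

    def test_monotone_decay_and_range(self, rng):
        m = random_matrix(rng, 16, 30)
        curve = ehh(m, m.site_ids[15], 0, maf_min=0.05)
        assert curve["ehh"].between(0, 1).all()
        for _, side in curve.groupby("direction"):
            vals = side.sort_values("distance_bp", key=lambda s: s.abs())["ehh"].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()

    def test_too_few_carriers(self):
        alleles = np.zeros((4, 3), dtype=np.int8)
        alleles[0, 1] = 1
        m = HaplotypeMatrix(alleles, [1, 2, 3])
        with pytest.raises(ValueError):
            ehh(m, m.site_ids[1], 1)


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

def _nsl_raw_oracle(h, focal, cap=None):
    def tract(a, b):
        eq = h[a] == h[b]
        if not eq[focal]:
            return 0
        lo = focal
        while lo > 0 and eq[lo - 1]:
            lo -= 1
        hi = focal
        while hi < h.shape[1] - 1 and eq[hi + 1]:
            hi += 1
        ln = hi - lo + 1
        return min(ln, cap) if cap else ln

    der = np.flatnonzero(h[:, focal] == 1)
    anc = np.flatnonzero(h[:, focal] == 0)
    if der.size < 2 or anc.size < 2:
        return None
    sl_d = np.mean([tract(a, b) for i, a in enumerate(der) for b in der[i + 1 :]])
    sl_a = np.mean([tract(a, b) for i, a in enumerate(anc) for b in anc[i + 1 :]])
    return math.log(sl_a / sl_d)


class TestNsl:
    def test_hand_matrix_matches_oracle(self):
        h = np.array(
            [
                [0, 1, 1, 0, 1],
                [0, 1, 1, 0, 0],
                [1, 0, 1, 1, 0],
                [1, 0, 1, 1, 1],
                [0, 1, 0, 0, 0],
                [1, 0, 0, 1, 1],
            ],
            dtype=np.int8,
        )
        m = HaplotypeMatrix(h, np.arange(1, 6))
        df = nsl(m, maf_min=0.0, max_window=None)
        for k, row in df.iterrows():
            expected = _nsl_raw_oracle(m.alleles, k)
            if expected is None:
                assert math.isnan(row["nsl_raw"])
            else:
                assert row["nsl_raw"] == pytest.approx(expected, rel=1e-12)

    def test_cap_inactive_on_short_matrix(self, rng):
        m = random_matrix(rng, 10, 30)  # < 100 SNPs
        capped = nsl(m, maf_min=0.0, max_window=100)["nsl_raw"]
        uncapped = nsl(m, maf_min=0.0, max_window=None)["nsl_raw"]
        assert np.allclose(capped, uncapped, equal_nan=True)

    def test_standardized_mean_zero_per_bin(self, rng):
        m = random_matrix(rng, 20, 80)
        df = nsl(m, maf_min=0.0, max_window=None)
        bins = np.minimum((df["derived_freq"] * 20).astype(int), 19)
        for b in np.unique(bins):
            vals = df.loc[bins == b, "nsl"].dropna()
            if len(vals) >= 2:
                assert abs(vals.mean()) < 1e-9

    def test_small_class_undefined(self):
        h = np.array([[1, 0], [0, 1], [0, 0], [0, 1]], dtype=np.int8)
        m = HaplotypeMatrix(h, [1, 2])
        df = nsl(m, maf_min=0.0)
        assert math.isnan(df["nsl_raw"].iloc[0])  # derived class of size 1


# ---------------------------------------------------------------------------
# PBS, LD, FDR
# ---------------------------------------------------------------------------

class TestPbs:
    def test_all_zero(self):
        assert pbs(0, 0, 0) == (0.0, 0.0)

    def test_plug_in(self):
        a, _ = pbs(0.1, 0.1, 0.0)
        assert a == pytest.approx(-math.log(0.9))

    def test_symmetry(self):
        a, b = pbs(0.2, 0.1, 0.1)
        assert a == pytest.approx(b)

    def test_fst_one_infinite(self):
        a, b = pbs(1.0, 0.1, 0.1)
        assert math.isinf(a)

    def test_monotone_in_fst_ab(self):
        prev = -1.0
        for f in (0.0, 0.1, 0.2, 0.4, 0.6):
            a, _ = pbs(f, 0.2, 0.1)
            assert a >= prev
            prev = a


class TestDprimeR2:
    def test_perfect_coupling(self):
        h = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        m = HaplotypeMatrix(h, [1, 2])
        dp, r2 = d_prime_r2(m.site_ids[0], m.site_ids[1], m)
        assert (dp, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_exact_independence(self):
        h = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        m = HaplotypeMatrix(h, [1, 2])
        dp, r2 = d_prime_r2(m.site_ids[0], m.site_ids[1], m)
        assert (dp, r2) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_contingency_oracle(self, rng):
        for _ in range(50):
            m = random_matrix(rng, 20, 2)
            x, y = m.alleles[:, 0], m.alleles[:, 1]
            pa, pb = x.mean(), y.mean()
            pab = (x & y).mean()
            d = pab - pa * pb
            dmax = (
                min(pa * (1 - pb), (1 - pa) * pb)
                if d >= 0
                else min(pa * pb, (1 - pa) * (1 - pb))
            )
            dp, r2 = d_prime_r2(m.site_ids[0], m.site_ids[1], m)
            assert dp == pytest.approx(abs(d) / dmax if dmax else 0.0)
            assert r2 == pytest.approx(d**2 / (pa * (1 - pa) * pb * (1 - pb)))

    def test_monomorphic_rejected(self):
        h = np.array([[0, 1], [0, 0]], dtype=np.int8)
        m = HaplotypeMatrix(h, [1, 2])
        with pytest.raises(ValueError):
            d_prime_r2(m.site_ids[0], m.site_ids[1], m)


class TestFindLdBlock:
    def _coupled_matrix(self, n_sites=10):
        col = np.array([1, 1, 0, 0, 1, 0], dtype=np.int8)
        h = np.tile(col[:, None], (1, n_sites))
        return HaplotypeMatrix(h, np.arange(10, 10 * (n_sites + 1), 10))

    def test_fully_coupled(self):
        m = self._coupled_matrix()
        block = find_ld_block(m, m.site_ids[4])
        assert block.n_sites == 10

    def test_break_in_coupling(self):
        m = self._coupled_matrix()
        # make sites 6..10 independent of 1..5 (D' = 0 across the junction)
        m.alleles[:, 5:] = np.array([1, 0, 1, 0, 1, 0], dtype=np.int8)[:, None]
        block = find_ld_block(m, m.site_ids[2])
        assert (block.start_index, block.end_index) == (0, 4)

    def test_isolated_anchor(self):
        h = np.array(
            [[1, 1, 0], [1, 0, 1], [0, 1, 1], [0, 0, 0], [1, 1, 0], [0, 0, 1]],
            dtype=np.int8,
        )
        m = HaplotypeMatrix(h, [1, 2, 3])
        block = find_ld_block(m, m.site_ids[1], dprime_min=0.999)
        assert block.n_sites == 1

    def test_anchor_fails_maf(self):
        h = np.zeros((20, 3), dtype=np.int8)
        h[0, 1] = 1  # MAF = 0.05 at threshold... below for others
        h[:10, 0] = 1
        h[:10, 2] = 1
        m = HaplotypeMatrix(h, [1, 2, 3])
        with pytest.raises(ValueError):
            find_ld_block(m, m.site_ids[1], maf_min=0.10)


class TestSelectCoreRegion:
    def test_fully_coupled(self):
        col = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        m = HaplotypeMatrix(np.tile(col[:, None], (1, 8)), np.arange(1, 9))
        region = select_core_region(m, m.site_ids[3])
        assert (region.start, region.end) == (1, 8)

    def test_decay_boundary(self, rng):
        col = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        h = np.tile(col[:, None], (1, 6))
        # site 5: decorrelate fully
        h[:, 5] = rng.permutation(col)
        m = HaplotypeMatrix(h, np.arange(1, 7))
        region = select_core_region(m, m.site_ids[2])
        assert region.end < m.positions[5]

    def test_anchor_alone(self, rng):
        h = np.zeros((20, 3), dtype=np.int8)
        h[:10, 1] = 1
        h[::2, 0] = 1
        h[1::2, 2] = 1
        m = HaplotypeMatrix(h, [1, 2, 3])
        region = select_core_region(m, m.site_ids[1])
        assert (region.start, region.end) == (2, 2)


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, ps):
        q = np.asarray(bh_fdr(ps))
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(ps) - 1e-12).all()
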