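"""Population-genetic statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from triophaser.io_core import Interval
from triophaser.popgen import (
    HaplotypePanel,
    distance_to_intervals,
    folded_sfs,
    ld_decay,
    maf_vs_distance,
    pnps,
    r_squared,
    tajimas_d_constants,
    variant_density,
    windowed_pi_d,
)


def _panel(g, positions=None, site_class=None, is_indel=None):
    g = np.asarray(g, dtype=np.int8)
    m = g.shape[1]
    return HaplotypePanel(
        genotypes=g,
        positions=np.array(positions if positions is not None else range(1, m + 1)),
        site_class=np.array(site_class if site_class is not None else ["other"] * m, dtype=object),
        is_indel=np.array(is_indel if is_indel is not None else [False] * m),
        names=[f"h{i}" for i in range(g.shape[0])],
    )


@pytest.fixture()
def random_panel(rng):
    g = (rng.random((20, 100)) < rng.uniform(0.05, 0.6, size=100)).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 10_001), size=100, replace=False))
    return _panel(g, positions)


class TestFoldedSfs:
    def test_single_low_frequency_site(self):
        counts, dropped = folded_sfs(_panel([[1], [0], [0], [0]]))
        assert counts[1] == 1 and dropped == 0

    def test_monomorphic_dropped_and_reported(self):
        counts, dropped = folded_sfs(_panel([[1, 0], [1, 0], [1, 0], [1, 0]]))
        assert counts.sum() == 0 and dropped == 2

    def test_matches_per_site_tally(self, random_panel):
        counts, dropped = folded_sfs(random_panel)
        # oracle: explicit per-site tally
        n = random_panel.n_haplotypes
        tally = {}
        mono = 0
        for j in range(random_panel.n_sites):
            c = int(random_panel.genotypes[:, j].sum())
            minor = min(c, n - c)
            if minor == 0:
                mono += 1
            else:
                tally[minor] = tally.get(minor, 0) + 1
        assert dropped == mono
        for i, c in enumerate(counts):
            assert c == tally.get(i, 0)
        assert counts.sum() == random_panel.n_sites - mono  # conservation


class TestWindowedPiD:
    def test_identical_haplotypes_zero_pi(self):
        g = np.zeros((6, 50), dtype=np.int8)
        df = windowed_pi_d(_panel(g), window=100, step=100, region=(1, 100))
        assert (df.pi == 0).all()

    def test_pi_matches_all_pairs_hamming(self, random_panel):
        """π equals exhaustive pairwise Hamming / (pairs × window bp)."""
        window, step = 2_000, 1_000
        df = windowed_pi_d(random_panel, window, step, region=(1, 10_000))
        g = random_panel.genotypes
        pos = random_panel.positions
        n = g.shape[0]
        pairs = list(itertools.combinations(range(n), 2))
        for _, row in df.iterrows():
            sel = (pos >= row.start) & (pos < row.end)
            sub = g[:, sel]
            diffs = sum(
                int((sub[a] != sub[b]).sum()) for a, b in pairs
            )
            expected = diffs / len(pairs) / window
            assert abs(row.pi - expected) < 1e-9

    def test_tajima_d_formula_against_direct_computation(self, random_panel):
        """D recomputed from scratch (fresh constants) matches to 1e-9."""
        window = 5_000
        df = windowed_pi_d(random_panel, window, window, region=(1, 10_000))
        g = random_panel.genotypes
        pos = random_panel.positions
        n = g.shape[0]
        i = np.arange(1, n)
        a1 = (1.0 / i).sum()
        a2 = (1.0 / i**2).sum()
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        pairs = n * (n - 1) / 2
        for _, row in df.iterrows():
            sel = (pos >= row.start) & (pos < row.end)
            sub = g[:, sel]
            c = sub.sum(axis=0)
            S = int(((c > 0) & (c < n)).sum())
            k = float((c * (n - c)).sum() / pairs)
            if S < 3:
                assert np.isnan(row.tajima_d)
            else:
                d = (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
                assert abs(row.tajima_d - d) < 1e-9

    def test_d_zero_when_k_equals_s_over_a1(self):
        """Constructed window with k = S/a1 gives D = 0 analytically."""
        # n=4: a1 = 1 + 1/2 + 1/3 = 11/6.  With 11 singleton sites,
        # k = 11 * (1*3)/6 = 5.5 and S/a1 = 11/(11/6) = 6: not zero.
        # Use sites with minor count 2: per-site k = 2*2/6 = 2/3.
        # k = S * 2/3; need 2/3 = 1/a1 = 6/11 -> impossible for n=4, so
        # build a mix: s singletons (k=1/2 each... ) — solve numerically
        # with n=4, x singletons + y doubletons: k = x/2 + 2y/3 = (x+y)*6/11.
        # x=22, y=3: k = 11 + 2 = 13, S/a1 = 25*6/11 = 13.636 (no).
        # x=2, y=21: k = 1 + 14 = 15, S/a1 = 23*6/11 = 12.545 (no).
        # integer solution: x/2 + 2y/3 = (x+y)6/11 -> 33x + 44y = 36x + 36y
        # -> 8y = 3x -> x=8, y=3.
        cols = []
        for _ in range(8):  # singletons
            cols.append([1, 0, 0, 0])
        for _ in range(3):  # doubletons
            cols.append([1, 1, 0, 0])
        g = np.array(cols, dtype=np.int8).T
        df = windowed_pi_d(_panel(g), window=100, step=100, region=(1, 100))
        assert abs(df.tajima_d.iloc[0]) < 1e-9

    def test_constants_small_n_closed_forms(self):
        c = tajimas_d_constants(4)
        assert abs(c["a1"] - (1 + 1 / 2 + 1 / 3)) < 1e-12
        assert abs(c["a2"] - (1 + 1 / 4 + 1 / 9)) < 1e-12
        assert abs(c["b1"] - 5 / 9) < 1e-12
        assert abs(c["b2"] - 2 * 23 / (9 * 12)) < 1e-12

    def test_window_must_cover_step(self, random_panel):
        with pytest.raises(ValueError):
            windowed_pi_d(random_panel, window=100, step=200)


class TestVariantDensity:
    def test_empty_panel_zero_counts(self):
        p = _panel(np.zeros((4, 0), dtype=np.int8), positions=[])
        df = variant_density(p, window=100, step=100, region=(1, 300))
        assert (df.snv_count == 0).all() and (df.indel_count == 0).all()

    def test_counts_match_interval_query(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 5_001), 60, replace=False))
        indel = rng.random(60) < 0.3
        p = _panel(np.ones((4, 60), dtype=np.int8) * [[0], [1], [0], [1]], pos, is_indel=indel)
        df = variant_density(p, window=1_000, step=500, region=(1, 5_000))
        for _, row in df.iterrows():
            sel = (pos >= row.start) & (pos < row.end)
            assert row.snv_count == int((~indel[sel]).sum())
            assert row.indel_count == int(indel[sel].sum())


class TestPnps:
    def _class_panel(self, n_nonsyn, n_syn):
        m = n_nonsyn + n_syn
        classes = ["nonsynonymous"] * n_nonsyn + ["synonymous"] * n_syn
        g = np.tile([[0], [1]], (1, m)).astype(np.int8)
        return _panel(g, positions=range(1, m + 1), site_class=classes)

    def test_equal_counts_forced_arithmetic(self):
        df = pnps(self._class_panel(10, 10), window=100, region=(1, 100))
        assert abs(df.pnps.iloc[0] - (10 / 0.73) / (10 / 0.27)) < 1e-12

    def test_calibration_point_is_unity(self):
        df = pnps(self._class_panel(73, 27), window=200, region=(1, 200))
        assert abs(df.pnps.iloc[0] - 1.0) < 1e-12

    def test_zero_synonymous_undefined(self):
        df = pnps(self._class_panel(5, 0), window=100, region=(1, 100))
        assert np.isnan(df.pnps.iloc[0])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            pnps(self._class_panel(1, 1), frac_nonsyn=0.8, frac_syn=0.27, window=10)


class TestMafVsDistance:
    def test_equidistant_variants_zero_slope(self):
        # four variants, each exactly 500 bp from a locus edge
        pos = [1_000, 3_001, 5_000, 7_001]
        classical = [Interval(1_499, 2_501), Interval(5_499, 6_501)]
        g = np.array(
            [[1, 1, 1, 0], [0, 0, 1, 1], [0, 1, 0, 0], [0, 0, 0, 1]], dtype=np.int8
        )
        res = maf_vs_distance(
            _panel(g, pos, site_class=["synonymous"] * 4),
            classical,
            classes=("synonymous",),
            bin_size=1,
        )
        reg = res["synonymous"]["regression"]
        assert reg["slope"] == 0.0

    def test_distance_matches_brute_force_min(self, rng):
        intervals = [Interval(100, 200), Interval(1_000, 1_500), Interval(4_000, 4_050)]
        pos = np.sort(rng.choice(np.arange(1, 5_001), 80, replace=False))
        d = distance_to_intervals(pos, intervals)
        for p, got in zip(pos, d):
            p0 = p - 1
            exp = min(
                0 if iv.start <= p0 < iv.end else min(abs(p0 - iv.start), abs(p0 - (iv.end - 1)))
                for iv in intervals
            )
            assert got == exp

    def test_bins_of_25_with_partial_dropped(self, rng):
        pos = np.sort(rng.choice(np.arange(2_000, 50_000), 120, replace=False))
        g = (rng.random((10, 120)) < 0.3).astype(np.int8)
        res = maf_vs_distance(
            _panel(g, pos, site_class=["nonsynonymous"] * 120),
            [Interval(0, 1_000)],
            classes=("nonsynonymous",),
        )
        bins = res["nonsynonymous"]["bins"]
        assert len(bins) == 120 // 25
        assert (bins.n == 25).all()
        assert bins.mean_distance.is_monotonic_increasing


class TestLdDecay:
    def test_perfectly_correlated_pair(self):
        g = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        assert r_squared(_panel(g), 0, 1) == pytest.approx(1.0)

    def test_r2_matches_contingency_table(self, rng):
        """r² equals the brute-force 2×2 haplotype-table computation."""
        g = (rng.random((20, 10)) < 0.4).astype(np.int8)
        p = _panel(g)
        for i, j in itertools.combinations(range(10), 2):
            gi, gj = g[:, i], g[:, j]
            if len(set(gi)) < 2 or len(set(gj)) < 2:
                continue
            # oracle: joint haplotype counts
            n = len(gi)
            pab = np.mean((gi == 1) & (gj == 1))
            pa, pb = gi.mean(), gj.mean()
            d = pab - pa * pb
            expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
            assert r_squared(p, i, j) == pytest.approx(expected, abs=1e-12)
            # symmetry and label-swap invariance
            assert r_squared(p, j, i) == pytest.approx(expected, abs=1e-12)
            q = _panel(1 - g)
            assert r_squared(q, i, j) == pytest.approx(expected, abs=1e-12)

    def test_independent_common_sites_near_zero(self, rng):
        """Independent sites at frequency 0.5: E[r²] ≈ 1/n."""
        n = 200
        reps = 300
        vals = []
        for _ in range(reps):
            gi = (rng.random(n) < 0.5).astype(np.int8)
            gj = (rng.random(n) < 0.5).astype(np.int8)
            p = _panel(np.stack([gi, gj], axis=1))
            v = r_squared(p, 0, 1)
            if not np.isnan(v):
                vals.append(v)
        mean = np.mean(vals)
        # E[r2] = 1/n for independent sites; allow 3 sigma of the mean
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean - 1 / n) < 3 * se + 1e-3

    def test_binned_means(self, rng):
        pos = np.array([100, 200, 5_100, 15_200, 25_300])
        g = (rng.random((30, 5)) < 0.5).astype(np.int8)
        p = _panel(g, pos)
        df = ld_decay(p, [Interval(50, 250)], maf_min=0.0, bin_bp=10_000)
        # focal = sites inside [50,250); others = remaining three
        assert df.n_pairs.sum() == 2 * 3

    def test_ld_higher_near_balanced_than_control_loci(self):
        """Balanced lineage structure elevates LD around classical loci."""
        import triophaser as tp

        length = 300_000
        classical = tp.default_classical_loci(length)
        control = tp.default_control_loci(length)
        wins = 0
        for seed in range(20, 25):
            src = tp.generate_founders(length, 50, 1 / 150, 0.0, classical, seed=seed)
            panel = HaplotypePanel.from_founder_panel(src)
            r2_c = ld_decay(panel, classical, max_distance=30_000).mean_r2.mean()
            r2_x = ld_decay(panel, control, max_distance=30_000).mean_r2.mean()
            wins += r2_c > r2_x
        assert wins >= 4

    def test_no_qualifying_pairs_empty(self):
        g = np.zeros((4, 2), dtype=np.int8)
        g[:, 0] = [0, 0, 0, 1]
        df = ld_decay(_panel(g, [100, 5_000]), [Interval(0, 200)], maf_min=0.4)
        assert df.empty
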