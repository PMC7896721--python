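"""Site-pattern arithmetic, Patterson's D with jackknife, f3, windowed
f_dM/dxy/pi, significance summaries and haplotype tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from introsel.haplotypes import HaplotypePanel
from introsel.introgression import (
    SitePattern,
    d_statistic,
    f3_test,
    haplotype_freqs,
    significant_windows,
    site_patterns,
    window_scan,
)

from conftest import make_gm

ROLES = {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}


def sp_from_freqs(p1, p2, p3, pO, bp=None, n=20):
    m = len(p1)
    bp = np.arange(1, m + 1) * 100_000 if bp is None else bp
    return SitePattern(
        freqs=pd.DataFrame(
            {
                "chrom": "1",
                "bp": np.asarray(bp, dtype=np.int64),
                "p1": p1, "n1": n,
                "p2": p2, "n2": n,
                "p3": p3, "n3": n,
                "pO": pO, "nO": n,
            }
        ),
        pops=ROLES,
    )


# ----------------------------------------------------------------- oracles
def abba_baba_oracle(p1, p2, p3, pO):
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def fdm_window_oracle(p1, p2, p3, pO):
    """Direct per-window f_dM from the published piecewise definition."""
    num = den = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        abba, baba = abba_baba_oracle(a, b, c, d)
        num += abba - baba
        if b >= a:
            pd_ = max(b, c)
            x, y = abba_baba_oracle(a, pd_, pd_, d)
            den += x - y
        else:
            pd_ = max(a, c)
            x, y = abba_baba_oracle(pd_, b, pd_, d)
            den -= x - y
    return num / den if den != 0 else np.nan


class TestSitePatterns:
    def test_fixed_abba_pattern(self):
        sp = sp_from_freqs([0.0], [1.0], [1.0], [0.0])
        abba, baba = abba_baba_oracle(
            sp.freqs["p1"], sp.freqs["p2"], sp.freqs["p3"], sp.freqs["pO"]
        )
        assert abba.iloc[0] == 1.0 and baba.iloc[0] == 0.0

    def test_computed_from_genotypes_matches_hand(self):
        # two individuals per population, constructed dosages
        d = np.array(
            [
                [0, 2], [0, 0],   # P1: freqs 0.0, 0.5
                [2, 2], [2, 0],   # P2: freqs 1.0, 0.5
                [2, 2], [2, 2],   # P3: freqs 1.0, 1.0
                [0, 0], [0, 0],   # O:  freqs 0.0, 0.0
            ],
            dtype=np.int8,
        )
        gm = make_gm(d, pops=["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2 + ["O"] * 2)
        sp = site_patterns(gm, ROLES)
        assert list(sp.freqs["p1"]) == [0.0, 0.5]
        assert list(sp.freqs["p2"]) == [1.0, 0.5]
        assert list(sp.freqs["p3"]) == [1.0, 1.0]
        assert list(sp.freqs["pO"]) == [0.0, 0.0]

    def test_outgroup_major_allele_polarized_away(self):
        d = np.array(
            [
                [2, 2], [2, 2],   # P1
                [0, 0], [0, 0],   # P2
                [0, 0], [0, 0],   # P3
                [2, 2], [2, 2],   # O fixed for allele1 -> flip
            ],
            dtype=np.int8,
        )
        gm = make_gm(d, pops=["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2 + ["O"] * 2)
        sp = site_patterns(gm, ROLES)
        assert sp.freqs["pO"].iloc[0] == 0.0
        assert sp.freqs["p1"].iloc[0] == 0.0  # flipped with the outgroup
        assert sp.freqs["p2"].iloc[0] == 1.0


class TestDStatistic:
    def _random_sp(self, seed=0, m=600):
        rng = np.random.default_rng(seed)
        return sp_from_freqs(
            rng.uniform(0, 1, m), rng.uniform(0, 1, m),
            rng.uniform(0, 1, m), rng.uniform(0, 0.3, m),
            bp=np.arange(1, m + 1) * 200_000,
        )

    def test_swap_p1_p2_flips_sign(self):
        sp = self._random_sp()
        swapped = SitePattern(
            freqs=sp.freqs.rename(columns={"p1": "p2", "p2": "p1",
                                           "n1": "n2", "n2": "n1"}),
            pops=ROLES,
        )
        a = d_statistic(sp)
        b = d_statistic(swapped)
        assert a.d == pytest.approx(-b.d, abs=1e-12)

    def test_point_estimate_equals_ratio_of_sums(self):
        sp = self._random_sp(seed=1)
        res = d_statistic(sp)
        abba, baba = abba_baba_oracle(
            sp.freqs["p1"], sp.freqs["p2"], sp.freqs["p3"], sp.freqs["pO"]
        )
        assert res.d == pytest.approx(
            (abba - baba).sum() / (abba + baba).sum(), abs=1e-12
        )

    def test_pulse_gives_positive_significant_d(self, sim_default):
        _, gm, _ = sim_default
        sp = site_patterns(gm, ROLES)
        res = d_statistic(sp)
        assert res.d > 0
        assert res.z > 3

    def test_too_few_blocks_rejected(self):
        sp = sp_from_freqs([0.1, 0.5], [0.5, 0.1], [0.9, 0.9], [0.0, 0.0])
        with pytest.raises(ValueError):
            d_statistic(sp, block_size_bp=1e9)


class TestF3:
    def test_known_frequency_limit(self):
        """a=0.5, b=0, c=1 at every SNP: (a-b)(a-c) = -0.25; the
        finite-sample correction subtracts a(1-a)/(n_A - 1) exactly."""
        n_dip = 30
        d = np.vstack(
            [np.ones((n_dip, 40)), np.zeros((n_dip, 40)), np.full((n_dip, 40), 2)]
        ).astype(np.int8)
        gm = make_gm(
            d, pops=["A"] * n_dip + ["B"] * n_dip + ["C"] * n_dip,
            bp=np.arange(1, 41) * 3_000_000,
        )
        res = f3_test(gm, "A", "B", "C", block_size_bp=10e6)
        expected = -0.25 - 0.25 / (2 * n_dip - 1)
        assert res.f3 == pytest.approx(expected, abs=1e-12)

    def test_fresh_mix_strongly_negative(self):
        rng = np.random.default_rng(2)
        m = 2000
        pb = rng.uniform(0.05, 0.95, m)
        pc = rng.uniform(0.05, 0.95, m)
        draw = lambda p, n: ((rng.random((n, m)) < p).astype(np.int8)
                             + (rng.random((n, m)) < p).astype(np.int8))
        # each target individual: one haplotype from B, one from C
        target = ((rng.random((40, m)) < pb).astype(np.int8)
                  + (rng.random((40, m)) < pc).astype(np.int8))
        d = np.vstack([target, draw(pb, 40), draw(pc, 40)])
        gm = make_gm(
            d, pops=["A"] * 40 + ["B"] * 40 + ["C"] * 40,
            bp=np.arange(1, m + 1) * 50_000,
        )
        res = f3_test(gm, "A", "B", "C")
        assert res.f3 < 0
        assert res.z < -2
        assert res.significant

    def test_unadmixed_drifted_target_nonnegative(self):
        """Unbiasedness gate: a pure drifted copy of B's source gives
        f3 within noise of its positive drift expectation, never the
        strong negative of admixture."""
        rng = np.random.default_rng(3)
        m = 2000
        p0 = rng.uniform(0.1, 0.9, m)
        drift = lambda p, sd: np.clip(p + rng.normal(0, sd, m), 0.01, 0.99)
        pa = drift(p0, 0.1)  # target drifts away on its own branch
        pb = drift(p0, 0.05)
        pc = drift(p0, 0.3)
        draw = lambda p, n: ((rng.random((n, m)) < p).astype(np.int8)
                             + (rng.random((n, m)) < p).astype(np.int8))
        d = np.vstack([draw(pa, 40), draw(pb, 40), draw(pc, 40)])
        gm = make_gm(
            d, pops=["A"] * 40 + ["B"] * 40 + ["C"] * 40,
            bp=np.arange(1, m + 1) * 50_000,
        )
        res = f3_test(gm, "A", "B", "C")
        assert res.f3 > -2 * res.se

    def test_single_target_individual_rejected(self):
        d = np.array([[1, 1], [0, 0], [2, 2]], dtype=np.int8)
        gm = make_gm(d, pops=["A", "B", "C"])
        with pytest.raises(ValueError):
            f3_test(gm, "A", "B", "C")


class TestWindowScan:
    def test_pure_abba_window_fdm_one(self):
        m = 10
        sp = sp_from_freqs(
            np.zeros(m), np.ones(m), np.ones(m), np.zeros(m)
        )
        w = window_scan(sp, window_snps=10, step_snps=2)
        assert len(w) == 1
        assert w["fdm"].iloc[0] == pytest.approx(1.0)

    def test_windows_match_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        m = 20
        p1, p2 = rng.uniform(0, 1, m), rng.uniform(0, 1, m)
        p3, pO = rng.uniform(0, 1, m), rng.uniform(0, 0.4, m)
        sp = sp_from_freqs(p1, p2, p3, pO)
        w = window_scan(sp, window_snps=10, step_snps=2)
        # expected windows: indices 0-9, 2-11, 4-13, 6-15, 8-17, 10-19
        assert list(w["start_idx"]) == [0, 2, 4, 6, 8, 10]
        for row in w.itertuples():
            s, e = row.start_idx, row.end_idx + 1
            expected = fdm_window_oracle(p1[s:e], p2[s:e], p3[s:e], pO[s:e])
            assert row.fdm == pytest.approx(expected, abs=1e-12)

    def test_dxy_pi_values(self):
        m = 10
        sp = sp_from_freqs(
            np.full(m, 0.0), np.full(m, 1.0), np.full(m, 0.5), np.zeros(m), n=20
        )
        w = window_scan(
            sp, window_snps=10, step_snps=2,
            pi_pops=("P2", "P3"), dxy_pairs=(("P1", "P2"), ("P3", "P3")),
        )
        assert w["dxy_P1_P2"].iloc[0] == pytest.approx(1.0)  # fixed difference
        assert w["dxy_P3_P3"].iloc[0] == pytest.approx(0.5)  # 2p(1-p) self-term
        assert w["pi_P2"].iloc[0] == pytest.approx(0.0)
        assert w["pi_P3"].iloc[0] == pytest.approx(0.5 * 20 / 19)

    def test_fdm_bounded(self, sim_default):
        _, gm, _ = sim_default
        sp = site_patterns(gm, ROLES)
        w = window_scan(sp)
        vals = w["fdm"].dropna()
        assert (vals >= -1).all() and (vals <= 1).all()

    def test_windows_never_span_chromosomes(self, sim_default):
        _, gm, _ = sim_default
        sp = site_patterns(gm, ROLES)
        w = window_scan(sp)
        chrom_of = sp.freqs.groupby("chrom")["bp"].max()
        for row in w.itertuples():
            assert row.start_bp <= row.end_bp <= chrom_of[row.chrom]

    def test_allele_label_invariance_of_dxy_pi(self):
        rng = np.random.default_rng(5)
        m = 10
        p1, p2 = rng.uniform(0, 1, m), rng.uniform(0, 1, m)
        p3, pO = rng.uniform(0, 1, m), rng.uniform(0, 1, m)
        a = window_scan(sp_from_freqs(p1, p2, p3, pO), pi_pops=("P1",),
                        dxy_pairs=(("P1", "P2"),))
        b = window_scan(sp_from_freqs(1 - p1, 1 - p2, 1 - p3, 1 - pO),
                        pi_pops=("P1",), dxy_pairs=(("P1", "P2"),))
        assert np.allclose(a["dxy_P1_P2"], b["dxy_P1_P2"])
        assert np.allclose(a["pi_P1"], b["pi_P1"])


class TestSignificantWindows:
    def _windows(self, fdm, pi2=None, pi1=None):
        m = len(fdm)
        w = pd.DataFrame(
            {
                "chrom": "1",
                "start_idx": np.arange(m),
                "end_idx": np.arange(m) + 9,
                "start_bp": np.arange(m) * 100_000 + 1,
                "end_bp": np.arange(m) * 100_000 + 90_000,
                "fdm": fdm,
            }
        )
        w["pi_P2"] = 0.3 if pi2 is None else pi2
        w["pi_P1"] = 0.25 if pi1 is None else pi1
        return w

    def test_constant_vector_nothing_significant(self):
        out = significant_windows(self._windows(np.full(200, 0.2)))
        assert out.windows["significant"].sum() == 0

    def test_planted_extreme_window_found_and_threshold_exact(self):
        rng = np.random.default_rng(6)
        fdm = rng.normal(0.0, 0.1, 300)
        fdm[137] = 0.9
        out = significant_windows(self._windows(fdm))
        sig = out.windows[out.windows["significant"]]
        assert 137 in set(sig["start_idx"])
        mu, sd = fdm.mean(), fdm.std()
        assert out.fdm_threshold == pytest.approx(
            mu + stats.norm.isf(0.01) * sd
        )
        assert stats.norm.isf(0.01) == pytest.approx(2.3263, abs=1e-4)

    def test_pi_boost_over_positive_windows(self):
        fdm = np.concatenate([np.full(100, -0.2), np.full(100, 0.4)])
        pi2 = np.concatenate([np.full(100, 0.2), np.full(100, 0.3)])
        pi1 = np.full(200, 0.25)
        out = significant_windows(self._windows(fdm, pi2=pi2, pi1=pi1))
        assert out.genome_fraction_positive == pytest.approx(0.5)
        assert out.pi_boost == pytest.approx((0.3 - 0.25) / 0.25)

    def test_significant_fdm_regions_overlap_truth(self, sim_default):
        """Localization: significant windows should fall where the
        simulator actually placed donor haplotypes."""
        _, gm, truth = sim_default
        sp = site_patterns(gm, ROLES)
        w = window_scan(sp)
        out = significant_windows(w)
        sig = out.windows[out.windows["significant"]]
        assert len(sig) > 0
        mask = truth.donor_mask()
        p2_rows = np.concatenate(
            [
                (2 * np.flatnonzero(truth.individuals["population"] == "P2")),
                (2 * np.flatnonzero(truth.individuals["population"] == "P2") + 1),
            ]
        )
        donor_frac_per_snp = mask[p2_rows].mean(axis=0)
        bp = truth.snps["bp"].to_numpy()
        chroms = truth.snps["chrom"].to_numpy()
        n_overlap = 0
        for row in sig.itertuples():
            inside = (chroms == row.chrom) & (bp >= row.start_bp) & (bp <= row.end_bp)
            if inside.any() and donor_frac_per_snp[inside].max() > 0:
                n_overlap += 1
        assert n_overlap / len(sig) >= 0.8


class TestHaplotypeFreqs:
    def _panel(self, haps, pops):
        haps = np.asarray(haps, dtype=np.uint8)
        m = haps.shape[1]
        snps = pd.DataFrame(
            {
                "chrom": "1",
                "snp_id": [f"s{j}" for j in range(m)],
                "cm": np.arange(m) / 100,
                "bp": np.arange(1, m + 1) * 1000,
                "allele1": "A",
                "allele2": "B",
            }
        )
        individuals = pd.DataFrame(
            {"id": [f"i{k}" for k in range(haps.shape[0] // 2)],
             "population": pops, "sex": "unknown"}
        )
        return HaplotypePanel(haplotypes=haps, snps=snps, individuals=individuals)

    def test_identical_homozygous_pair_single_haplotype(self):
        haps = np.ones((4, 5), dtype=np.uint8)
        panel = self._panel(haps, ["X", "X"])
        t = haplotype_freqs(panel, slice(0, 5))
        assert len(t) == 1
        assert t["total"].iloc[0] == 4

    def test_counts_sum_to_2n_per_population(self):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(12, 6)).astype(np.uint8)
        panel = self._panel(haps, ["X"] * 3 + ["Y"] * 3)
        t = haplotype_freqs(panel, slice(0, 6))
        assert t["X"].sum() == 6
        assert t["Y"].sum() == 6

    def test_manual_tally(self):
        haps = np.array(
            [[0, 0], [0, 0], [1, 1], [0, 0], [1, 0], [1, 1]], dtype=np.uint8
        )
        panel = self._panel(haps, ["X", "X", "Y"])
        t = haplotype_freqs(panel, slice(0, 2)).set_index("haplotype")
        assert t.loc["00", "total"] == 3
        assert t.loc["11", "total"] == 2
        assert t.loc["10", "total"] == 1
        assert t.index[0] == "00"  # most frequent first
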