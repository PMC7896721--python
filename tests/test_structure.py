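"""Distance matrices, Weir-Cockerham FST vs a textbook oracle, NJ tree
recovery, GRM/PCA, supervised ancestry, conservation tiers, families."""

import numpy as np
import pandas as pd
import pytest
from skbio.tree import TreeNode

from introsel.structure import (
    DistanceMatrix,
    assign_families,
    classify_conservation,
    fst_matrix,
    grm_matrix,
    ibs_matrix,
    nj_tree,
    pca_grm,
    supervised_ancestry,
    wc_fst,
)

from conftest import make_gm


# ------------------------------------------------------------------ oracles
def wc_theta_oracle(counts_a, counts_b):
    """Independent Weir & Cockerham (1984) two-population theta,
    coded directly from the published variance-component formulas.

    counts_* : (n_hom_ref, n_het, n_hom_alt) genotype counts per SNP.
    Returns per-SNP (a, b, c) components.
    """
    out = []
    for (a0, a1, a2), (b0, b1, b2) in zip(counts_a, counts_b):
        r = 2
        n_i = np.array([a0 + a1 + a2, b0 + b1 + b2], dtype=float)
        p_i = np.array(
            [(2 * a2 + a1) / (2 * n_i[0]), (2 * b2 + b1) / (2 * n_i[1])]
        )
        h_i = np.array([a1 / n_i[0], b1 / n_i[1]])
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out.append((a, b, c))
    return np.array(out)


def genotype_counts(d):
    return [(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            for col in d.T]


class TestIBSMatrix:
    def test_identical_individuals_distance_zero(self):
        row = np.array([0, 1, 2, 1], dtype=np.int8)
        gm = make_gm(np.vstack([row, row, 2 - row]))
        dm = ibs_matrix(gm)
        assert dm.matrix[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm(np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8))
        assert ibs_matrix(gm).matrix[0, 1] == 1.0

    def test_toy_matches_hand_computation(self):
        d = np.array([[0, 1, 2, 1], [2, 1, 1, 0], [1, 1, 2, 2]], dtype=np.int8)
        dm = ibs_matrix(make_gm(d))
        # pair (0,1): diffs /2 = 1,0,.5,.5 -> IBS .5; (0,2): .5,0,0,.5 -> .75
        assert dm.matrix[0, 1] == pytest.approx(0.5)
        assert dm.matrix[0, 2] == pytest.approx(1 - 0.75)
        assert dm.matrix[1, 2] == pytest.approx((0.5 + 0 + 0.5 + 1) / 4)


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        d = np.vstack([np.zeros((5, 3)), np.full((5, 3), 2)]).astype(np.int8)
        gm = make_gm(d, pops=["A"] * 5 + ["B"] * 5)
        gw, per = wc_fst(gm, "A", "B")
        assert np.allclose(per, 1.0)
        assert gw == pytest.approx(1.0)

    def test_identical_frequencies_theta_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 500)
        draw = lambda n: ((rng.random((n, 500)) < p).astype(np.int8)
                          + (rng.random((n, 500)) < p).astype(np.int8))
        gm = make_gm(np.vstack([draw(100), draw(100)]),
                     pops=["A"] * 100 + ["B"] * 100)
        gw, _ = wc_fst(gm, "A", "B")
        assert abs(gw) < 0.005

    def test_matches_textbook_oracle_to_1e12(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(40, 100)).astype(np.int8)
        gm = make_gm(d, pops=["A"] * 18 + ["B"] * 22)
        gw, per = wc_fst(gm, "A", "B")
        comp = wc_theta_oracle(
            genotype_counts(d[:18]), genotype_counts(d[18:])
        )
        a, b, c = comp[:, 0], comp[:, 1], comp[:, 2]
        expected_per = a / (a + b + c)
        ok = ~np.isnan(expected_per)
        assert np.allclose(per[ok], expected_per[ok], atol=1e-12)
        assert gw == pytest.approx(
            a[ok].sum() / (a + b + c)[ok].sum(), abs=1e-12
        )

    def test_fst_matrix_symmetric_zero_diagonal(self, sim_small):
        _, gm, _ = sim_small
        dm = fst_matrix(gm)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # tree ((a:2,b:3):1,(c:4,d:5)) -> additive distance matrix
        dist = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(list("abcd"), dist))
        tip_dist = {
            frozenset((x.name, y.name)): tree.find(x.name).distance(tree.find(y.name))
            for i, x in enumerate(tree.tips())
            for y in list(tree.tips())[i + 1:]
        }
        for (i, x), (j, y) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")),
                               ((1, "b"), (3, "d")), ((2, "c"), (3, "d"))]:
            assert tip_dist[frozenset((x, y))] == pytest.approx(dist[i, j])

    def test_three_taxa_closed_form(self):
        dist = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("abc"), dist))
        # branch lengths: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(1), "b": pytest.approx(2),
                           "c": pytest.approx(3)}

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n = 6
        base = rng.uniform(1, 5, size=(n, n))
        dist = np.triu(base, 1)
        dist = dist + dist.T + 2.0
        np.fill_diagonal(dist, 0.0)
        labels = list("abcdef")
        t1 = nj_tree(DistanceMatrix(labels, dist))
        perm = rng.permutation(n)
        t2 = nj_tree(
            DistanceMatrix([labels[i] for i in perm], dist[np.ix_(perm, perm)])
        )
        assert t1.compare_rfd(t2) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPcaGrm:
    def test_pc1_separates_deep_split(self, sim_small):
        _, gm, _ = sim_small
        two = gm.subset(
            individuals=np.concatenate([gm.pop_index("P1"), gm.pop_index("O")])
        )
        evec, evals = pca_grm(two, k=2)
        labels = (two.individuals["population"] == "O").to_numpy()
        pc1 = evec[:, 0]
        # perfect partition regardless of sign: group ranges do not overlap
        assert (pc1[labels].min() > pc1[~labels].max()
                or pc1[labels].max() < pc1[~labels].min())

    def test_eigenvalues_nonnegative_descending(self, sim_small):
        _, gm, _ = sim_small
        _, evals = pca_grm(gm, k=5)
        assert np.all(np.diff(evals) <= 1e-10)
        assert evals.min() > -1e-8

    def test_grm_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 800)
        d = ((rng.random((120, 800)) < p).astype(np.int8)
             + (rng.random((120, 800)) < p).astype(np.int8))
        K = grm_matrix(make_gm(d))
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.05)


class TestSupervisedAncestry:
    def _refs(self, m=800, seed=4):
        rng = np.random.default_rng(seed)
        return (
            rng.uniform(0.05, 0.95, m),
            rng.uniform(0.05, 0.95, m),
            rng,
        )

    def test_pure_individual_assigned_to_its_reference(self):
        pa, pb, rng = self._refs(m=2000)
        d = ((rng.random((10, 2000)) < pa).astype(np.int8)
             + (rng.random((10, 2000)) < pa).astype(np.int8))
        q = supervised_ancestry(make_gm(d), {"A": pa, "B": pb})
        assert (q["A"] >= 0.95).all()

    def test_half_mosaic_recovers_half(self):
        pa, pb, rng = self._refs(seed=5)
        # alternate 50-SNP blocks drawn from A and B frequencies
        src = (np.arange(800) // 50) % 2 == 0
        p_ind = np.where(src, pa, pb)
        d = ((rng.random((12, 800)) < p_ind).astype(np.int8)
             + (rng.random((12, 800)) < p_ind).astype(np.int8))
        q = supervised_ancestry(make_gm(d), {"A": pa, "B": pb})
        assert abs(q["A"].mean() - 0.5) < 0.05

    def test_simplex_constraint(self, sim_small):
        _, gm, truth = sim_small
        refs = {
            "native": truth.source_freqs["native"],
            "donor": truth.source_freqs["donor"],
        }
        q = supervised_ancestry(gm.subset(individuals=gm.pop_index("P2")), refs)
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-9)
        assert (q.to_numpy() >= 0).all() and (q.to_numpy() <= 1).all()

    def test_recovers_pulse_fraction(self, sim_small):
        _, gm, truth = sim_small
        refs = {
            "native": truth.source_freqs["native"],
            "donor": truth.source_freqs["donor"],
        }
        q = supervised_ancestry(gm.subset(individuals=gm.pop_index("P2")), refs)
        assert abs(q["donor"].mean() - truth.donor_fraction("P2")) < 0.05


class TestClassifyConservation:
    def test_printed_cutpoints(self):
        """Mean 73.25% and SD 12.22% put the tier boundaries at 61.03%
        and 48.81% of native-lineage ancestry."""
        props = pd.DataFrame({"CN": np.linspace(0.3, 0.9, 20)},
                             index=[f"i{k}" for k in range(20)])
        g = classify_conservation(props, "CN", mean=0.7325, sd=0.1222)
        assert g.cutpoints["minus1sd"] == pytest.approx(0.6103)
        assert g.cutpoints["minus2sd"] == pytest.approx(0.4881)

    def test_bin_lookup_with_supplied_moments(self):
        props = pd.DataFrame({"CN": [0.90, 0.80, 0.62, 0.40]},
                             index=list("wxyz"))
        g = classify_conservation(props, "CN", mean=0.7, sd=0.1)
        assert list(g.assignments["group"]) == [
            "nucleus", "nucleus", "candidate1", "discard"
        ]

    def test_some_individual_below_mean(self):
        rng = np.random.default_rng(6)
        props = pd.DataFrame({"CN": rng.uniform(0.3, 0.9, 50)},
                             index=[f"i{k}" for k in range(50)])
        g = classify_conservation(props, "CN")
        assert (g.assignments["group"] != "nucleus").any()

    def test_zero_variance_rejected(self):
        props = pd.DataFrame({"CN": [0.5] * 5}, index=list("abcde"))
        with pytest.raises(ValueError):
            classify_conservation(props, "CN")

    def test_inbreeding_outliers_flagged(self):
        idx = [f"i{k}" for k in range(20)]
        props = pd.DataFrame({"CN": np.linspace(0.4, 0.9, 20)}, index=idx)
        f = pd.Series(0.05, index=idx)
        f.iloc[3] = 0.9  # way above mean + 2 sd
        g = classify_conservation(props, "CN", inbreeding=f)
        assert g.assignments.loc[3, "inbreeding_outlier"]
        assert g.assignments["inbreeding_outlier"].sum() == 1


class TestAssignFamilies:
    def test_two_clades_one_male_each(self):
        tree = TreeNode.read(["((m1:0.1,f1:0.1,f2:0.1):1.0,(m2:0.1,f3:0.1):1.0);"])
        sex = {"m1": "male", "m2": "male", "f1": "female", "f2": "female",
               "f3": "female"}
        fams = assign_families(tree, sex)
        by_fam = fams.groupby("family")["id"].apply(set)
        assert len(by_fam) == 2
        assert {"m1", "f1", "f2"} in set(map(frozenset, by_fam))

    def test_star_three_males_three_families(self):
        tree = TreeNode.read(["(m1:1.0,m2:1.0,m3:1.0);"])
        fams = assign_families(tree, {f"m{i}": "male" for i in (1, 2, 3)})
        assert fams["family"].nunique() == 3

    def test_all_female_rejected(self):
        tree = TreeNode.read(["(f1:1.0,f2:1.0,f3:1.0);"])
        with pytest.raises(ValueError):
            assign_families(tree, {f"f{i}": "female" for i in (1, 2, 3)})

    def test_family_count_override(self):
        tree = TreeNode.read(
            ["((m1:0.1,f1:0.1):1.0,((m2:0.1,f2:0.1):0.8,(m3:0.1,f3:0.1):0.9):1.0);"]
        )
        sex = {"m1": "male", "m2": "male", "m3": "male",
               "f1": "female", "f2": "female", "f3": "female"}
        fams = assign_families(tree, sex, n_families=2)
        assert fams["family"].nunique() == 2
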