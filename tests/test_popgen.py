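"""Nei distances, neighbour joining, admixture, coancestry, selection S."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from photoadapt.popgen import (GenotypeMatrix, QMatrix, allele_freq_by_subpop,
                               assign_subpops, bootstrap_support, choose_k,
                               coancestry, estimate_admixture, nei_distance,
                               nei_distance_matrix, nj_tree, selection_S,
                               tree_bipartitions, _project_simplex)
from photoadapt.synthdata import SimConfig, simulate_genotypes


class TestNeiDistance:
    def test_identical_vectors_give_zero(self, rng):
        f = rng.uniform(0, 1, 200)
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        fx, fy = rng.uniform(0, 1, (2, 300))
        assert nei_distance(fx, fy) == pytest.approx(nei_distance(fy, fx))

    def test_orthogonal_fixed_vectors_hit_cap(self):
        fx = np.array([1.0, 1.0]); fy = np.array([0.0, 0.0])
        with pytest.warns(UserWarning):
            assert nei_distance(fx, fy, cap=10.0) == 10.0

    def test_matches_direct_formula(self, rng):
        fx, fy = rng.uniform(0.05, 0.95, (2, 500))
        jx = np.mean(fx ** 2 + (1 - fx) ** 2)
        jy = np.mean(fy ** 2 + (1 - fy) ** 2)
        jxy = np.mean(fx * fy + (1 - fx) * (1 - fy))
        assert nei_distance(fx, fy) == pytest.approx(-np.log(jxy / np.sqrt(jx * jy)))


class TestNeighbourJoining:
    def test_four_taxon_additive_tree_recovered_exactly(self):
        # ((A:2,B:3):1,(C:4,D:5)) gives these pairwise path lengths
        d = np.array([[0, 5, 7, 8],
                      [5, 0, 8, 9],
                      [7, 8, 0, 9],
                      [8, 9, 9, 0]], dtype=float)
        tree = nj_tree(d, ["A", "B", "C", "D"])
        parts = tree_bipartitions(tree)
        assert parts == {frozenset({"C", "D"})}  # == AB|CD split
        tt = tree.tip_tip_distances()
        ids = list(tt.ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                ia, ib = "ABCD".index(a), "ABCD".index(b)
                assert tt.data[i, j] == pytest.approx(d[ia, ib])

    def test_agrees_with_reference_nj_topology(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        f = rng.uniform(0.1, 0.9, (7, 400))
        d = nei_distance_matrix(f)
        labels = [f"t{i}" for i in range(7)]
        mine = nj_tree(d, labels)
        ref = skbio_nj(DistanceMatrix(d, ids=labels))
        assert tree_bipartitions(mine) == tree_bipartitions(ref)

    def test_bootstrap_support_high_for_clear_split(self, two_pop_panel):
        _, gm, truth = two_pop_panel
        lab = truth.true_subpop
        freqs = allele_freq_by_subpop(gm, lab)
        # four taxa: the two subpops plus two perturbed copies
        rng = np.random.default_rng(0)
        f1, f2 = freqs.loc["subpop1"].to_numpy(), freqs.loc["subpop2"].to_numpy()
        mat = np.vstack([f1, np.clip(f1 + rng.normal(0, 0.02, f1.size), 0, 1),
                         f2, np.clip(f2 + rng.normal(0, 0.02, f2.size), 0, 1)])
        tree = bootstrap_support(mat, ["p1a", "p1b", "p2a", "p2b"],
                                 n_replicates=50, seed=1)
        sups = [n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")]
        assert sups and min(sups) > 0.95


class TestAdmixture:
    def test_q_rows_on_simplex(self, two_pop_panel):
        _, gm, _ = two_pop_panel
        q = estimate_admixture(gm, 2, seed=0)
        assert np.allclose(q.q.sum(axis=1), 1.0, atol=1e-6)
        assert q.q.min() >= -1e-9

    def test_two_pop_label_recovery(self, two_pop_panel, label_match_accuracy):
        _, gm, truth = two_pop_panel
        q = estimate_admixture(gm, 2, seed=0)
        labels = assign_subpops(q)
        nonadm = truth.true_subpop[truth.true_subpop != "admixed"]
        maxq = q.q.max(axis=1)[:len(nonadm)]
        assert (maxq > 0.9).mean() >= 0.95
        assert label_match_accuracy(nonadm, labels[nonadm.index]) >= 0.95

    def test_choose_k_self_consistent(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_subpops=3,
                            accessions_per_subpop=(40, 40, 40), n_admixed=0,
                            n_snps=1500, fst=0.2)
            gm, _ = simulate_genotypes(cfg)
            hits += choose_k(gm) == 3
        assert hits >= 8

    def test_k_not_smaller_than_panel(self, two_pop_panel):
        _, gm, _ = two_pop_panel
        with pytest.raises(ValueError):
            estimate_admixture(gm, gm.n_accessions)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=8))
    def test_simplex_projection_feasible_and_idempotent(self, v):
        p = _project_simplex(np.array([v]))
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(_project_simplex(p), p, atol=1e-12)


class TestAssignment:
    def test_majority_cluster_assigned(self):
        q = QMatrix(q=np.array([[0.6, 0.3, 0.1]]), accessions=["x"])
        assert assign_subpops(q)["x"] == "subpop1"

    def test_no_majority_is_admixed(self):
        q = QMatrix(q=np.array([[0.45, 0.45, 0.10]]), accessions=["x"])
        assert assign_subpops(q)["x"] == "admixed"

    def test_strict_inequality_at_half(self):
        eps = 1e-9
        q = QMatrix(q=np.array([[0.5 + eps, 0.5 - eps], [0.5, 0.5]]),
                    accessions=["x", "y"])
        lab = assign_subpops(q)
        assert lab["x"] == "subpop1" and lab["y"] == "admixed"


class TestAlleleFrequencies:
    def test_counting_oracle_on_small_matrices(self, rng):
        for _ in range(5):
            codes = rng.integers(0, 2, (9, 12)).astype(np.int8)
            codes[rng.random((9, 12)) < 0.2] = -1
            gm = GenotypeMatrix(
                codes=codes, accessions=[f"a{i}" for i in range(9)],
                snp_ids=[f"s{j}" for j in range(12)],
                chrom=np.array(["1H"] * 12), pos=np.arange(1, 13))
            labels = pd.Series(["A"] * 4 + ["B"] * 4 + ["admixed"],
                               index=gm.accessions)
            freqs = allele_freq_by_subpop(gm, labels)
            for sp, rows in [("A", range(4)), ("B", range(4, 8))]:
                for j in range(12):
                    vals = [codes[i, j] for i in rows if codes[i, j] != -1]
                    expect = np.mean(vals) if vals else np.nan
                    got = freqs.loc[sp, f"s{j}"]
                    assert (np.isnan(got) and np.isnan(expect)) or \
                        got == pytest.approx(expect)

    def test_bounds_and_fixed_allele(self):
        codes = np.array([[0, 1], [1, 1], [1, 1]], dtype=np.int8)
        gm = GenotypeMatrix(codes=codes, accessions=["a", "b", "c"],
                            snp_ids=["s1", "s2"], chrom=np.array(["1H", "1H"]),
                            pos=np.array([1, 2]))
        labels = pd.Series(["A", "A", "A"], index=gm.accessions)
        freqs = allele_freq_by_subpop(gm, labels)
        assert freqs.loc["A", "s1"] == pytest.approx(2 / 3)
        assert freqs.loc["A", "s2"] == 1.0


class TestCoancestry:
    def test_symmetric_psd_with_fst_scale_diagonal(self, eight_pop_panel):
        _, gm, truth = eight_pop_panel
        theta = coancestry(gm, truth.true_subpop)
        assert np.allclose(theta.theta, theta.theta.T)
        assert np.linalg.eigvalsh(theta.theta).min() >= -1e-10
        # Balding–Nichols: E[θ_AA] ≈ F_ST = 0.15
        assert np.diag(theta.theta).mean() == pytest.approx(0.15, abs=0.04)

    def test_panmictic_offdiagonals_vanish(self):
        cfg = SimConfig(seed=5, n_subpops=2, accessions_per_subpop=(60, 60),
                        n_admixed=0, n_snps=5000, fst=0.005)
        gm, truth = simulate_genotypes(cfg)
        # label arbitrarily: effectively one panmictic pool split in two
        labels = pd.Series(["A"] * 60 + ["B"] * 60, index=gm.accessions)
        theta = coancestry(gm, labels)
        assert abs(theta.theta[0, 1]) < 0.02

    def test_duplicated_subpopulation_attains_max_coancestry(self, two_pop_panel):
        _, gm, truth = two_pop_panel
        lab = truth.true_subpop.copy()
        half1 = [a for a, s in lab.items() if s == "subpop1"][:25]
        lab[half1] = "subpop1b"  # split one subpop into two identical pools
        theta = coancestry(gm, lab)
        names = theta.subpops
        i, j = names.index("subpop1"), names.index("subpop1b")
        off = theta.theta.copy()
        np.fill_diagonal(off, -np.inf)
        assert off[i, j] == pytest.approx(off.max())


@pytest.fixture(scope="module")
def theta(eight_pop_panel):
    _, gm, truth = eight_pop_panel
    return coancestry(gm, truth.true_subpop)


class TestSelectionS:

    def test_no_divergence_gives_zero(self, theta):
        res = selection_S(np.full(8, 3.3), 1.0, theta, n_draws=500, seed=0)
        assert res.s == 0.0
        assert res.d_observed == pytest.approx(0.0, abs=1e-12)

    def test_neutral_probability_integral_transform(self, theta):
        rng = np.random.default_rng(77)
        sigma = 2.0 * theta.theta
        lam, vec = np.linalg.eigh(sigma)
        root = vec * np.sqrt(np.maximum(lam, 0))
        svals = [selection_S(1.0 + root @ rng.standard_normal(8), 1.0,
                             theta, n_draws=800, seed=r).s
                 for r in range(300)]
        assert 0.45 <= np.mean(svals) <= 0.55

    def test_divergent_perturbation_detected(self, theta):
        m = 5.0 + 5.0 * np.array([1, -1] * 4, dtype=float)
        assert selection_S(m, 1.0, theta, n_draws=3000, seed=1).s > 0.95

    def test_invariance_to_shift_and_unit_rescaling(self, theta):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, 8)
        base = selection_S(m, 1.0, theta, n_draws=1000, seed=9).s
        shifted = selection_S(m + 100.0, 1.0, theta, n_draws=1000, seed=9).s
        scaled = selection_S(10.0 * m, 100.0, theta, n_draws=1000, seed=9).s
        assert base == shifted == scaled
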