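import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msapkit import (
    DistanceMatrix,
    EmptyAnalysisError,
    MsapError,
    SimulationConfig,
    aflp_mode_phist,
    amova,
    n_distinct_assignments,
    pairwise_distance,
    pairwise_phist,
    pcoa,
    phist_matrix,
    simulate_dataset,
)


# ---------------------------------------------------------------------------
# Brute-force AMOVA oracle: direct evaluation of the SS formulas
# ---------------------------------------------------------------------------


def amova_oracle(d2, labels):
    """Plain-loop evaluation of the AMOVA sums of squares and components."""
    n = len(labels)
    groups = sorted(set(labels))
    k = len(groups)
    ss_total = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d2[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    sigma2_w = ss_within / (n - k)
    n0 = (n - sum(len([i for i in range(n) if labels[i] == g]) ** 2 for g in groups) / n) / (k - 1)
    sigma2_a = (ss_among / (k - 1) - sigma2_w) / n0
    phi = sigma2_a / (sigma2_a + sigma2_w) if (sigma2_a + sigma2_w) != 0 else 0.0
    return ss_among, ss_within, sigma2_a, sigma2_w, phi


def random_instance(rng, n_max=8):
    """Random squared-distance matrix and a 2-3 group labelling, sizes >= 2."""
    while True:
        k = rng.integers(2, 4)
        sizes = rng.integers(2, 4, size=k)
        if sizes.sum() <= n_max:
            break
    n = int(sizes.sum())
    pts = rng.normal(size=(n, 3))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    labels = np.repeat([f"g{i}" for i in range(k)], sizes)
    perm = rng.permutation(n)
    return d2[np.ix_(perm, perm)], labels[perm]


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        mat = np.tile([1.0, 0.0, 1.0], (3, 1))
        dist = pairwise_distance(mat)
        np.testing.assert_allclose(dist.values, 0.0)

    def test_mismatch_count_without_missing(self):
        mat = np.array([[1, 0, 1, 0], [1, 1, 0, 0]], dtype=float)  # 2 mismatches
        dist = pairwise_distance(mat)
        assert dist.values[0, 1] == pytest.approx(2.0)

    def test_missing_rescaling(self):
        # length 4, one missing position, 1 mismatch among 3 compared -> 4/3
        mat = np.array([[1, 0, 1, np.nan], [1, 1, 1, 0]], dtype=float)
        dist = pairwise_distance(mat)
        assert dist.values[0, 1] == pytest.approx(4 / 3)

    def test_no_shared_loci_names_pair(self):
        mat = np.array([[1, np.nan], [np.nan, 0], [1, 0]], dtype=float)
        with pytest.raises(MsapError, match="ind0.*ind1|ind1.*ind0"):
            pairwise_distance(mat)

    def test_complete_case_policy_drops_missing_loci(self):
        mat = np.array([[1, 0, np.nan], [0, 0, 1], [1, 1, 0]], dtype=float)
        dist = pairwise_distance(mat, missing_policy="complete")
        # only loci 0 and 1 remain, rescaled by 2/2
        assert dist.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(MsapError):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(MsapError):
            DistanceMatrix(ids=["a", "b"], values=np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestAMOVA:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            d2, labels = random_instance(rng)
            dist = DistanceMatrix(ids=[f"i{k}" for k in range(len(labels))], values=d2)
            res = amova(dist, labels, n_perm=1, seed=0)
            ss_a, ss_w, s2a, s2w, phi = amova_oracle(d2.tolist(), list(labels))
            assert res.ss_among == pytest.approx(ss_a, abs=1e-10)
            assert res.ss_within == pytest.approx(ss_w, abs=1e-10)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-10)
            assert res.sigma2_within == pytest.approx(s2w, abs=1e-10)
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d2, labels = random_instance(rng)
            if n_distinct_assignments(labels) > 10_000:
                continue
            dist = DistanceMatrix(ids=[f"i{k}" for k in range(len(labels))], values=d2)
            res = amova(dist, labels, method="exact")
            # oracle: loop over all multiset permutations of the labels
            obs_phi = amova_oracle(d2.tolist(), list(labels))[4]
            hits = total = 0
            seen = set()
            for perm in itertools.permutations(range(len(labels))):
                key = tuple(labels[list(perm)])
                if key in seen:
                    continue
                seen.add(key)
                total += 1
                hits += amova_oracle(d2.tolist(), list(key))[4] >= obs_phi - 1e-12
            assert res.p_value == pytest.approx(hits / total)

    def test_monte_carlo_p_close_to_exact(self):
        rng = np.random.default_rng(21)
        d2, labels = random_instance(rng)
        dist = DistanceMatrix(ids=[f"i{k}" for k in range(len(labels))], values=d2)
        exact = amova(dist, labels, method="exact")
        mc = amova(dist, labels, n_perm=20_000, seed=5)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_fixed_complementary_groups_phi_one(self):
        mat = np.array([[1, 1, 1]] * 3 + [[0, 0, 0]] * 3, dtype=float)
        dist = pairwise_distance(mat)
        res = amova(dist, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.sigma2_within == pytest.approx(0.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_exchangeable_pool_phi_near_zero(self):
        rng = np.random.default_rng(3)
        mat = (rng.random((40, 60)) < 0.5).astype(float)
        dist = pairwise_distance(mat)
        res = amova(dist, ["a"] * 20 + ["b"] * 20, n_perm=199, seed=1)
        assert abs(res.phi_st) < 0.05
        assert res.p_value > 0.01

    def test_p_in_zero_one_and_positive(self):
        mat = np.array([[1, 1, 0]] * 3 + [[0, 1, 1]] * 3, dtype=float)
        dist = pairwise_distance(mat)
        res = amova(dist, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=4)
        assert 0 < res.p_value <= 1

    def test_singleton_group_rejected(self):
        mat = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
        dist = pairwise_distance(mat)
        with pytest.raises(MsapError, match="[Ss]ingleton"):
            amova(dist, ["a", "a", "b"], n_perm=10, seed=0)

    def test_nperm_zero_rejected(self):
        mat = np.array([[1, 0]] * 2 + [[0, 1]] * 2, dtype=float)
        dist = pairwise_distance(mat)
        with pytest.raises(MsapError):
            amova(dist, ["a", "a", "b", "b"], n_perm=0, seed=0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_invariant_to_relabeling_within_populations(self, seed):
        rng = np.random.default_rng(seed)
        mat = (rng.random((10, 12)) < 0.5).astype(float)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        dist = pairwise_distance(mat)
        base = amova(dist, labels, n_perm=1, seed=0).phi_st
        # permute individuals within each population
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        dist_p = pairwise_distance(mat[perm])
        assert amova(dist_p, labels[perm], n_perm=1, seed=0).phi_st == pytest.approx(base)
        # locus permutation leaves distances unchanged
        dist_l = pairwise_distance(mat[:, rng.permutation(12)])
        assert amova(dist_l, labels, n_perm=1, seed=0).phi_st == pytest.approx(base)

    def test_permutation_reproducible_from_seed(self):
        rng = np.random.default_rng(1)
        mat = (rng.random((12, 20)) < 0.5).astype(float)
        dist = pairwise_distance(mat)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = amova(dist, labels, n_perm=500, seed=99).p_value
        p2 = amova(dist, labels, n_perm=500, seed=99).p_value
        assert p1 == p2


class TestPairwisePhist:
    def test_table_shape_and_symmetry(self):
        rng = np.random.default_rng(8)
        mat = (rng.random((18, 30)) < 0.5).astype(float)
        groups = np.repeat(["a", "b", "c"], 6)
        table = pairwise_phist(mat, [f"i{k}" for k in range(18)], groups, n_perm=49, seed=2)
        assert len(table) == 3
        square = phist_matrix(table)
        np.testing.assert_allclose(square.values, square.values.T)
        np.testing.assert_allclose(np.diag(square.values), 0.0)

    def test_split_of_one_pool_phi_near_zero(self):
        rng = np.random.default_rng(10)
        mat = (rng.random((30, 40)) < 0.4).astype(float)
        groups = np.array(["a"] * 15 + ["b"] * 15)
        table = pairwise_phist(mat, [f"i{k}" for k in range(30)], groups, n_perm=99, seed=0)
        assert abs(table["phi_st"].iloc[0]) < 0.05

    def test_negative_phi_reported_not_truncated(self):
        # near-identical groups commonly give slightly negative estimates
        rng = np.random.default_rng(0)
        found = False
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mat = (rng.random((10, 25)) < 0.5).astype(float)
            table = pairwise_phist(
                mat, [f"i{k}" for k in range(10)], ["a"] * 5 + ["b"] * 5, n_perm=9, seed=1
            )
            if table["phi_st"].iloc[0] < 0:
                found = True
                break
        assert found


class TestPCoA:
    def test_reconstructs_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0], [-1.0, -2.0]])
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        dist = DistanceMatrix(ids=list("abcde"), values=d2)
        res = pcoa(dist)
        rec = res.coordinates
        d2_rec = ((rec[:, None] - rec[None, :]) ** 2).sum(-1)
        np.testing.assert_allclose(d2_rec, d2, atol=1e-9)
        # coordinates centered at the origin
        np.testing.assert_allclose(rec.mean(axis=0), 0.0, atol=1e-9)

    def test_equilateral_triangle_equal_eigenvalues(self):
        d2 = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(ids=list("abc"), values=d2))
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 3))
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        res = pcoa(DistanceMatrix(ids=[f"i{k}" for k in range(7)], values=d2))
        n = 7
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        assert res.eigenvalues.sum() + res.negative_eigenvalues.sum() == pytest.approx(
            np.trace(g)
        )

    def test_axes_ordered_by_decreasing_eigenvalue(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(8, 4))
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        res = pcoa(DistanceMatrix(ids=[f"i{k}" for k in range(8)], values=d2))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_all_zero_distances_degenerate(self):
        dist = DistanceMatrix(ids=list("abc"), values=np.zeros((3, 3)))
        with pytest.raises(EmptyAnalysisError):
            pcoa(dist)

    def test_agrees_with_skbio(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        import skbio

        rng = np.random.default_rng(4)
        mat = (rng.random((9, 15)) < 0.5).astype(float)
        dist = pairwise_distance(mat)
        ours = pcoa(dist)
        # skbio expects plain distances and squares them internally
        dm = skbio.DistanceMatrix(np.sqrt(dist.values), ids=dist.ids)
        theirs = skbio_ordination.pcoa(dm, method="eigh")
        k = len(ours.eigenvalues)
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, :3]),
            np.abs(theirs.samples.values[:, :3]),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.values[:k], atol=1e-8
        )


class TestAflpMode:
    def test_concatenation_doubles_locus_count_before_filter(self, small_simulation):
        pair, sheet, _ = small_simulation
        concat = np.hstack([pair.hpa, pair.msp])
        assert concat.shape[1] == 2 * pair.n_loci

    def test_identical_populations_phi_near_zero(self):
        config = SimulationConfig(
            sizes=(15, 15),
            n_loci=100,
            methylation_means=(0.6, 0.6),
            divergence_f=0.0,
            seed=11,
        )
        pair, sheet, _ = simulate_dataset(config)
        res, table = aflp_mode_phist(pair, sheet.groups(pair.individuals), n_perm=99, seed=3)
        assert abs(res.phi_st) < 0.05
        assert len(table) == 1

    def test_diverged_populations_detected(self):
        config = SimulationConfig(
            sizes=(15, 15),
            n_loci=150,
            methylation_means=(0.6, 0.6),
            divergence_f=0.25,
            seed=12,
        )
        pair, sheet, _ = simulate_dataset(config)
        res, _ = aflp_mode_phist(pair, sheet.groups(pair.individuals), n_perm=199, seed=3)
        assert res.phi_st > 0.03
        assert res.p_value < 0.05
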