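import numpy as np
import pandas as pd
import pytest

from symbiorad.analysis import (
    DapcConfig,
    dapc_fit,
    nj_tree,
    p_distance_matrix,
    predict_membership,
    regress_counts_vs_divergence,
    shared_loci_matrix,
    tree_splits,
)
from symbiorad.clustering import LocusCluster, SnpMatrix
from symbiorad.io import read_phylip, write_phylip
from symbiorad.loci import ConsensusLocus

from .oracles import ols_normal_equations


def _cluster(cid, sample_rows):
    members = {s: ConsensusLocus(f"{s}_{cid}", r.replace("-", "")) for s, r in sample_rows.items()}
    return LocusCluster(cid, members, dict(sample_rows), [])


class TestSharedLoci:
    def test_identical_membership_gives_one(self):
        clusters = [_cluster(f"C{i}", {"A": "ACGT", "B": "ACGT"}) for i in range(3)]
        m = shared_loci_matrix(clusters, ["A", "B"])
        assert m.proportions[0, 1] == 1.0
        assert np.allclose(np.diag(m.proportions), 1.0)

    def test_disjoint_membership_gives_zero(self):
        clusters = [
            _cluster("C0", {"A": "ACGT", "C": "ACGT"}),
            _cluster("C1", {"B": "ACGT", "C": "ACGT"}),
        ]
        m = shared_loci_matrix(clusters, ["A", "B", "C"])
        assert m.proportions[0, 1] == 0.0

    def test_three_sample_hand_enumeration(self):
        # A: {C0,C1,C2}, B: {C0,C1}, C: {C2}
        clusters = [
            _cluster("C0", {"A": "ACGT", "B": "ACGT"}),
            _cluster("C1", {"A": "ACGT", "B": "ACGT"}),
            _cluster("C2", {"A": "ACGT", "C": "ACGT"}),
        ]
        m = shared_loci_matrix(clusters, ["A", "B", "C"]).to_frame()
        assert m.loc["A", "B"] == pytest.approx(2 / 2)  # min(3, 2)
        assert m.loc["A", "C"] == pytest.approx(1 / 1)
        assert m.loc["B", "C"] == pytest.approx(0.0)
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_empty_sample_flagged_nan(self):
        clusters = [_cluster("C0", {"A": "ACGT", "B": "ACGT"})]
        m = shared_loci_matrix(clusters, ["A", "B", "Z"])
        assert np.isnan(m.proportions[2]).all()


class TestRegression:
    def test_exact_line(self):
        res = regress_counts_vs_divergence([0, 2, 4, 6, 8], [0, 1, 2, 3, 4])
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [10.0, 8.0, 9.0, 5.0]
        res = regress_counts_vs_divergence(y, x)
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_dict_inputs_align_on_samples(self):
        res = regress_counts_vs_divergence(
            {"a": 10, "b": 8, "c": 9, "d": 5}, {"a": 0, "b": 1, "c": 2, "d": 3}
        )
        assert res.n == 4

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            regress_counts_vs_divergence([1, 2], [0, 1])
        with pytest.raises(ValueError, match="zero variance"):
            regress_counts_vs_divergence([1, 2, 3], [5, 5, 5])


class TestNeighborJoining:
    def test_three_samples_unique_topology(self):
        nwk = nj_tree(np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]), ["A", "B", "C"])
        assert tree_splits(nwk) == set()  # 3-tip tree has no non-trivial split

    def test_additive_matrix_recovered_exactly(self):
        # metric of ((A:1,B:2):3,(C:4,D:5))
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        nwk = nj_tree(D, ["A", "B", "C", "D"])
        assert tree_splits(nwk) == {frozenset({"A", "B"})}
        # NJ is consistent on additive input: branch lengths appear verbatim
        assert ":1.000000" in nwk and ":3.000000" in nwk

    def test_pairwise_deletion_and_zero_overlap_error(self):
        data = np.array(
            [["A", "N", "C"], ["A", "G", "N"], ["N", "G", "C"]], dtype="<U1"
        )
        snps = SnpMatrix(["x", "y", "z"], [("C0", 0), ("C1", 0), ("C2", 0)], data)
        dist, _ = p_distance_matrix(snps)
        assert dist[0, 1] == 0.0  # only site 0 overlaps, identical
        bad = SnpMatrix(
            ["x", "y"], [("C0", 0)], np.array([["A"], ["N"]], dtype="<U1")
        )
        with pytest.raises(ValueError, match=r"\(x, y\)"):
            p_distance_matrix(bad)

    def test_negative_branches_clamped(self):
        D = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0.0]])
        nwk = nj_tree(D, list("ABCD"))
        assert ":-" not in nwk


def _two_group_snps(seed=0, n_per_group=10, n_sites=500, n_fixed=50, missing=0.10):
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    data = np.full((2 * n_per_group, n_sites), "A", dtype="<U1")
    fixed = rng.choice(n_sites, n_fixed, replace=False)
    data[n_per_group:, fixed] = "G"
    for j in range(n_sites):
        if j not in set(fixed):
            data[rng.integers(0, 2 * n_per_group), j] = "C"
    if missing:
        data[rng.random(data.shape) < missing] = "N"
    sites = [(f"C{j:04d}", 0) for j in range(n_sites)]
    labels = {s: s[0] for s in samples}
    return SnpMatrix(samples, sites, data), labels


class TestDapc:
    def test_site_above_missing_cutoff_excluded(self):
        data = np.array(
            [["A"] * 2 for _ in range(10)], dtype="<U1"
        )
        data[0, 0] = "G"
        data[1:4, 0] = "N"  # 3 of 10 missing = 30% > 20%
        data[5:, 1] = "G"  # clean separated site
        snps = SnpMatrix([f"s{i}" for i in range(10)], [("C0", 0), ("C1", 0)], data)
        labels = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        res = dapc_fit(snps, labels, DapcConfig(n_pcs=1))
        assert ("C0", 0) not in res.retained_sites
        assert ("C1", 0) in res.retained_sites

    def test_separated_groups_fully_assigned(self):
        snps, labels = _two_group_snps()
        res = dapc_fit(snps, labels, DapcConfig(n_pcs=5))
        pred = res.membership.idxmax(axis=1)
        assert all(pred[s] == labels[s] for s in snps.samples)
        self_prob = [res.membership.loc[s, labels[s]] for s in snps.samples]
        assert np.mean(self_prob) >= 0.99

    def test_membership_rows_sum_to_one(self):
        snps, labels = _two_group_snps(seed=3)
        res = dapc_fit(snps, labels)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_npcs_above_rank_reduced_with_warning(self):
        snps, labels = _two_group_snps(seed=4, n_per_group=3, n_sites=40, n_fixed=10, missing=0)
        with pytest.warns(UserWarning, match="reduced"):
            res = dapc_fit(snps, labels, DapcConfig(n_pcs=50))
        assert res.pc_components.shape[0] < 50

    def test_agrees_with_sklearn_lda_on_separable_data(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.decomposition import PCA

        snps, labels = _two_group_snps(seed=5, missing=0.0)
        res = dapc_fit(snps, labels, DapcConfig(n_pcs=5))
        # independent route: same coding, sklearn PCA + LDA classification
        X = (snps.data != "A").astype(float)
        keep = [j for j, site in enumerate(snps.site_ids) if site in set(res.retained_sites)]
        scores = PCA(n_components=5).fit_transform(X[:, keep])
        y = [labels[s] for s in snps.samples]
        lda = LinearDiscriminantAnalysis().fit(scores, y)
        assert list(lda.predict(scores)) == list(res.membership.idxmax(axis=1))


class TestPredictMembership:
    def test_training_samples_reproduced(self):
        snps, labels = _two_group_snps(seed=6)
        res = dapc_fit(snps, labels)
        pred = predict_membership(res, snps)
        assert np.allclose(pred.values, res.membership.values, atol=1e-9)

    def test_new_sample_from_group_assigned_to_it(self):
        snps, labels = _two_group_snps(seed=7, missing=0.0)
        res = dapc_fit(snps, labels)
        new = SnpMatrix(["newB"], snps.site_ids, snps.data[-1:].copy())
        pred = predict_membership(res, new)
        assert pred.idxmax(axis=1)["newB"] == "B"

    def test_hybrid_rows_divided_between_groups_on_average(self):
        # A 50/50 hybrid of two moderately separated groups is, over
        # replicates, assigned intermediate membership and with visibly less
        # confidence than pure group members (Gaussian posteriors are sharp,
        # so single replicates can still land near 0 or 1).
        import warnings

        def build(seed, n=15, m=300, nf=12, noise=0.15):
            rng = np.random.default_rng(seed)
            samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
            data = np.full((2 * n, m), "A", dtype="<U1")
            fixed = np.sort(rng.choice(m, nf, replace=False))
            data[n:, fixed] = "G"
            flip = rng.random(data.shape) < noise
            alt = np.where(data == "A", "G", "A")
            data[flip] = alt[flip]
            sites = [(f"C{j:04d}", 0) for j in range(m)]
            return SnpMatrix(samples, sites, data), {s: s[0] for s in samples}, fixed, rng

        hybrid_a, hybrid_conf, pure_conf = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(30):
                snps, labels, fixed, rng = build(seed)
                res = dapc_fit(snps, labels)
                hyb = np.full(snps.shape[1], "A", dtype="<U1")
                pick = rng.random(len(fixed)) < 0.5
                hyb[fixed[pick]] = "G"
                p = predict_membership(
                    res, SnpMatrix(["h"], snps.site_ids, hyb[None, :])
                ).loc["h", "A"]
                hybrid_a.append(float(p))
                hybrid_conf.append(max(p, 1 - p))
                pure_conf.append(res.membership.values.max(axis=1).mean())
        assert 0.2 <= np.mean(hybrid_a) <= 0.8
        assert np.mean(hybrid_conf) < np.mean(pure_conf) - 0.05


class TestExport:
    def test_phylip_roundtrip_preserves_long_names(self, tmp_path):
        snps, _ = _two_group_snps(seed=9, n_per_group=3, n_sites=20, n_fixed=5)
        snps.samples[0] = "a_very_long_sample_name_indeed"
        path = tmp_path / "m.phy"
        write_phylip(snps, path)
        names, data = read_phylip(path)
        assert names == snps.samples
        assert (data == snps.data).all()

    def test_newick_reparses_to_same_topology(self):
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        nwk = nj_tree(D, ["A", "B", "C", "D"])
        assert tree_splits(nwk) == tree_splits(nwk.strip())
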