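import numpy as np
import pytest

from symbiorad.clustering import (
    ClusterParams,
    LocusCluster,
    cluster_across,
    consensus,
    dataset_stats,
    extract_unlinked_snps,
    filter_samples,
    per_sample_locus_counts,
    within_sample_cluster,
)
from symbiorad.digest import SimReadParams, SizeWindow, simulate_rad_sample
from symbiorad.enzymes import get_enzyme
from symbiorad.loci import ConsensusLocus, SampleLociSet
from symbiorad.seqs import canonical, revcomp
from symbiorad.synth import evolve_genome, random_genome

from .oracles import clustering_instance, mutate, single_linkage_partition


def _sample(sample_id, seqs, depth=5):
    return SampleLociSet(
        sample_id,
        "simulated",
        [ConsensusLocus(f"{sample_id}_{i}", s, depth) for i, s in enumerate(seqs)],
    )


class TestWithinSample:
    def test_five_identical_reads_one_consensus(self):
        read = random_genome(140, 0.5, 1)
        out = within_sample_cluster([read] * 5, ClusterParams(), "s")
        assert len(out) == 1
        assert out.loci[0].sequence == canonical(read)
        assert out.loci[0].depth == 5

    def test_below_min_depth_discarded(self):
        read = random_genome(140, 0.5, 2)
        assert len(within_sample_cluster([read] * 3, ClusterParams(), "s")) == 0

    def test_two_divergent_groups_stay_separate(self):
        rng = np.random.default_rng(3)
        a = random_genome(140, 0.5, 4)
        b = mutate(a, 28, rng)  # 80% identity, below the 0.90 threshold
        out = within_sample_cluster([a] * 5 + [b] * 5, ClusterParams(), "s")
        assert len(out) == 2

    def test_orientation_insensitive(self):
        read = random_genome(140, 0.5, 5)
        out = within_sample_cluster([read, revcomp(read)] * 3, ClusterParams(), "s")
        assert len(out) == 1 and out.loci[0].depth == 6

    def test_sequencing_errors_absorbed_into_consensus(self):
        rng = np.random.default_rng(6)
        read = random_genome(140, 0.5, 7)
        noisy = [mutate(read, 2, rng) for _ in range(3)]
        out = within_sample_cluster([read] * 10 + noisy, ClusterParams(), "s")
        assert len(out) == 1
        assert out.loci[0].sequence == canonical(read)  # majority restores the truth


class TestConsensus:
    def test_identical_members(self):
        seq = random_genome(50, 0.5, 8)
        assert consensus([(seq, 4)], seq) == seq

    def test_majority_base(self):
        assert consensus([("AAAA", 3), ("AGAA", 1)], "AAAA") == "AAAA"

    def test_tie_breaks_to_lexicographically_smaller(self):
        assert consensus([("AAAA", 2), ("AGAA", 2)], "AAAA") == "AAAA"
        assert consensus([("TTTT", 2), ("TGTT", 2)], "TTTT") == "TGTT"


class TestClusterAcross:
    def test_locus_in_four_samples_retained_three_dropped(self):
        shared = random_genome(140, 0.5, 9)
        rare = random_genome(140, 0.5, 10)
        samples = [_sample(f"S{i}", [shared] if i == 3 else [shared, rare]) for i in range(4)]
        # 'rare' appears in 3 samples only
        clusters = cluster_across(samples, ClusterParams(min_samples=4))
        assert len(clusters) == 1
        assert set(clusters[0].members) == {"S0", "S1", "S2", "S3"}

    def test_partition_matches_single_linkage_oracle(self):
        for seed in range(10):
            seqs, threshold = clustering_instance(seed)
            expected = single_linkage_partition(seqs, threshold)
            # one locus per pseudo-sample so nothing is dropped or deduplicated
            samples = [_sample(f"S{i:02d}", [s]) for i, s in enumerate(seqs)]
            clusters = cluster_across(samples, ClusterParams(min_samples=2, identity_threshold=threshold))
            got = sorted(
                {int(s[1:]) for s in cl.members} for cl in clusters
            )
            expected_multi = sorted(g for g in expected if len(g) >= 2)
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected_multi))

    def test_paralog_deduplication_keeps_deepest(self):
        seq = random_genome(140, 0.5, 11)
        near = mutate(seq, 3, np.random.default_rng(12))
        dup = SampleLociSet(
            "S0", "simulated",
            [ConsensusLocus("S0_a", seq, 9), ConsensusLocus("S0_b", near, 2)],
        )
        others = [_sample(f"S{i}", [seq]) for i in range(1, 4)]
        (cluster,) = cluster_across([dup, *others], ClusterParams(min_samples=4))
        assert cluster.paralog_flagged
        assert cluster.members["S0"].locus_id == "S0_a"

    def test_alignment_rows_equal_length_and_variable_columns(self):
        seq = random_genome(140, 0.5, 13)
        variant = seq[:70] + ("A" if seq[70] != "A" else "C") + seq[71:]
        samples = [_sample(f"S{i}", [seq if i < 2 else variant]) for i in range(4)]
        (cluster,) = cluster_across(samples, ClusterParams(min_samples=4))
        lengths = {len(row) for row in cluster.alignment.values()}
        assert len(lengths) == 1
        assert cluster.variable_columns == [70]


class TestFilterSamples:
    def test_below_threshold_sample_removed_and_reclustered(self):
        common = [random_genome(140, 0.5, 20 + i) for i in range(3)]
        full = [_sample(f"S{i}", common) for i in range(4)]
        poor = _sample("S4", common[:1])
        params = ClusterParams(min_samples=2, min_loci_per_sample=2)
        retained, clusters = filter_samples([*full, poor], params)
        assert [s.sample_id for s in retained] == ["S0", "S1", "S2", "S3"]
        assert all("S4" not in cl.members for cl in clusters)

    def test_identity_when_all_pass(self):
        common = [random_genome(140, 0.5, 30 + i) for i in range(3)]
        samples = [_sample(f"S{i}", common) for i in range(4)]
        params = ClusterParams(min_samples=2, min_loci_per_sample=1)
        retained, _ = filter_samples(samples, params)
        assert retained == samples

    def test_all_removed_is_explicit_failure(self):
        samples = [_sample(f"S{i}", [random_genome(140, 0.5, 40 + i)]) for i in range(4)]
        with pytest.raises(ValueError, match="below min_loci_per_sample"):
            filter_samples(samples, ClusterParams(min_samples=2, min_loci_per_sample=100))


def _toy_clusters():
    rows_a = {f"S{i}": "ACGT" for i in range(4)}
    rows_b = {f"S{i}": "AAAA" if i else "AATA" for i in range(3)}
    return [
        LocusCluster("C0", {s: ConsensusLocus(f"{s}_0", r) for s, r in rows_a.items()}, rows_a, []),
        LocusCluster("C1", {s: ConsensusLocus(f"{s}_1", r) for s, r in rows_b.items()}, rows_b, [2]),
    ]


class TestSnpsAndStats:
    def test_one_column_per_cluster_and_determinism(self):
        clusters = _toy_clusters()
        samples = [f"S{i}" for i in range(4)]
        snps = extract_unlinked_snps(clusters, samples, seed=5)
        assert snps.shape == (4, 1)  # C0 has no variable column
        assert snps.site_ids == [("C1", 2)]
        assert list(snps.data[:, 0]) == ["T", "A", "A", "N"]  # S3 absent from C1
        again = extract_unlinked_snps(clusters, samples, seed=5)
        assert (again.data == snps.data).all()

    def test_every_emitted_column_is_variable(self):
        g = random_genome(60_000, 0.5, 50)
        tips = {f"S{i}": evolve_genome(g, 1.0, 0.01, 0, 60 + i) for i in range(4)}
        apeki = get_enzyme("ApeKI")
        samples = [
            simulate_rad_sample([("c", t)], apeki, SizeWindow(), SimReadParams(), sid)
            for sid, t in tips.items()
        ]
        clusters = cluster_across(samples, ClusterParams(min_samples=4))
        snps = extract_unlinked_snps(clusters, list(tips), seed=0)
        assert snps.shape[1] > 0
        for j in range(snps.shape[1]):
            col = snps.data[:, j]
            states = set(col) - {"N", "-"}
            assert len(states) >= 2

    def test_gap_fraction_direct_count(self):
        # 2 clusters of equal aligned length, 4 samples, one cluster missing
        # in one sample -> 1/8 of the concatenated cells are gaps
        rows_full = {f"S{i}": "ACGT" for i in range(4)}
        rows_part = {f"S{i}": "ACGT" for i in range(3)}
        clusters = [
            LocusCluster("C0", {s: ConsensusLocus(s + "a", r) for s, r in rows_full.items()}, rows_full, []),
            LocusCluster("C1", {s: ConsensusLocus(s + "b", r) for s, r in rows_part.items()}, rows_part, []),
        ]
        stats = dataset_stats(clusters)
        assert stats["gap_pct"] == pytest.approx(100 / 8)
        assert stats["alignment_positions"] == 8

    def test_totals_invariant_under_sample_order(self):
        clusters = _toy_clusters()
        counts = per_sample_locus_counts(clusters)
        assert counts == {"S0": 2, "S1": 2, "S2": 2, "S3": 1}


class TestEndToEndRecovery:
    def test_identical_genomes_recover_every_locus(self, apeki, small_genome):
        samples = [
            simulate_rad_sample([("c", small_genome)], apeki, sample_id=f"S{i}")
            for i in range(5)
        ]
        clusters = cluster_across(samples, ClusterParams(min_samples=4))
        assert len(clusters) == len(samples[0])
        assert all(cl.n_samples == 5 for cl in clusters)

    def test_divergence_decreases_shared_clusters(self, apeki):
        base_counts, div_counts = [], []
        for rep in range(3):
            g = random_genome(40_000, 0.5, 70 + rep)
            identical = [
                simulate_rad_sample([("c", g)], apeki, sample_id=f"S{i}") for i in range(4)
            ]
            diverged_genomes = [evolve_genome(g, 1.0, 0.03, 0, 80 + rep * 4 + i) for i in range(4)]
            diverged = [
                simulate_rad_sample([("c", t)], apeki, sample_id=f"S{i}")
                for i, t in enumerate(diverged_genomes)
            ]
            params = ClusterParams(min_samples=4)
            base_counts.append(len(cluster_across(identical, params)))
            div_counts.append(len(cluster_across(diverged, params)))
        # allele dropout + identity failures lose shared loci under divergence
        assert np.mean(div_counts) < np.mean(base_counts)
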