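"""Quality filtering and greedy ANI clustering of genome bins."""

from __future__ import annotations

import pytest

from fermbgc import (
    AniTable,
    MagRecord,
    cluster_genomes,
    filter_by_quality,
    flag_unknown_species,
    habitat_specific_clusters,
    quality_score,
)
from fermbgc.catalog import GenomeCluster

from conftest import small_config
from fermbgc import generate_community


def mag(mag_id, habitat="cheese", completeness=90.0, contamination=1.0):
    return MagRecord(mag_id=mag_id, habitat=habitat,
                     completeness=completeness, contamination=contamination)


class TestQualityFilter:
    def test_boundary_values_retained(self):
        kept = filter_by_quality([mag("A", completeness=50.0, contamination=10.0)])
        assert [m.mag_id for m in kept] == ["A"]

    def test_below_completeness_removed(self):
        assert filter_by_quality([mag("A", completeness=49.9, contamination=0.0)]) == []

    def test_enumerated_three_mag_case(self):
        mags = [
            mag("A", completeness=40, contamination=5),
            mag("B", completeness=60, contamination=12),
            mag("C", completeness=90, contamination=5),
        ]
        kept = filter_by_quality(mags)
        assert [m.mag_id for m in kept] == ["C"]

    def test_order_preserved(self):
        mags = [mag(i) for i in "DCBA"]
        assert [m.mag_id for m in filter_by_quality(mags)] == list("DCBA")


@pytest.mark.parametrize(
    "completeness,contamination,expected",
    [(100, 0, 100.0), (80, 4, 60.0), (50, 10, 0.0)],
)
def test_quality_score(completeness, contamination, expected):
    assert quality_score(mag("A", completeness=completeness, contamination=contamination)) == expected


def _table(pairs):
    t = AniTable()
    for a, b, ani, *ov in pairs:
        overlap = ov[0] if ov else 1.0
        t.add(a, b, ani, overlap)
        t.add(b, a, ani, overlap)
    return t


class TestGreedyClustering:
    def test_greedy_is_not_transitive_closure(self):
        # A-B and B-C above threshold but A-C below: the best-quality MAG A
        # seeds {A, B}; C starts its own cluster
        mags = [
            mag("A", completeness=99),
            mag("B", completeness=95),
            mag("C", completeness=90),
        ]
        ani = _table([("A", "B", 99.5), ("B", "C", 99.5), ("A", "C", 98.0)])
        clusters = cluster_genomes(mags, ani, ani_threshold=99.0)
        parts = {frozenset(c.member_mag_ids) for c in clusters}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_all_pairs_above_species_threshold_single_cluster(self):
        mags = [mag(i) for i in "ABC"]
        ani = _table([("A", "B", 96.0), ("B", "C", 97.0), ("A", "C", 95.0)])
        clusters = cluster_genomes(mags, ani, ani_threshold=95.0, level="species")
        assert len(clusters) == 1

    def test_low_overlap_pair_not_merged(self):
        mags = [mag("A"), mag("B")]
        ani = _table([("A", "B", 99.5, 0.10)])
        clusters = cluster_genomes(mags, ani, ani_threshold=99.0)
        assert len(clusters) == 2

    def test_representative_is_highest_quality(self):
        mags = [mag("A", completeness=80), mag("B", completeness=99)]
        ani = _table([("A", "B", 99.5)])
        (c,) = cluster_genomes(mags, ani, ani_threshold=99.0)
        assert c.representative_mag_id == "B"

    def test_quality_tie_broken_by_smallest_id(self):
        mags = [mag("B"), mag("A")]
        ani = _table([("A", "B", 99.5)])
        (c,) = cluster_genomes(mags, ani, ani_threshold=99.0)
        assert c.representative_mag_id == "A"

    def test_duplicate_mag_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cluster_genomes([mag("A"), mag("A")], AniTable(), 99.0)

    def test_unknown_ids_in_ani_table_ignored_with_warning(self, caplog):
        mags = [mag("A")]
        ani = _table([("A", "GHOST", 99.9)])
        with caplog.at_level("WARNING"):
            clusters = cluster_genomes(mags, ani, 99.0)
        assert len(clusters) == 1
        assert any("ignored" in r.message for r in caplog.records)

    def test_asymmetric_directed_entries_symmetrized(self):
        t = AniTable()
        t.add("A", "B", 99.0, 0.9)
        t.add("B", "A", 99.8, 0.3)
        ani, overlap = t.get("A", "B")
        assert ani == pytest.approx(99.4)
        assert overlap == 0.3  # conservative minimum

    def test_absent_pair_means_below_threshold(self):
        mags = [mag("A"), mag("B")]
        clusters = cluster_genomes(mags, AniTable(), 99.0)
        assert len(clusters) == 2


class TestClusterProperties:
    def test_clusters_partition_the_mag_set(self, zero_noise_bundle):
        from fermbgc import run_bundle

        res = run_bundle(zero_noise_bundle)
        for clusters in (res.genotype_clusters, res.species_clusters):
            members = [m for c in clusters for m in c.member_mag_ids]
            assert sorted(members) == sorted(m.mag_id for m in res.mags_retained)

    def test_genotypes_refine_species_at_zero_noise(self, zero_noise_bundle):
        from fermbgc import run_bundle

        res = run_bundle(zero_noise_bundle)
        species_of = {m: c.cluster_id for c in res.species_clusters for m in c.member_mag_ids}
        for gc in res.genotype_clusters:
            assert len({species_of[m] for m in gc.member_mag_ids}) == 1

    def test_lowering_threshold_never_increases_cluster_count(self, zero_noise_bundle):
        bundle = zero_noise_bundle
        counts = [
            len(cluster_genomes(bundle.mags, bundle.ani, thr))
            for thr in (99.5, 99.0, 97.0, 95.0, 90.0, 80.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_greedy_equals_single_linkage_closure_on_separated_ani(self):
        # when ANI ranges are separated from the threshold, chaining cannot
        # occur and greedy clustering equals the transitive closure
        for seed in range(5):
            bundle = generate_community(small_config(seed=seed))
            assert len(bundle.mags) <= 50
            for thr in (99.0, 95.0):
                clusters = cluster_genomes(bundle.mags, bundle.ani, thr)
                got = {frozenset(c.member_mag_ids) for c in clusters}
                assert got == _closure_oracle(bundle.mags, bundle.ani, thr)


def _closure_oracle(mags, ani, threshold, min_overlap=0.25):
    """Brute-force single-linkage transitive closure via union-find."""
    ids = [m.mag_id for m in mags]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pair = ani.get(a, b)
            if pair and pair[0] >= threshold and pair[1] >= min_overlap:
                parent[find(a)] = find(b)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in groups.values()}


def _cluster(cid, members, habitats, level="species"):
    return GenomeCluster(
        cluster_id=cid, level=level, representative_mag_id=members[0],
        member_mag_ids=tuple(members), habitat_set=frozenset(habitats),
    )


class TestHabitatPartition:
    def test_single_habitat_cluster_is_specific(self):
        part = habitat_specific_clusters([_cluster("c0", ["A"], {"cheese"})])
        assert part.habitat_specific and not part.multi_habitat

    def test_two_habitat_cluster_is_multi(self):
        part = habitat_specific_clusters([_cluster("c0", ["A", "B"], {"cheese", "nunu"})])
        assert part.multi_habitat and not part.habitat_specific

    def test_ratio_is_two_decimal_percentage(self):
        # 245 specific of 297 -> 82.49%
        clusters = [
            _cluster(f"s{i}", [f"M{i}"], {"cheese"}) for i in range(245)
        ] + [
            _cluster(f"m{i}", [f"N{i}"], {"cheese", "nunu"}) for i in range(52)
        ]
        part = habitat_specific_clusters(clusters)
        assert part.ratio_percent == 82.49
        assert part.per_habitat_counts == {"cheese": 245}


class TestUnknownSpecies:
    def test_member_matching_reference_marks_cluster_known(self):
        ref = AniTable()
        ref.add("A", "ref1", 96.2)
        (c,) = flag_unknown_species([_cluster("c0", ["A"], {"cheese"})], ref)
        assert c.is_unknown is False

    def test_best_hit_below_threshold_is_unknown(self):
        ref = AniTable()
        ref.add("A", "ref1", 94.9)
        (c,) = flag_unknown_species([_cluster("c0", ["A"], {"cheese"})], ref)
        assert c.is_unknown is True

    def test_empty_reference_table_flags_everything_unknown(self, caplog):
        with caplog.at_level("WARNING"):
            out = flag_unknown_species(
                [_cluster("c0", ["A"], {"cheese"}), _cluster("c1", ["B"], {"nunu"})], None
            )
        assert all(c.is_unknown for c in out)
        assert any("unknown" in r.message for r in caplog.records)
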