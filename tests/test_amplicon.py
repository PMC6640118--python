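"""Read simulation, read joining and mock-community sampling."""

import numpy as np
import pytest

from amplipair.amplicon import (
    JOINT_N,
    Fragment,
    ReadPair,
    build_env_community,
    build_gene_pool,
    extract_region,
    join_read_pair,
    make_fragment,
    parse_target,
    revcomp,
    sample_mock_dataset,
    simulate_read_pair,
)


def first_record(db):
    return next(iter(db))


class TestExtractRegion:
    def test_coordinates(self, db, region_map):
        rec = first_record(db)
        start, end = region_map[rec.id]["V4"]
        sub = extract_region(rec, region_map, "V4")
        assert sub == rec.sequence[start:end]
        assert rec.sequence.find(sub) == rec.sequence.index(sub)

    def test_unknown_label(self, db, region_map):
        with pytest.raises(KeyError, match="V10"):
            extract_region(first_record(db), region_map, "V10")


class TestParseTarget:
    def test_valid(self):
        assert parse_target("V1+V4") == ("V1", "V4")

    @pytest.mark.parametrize("bad", ["V4+V1", "V1+V1", "V1", "C1+V4", "V0+V4"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            parse_target(bad)


class TestSimulateReadPair:
    def test_anchors_at_conserved_boundaries(self, db, region_map):
        rec = first_record(db)
        regions = region_map[rec.id]
        pair = simulate_read_pair(rec, region_map, ("V1", "V4"), read_len=250)
        c1_start = regions["C1"][0]
        c5_end = regions["C5"][1]
        assert pair.fwd == rec.sequence[c1_start : c1_start + 250]
        assert pair.rev == revcomp(rec.sequence[c5_end - 250 : c5_end])
        assert pair.fwd_covers_target and pair.rev_covers_target

    def test_adjacent_windows_overlap_by_interval_arithmetic(
        self, db, region_map, template
    ):
        # oracle: overlap = 2*read_len - span(C3-start .. C5-end), computed
        # from the record's own coordinates
        rec = first_record(db)
        regions = region_map[rec.id]
        span = regions["C5"][1] - regions["C3"][0]
        expected_overlap = 2 * 250 - span
        assert expected_overlap > 0
        pair = simulate_read_pair(rec, region_map, ("V3", "V4"), read_len=250)
        frag = join_read_pair(pair)
        assert frag.mode == "merged"
        assert len(frag.sequence) == span

    def test_read_longer_than_gene_truncates(self, db, region_map):
        rec = first_record(db)
        pair = simulate_read_pair(rec, region_map, ("V1", "V9"), read_len=10_000)
        assert pair.fwd == rec.sequence[region_map[rec.id]["C1"][0] :]
        assert len(pair.rev) <= len(rec.sequence)
        assert pair.fwd_covers_target and pair.rev_covers_target

    def test_identical_targets_rejected(self, db, region_map):
        with pytest.raises(ValueError):
            simulate_read_pair(first_record(db), region_map, ("V4", "V4"))


class TestJoinReadPair:
    def _pair(self, fwd, rev_plus, target=("V1", "V2")):
        return ReadPair(fwd, revcomp(rev_plus), target, "r", max(len(fwd), len(rev_plus)), True, True)

    def test_hand_aligned_overlap(self):
        # fwd suffix CGTAA == rev prefix CGTAA (5 bp overlap)
        frag = join_read_pair(self._pair("ACGTACGTAA", "CGTAATTTTT"), min_overlap=5)
        assert frag.mode == "merged"
        assert frag.sequence == "ACGTACGTAATTTTT"
        assert len(frag.sequence) == 15

    def test_disjoint_reads_concatenated(self):
        fwd = "AC" * 125
        rev_plus = "GT" * 125
        frag = join_read_pair(self._pair(fwd, rev_plus), min_overlap=10)
        assert frag.mode == "concatenated"
        assert len(frag.sequence) == 508
        assert frag.sequence.count("N") == JOINT_N
        assert "N" * JOINT_N in frag.sequence
        assert "N" * (JOINT_N + 1) not in frag.sequence

    def test_full_overlap_is_idempotent(self):
        frag = join_read_pair(self._pair("ACGTACGTGA", "ACGTACGTGA"), min_overlap=5)
        assert frag.mode == "merged"
        assert frag.sequence == "ACGTACGTGA"

    def test_merged_length_bound(self, db, region_map):
        for rec in list(db)[:10]:
            pair = simulate_read_pair(rec, region_map, ("V3", "V4"))
            frag = join_read_pair(pair, min_overlap=10)
            assert len(frag.sequence) <= len(pair.fwd) + len(pair.rev) - 10

    def test_adjacent_merge_distant_concatenate(self, db, region_map):
        for rec in list(db)[:10]:
            adjacent = make_fragment(rec, region_map, ("V3", "V4"))
            distant = make_fragment(rec, region_map, ("V1", "V8"))
            assert adjacent.mode == "merged"
            assert distant.mode == "concatenated"

    def test_concatenated_flanks_are_substrings_of_origin(self, db, region_map):
        for rec in list(db)[:10]:
            frag = make_fragment(rec, region_map, ("V1", "V8"))
            left, right = frag.sequence.split("N" * JOINT_N)
            assert left in rec.sequence
            assert right in rec.sequence  # already plus-strand after joining


class TestCommunities:
    def test_too_few_taxa_rejected(self, db):
        with pytest.raises(ValueError, match="50"):
            build_gene_pool(db, n_taxa=50, rank="genus", seed=0)

    def test_pool_includes_all_when_exact(self, db):
        community = build_gene_pool(db, n_taxa=10, rank="genus", seed=0)
        assert community.taxa == db.taxa_at("genus")
        assert abs(sum(community.proportions.values()) - 1.0) < 1e-9

    def test_pool_deterministic_under_seed(self, db):
        a = build_gene_pool(db, n_taxa=6, rank="genus", seed=5)
        b = build_gene_pool(db, n_taxa=6, rank="genus", seed=5)
        assert a.taxa == b.taxa
        assert a.proportions == b.proportions

    def test_env_community_normalizes(self, db):
        genera = db.taxa_at("genus")[:2]
        community = build_env_community(db, {genera[0]: 2, genera[1]: 6})
        assert community.proportions[genera[0]] == pytest.approx(0.25)
        assert community.proportions[genera[1]] == pytest.approx(0.75)

    def test_env_community_missing_taxon(self, db):
        with pytest.raises(ValueError, match="G999"):
            build_env_community(db, {"G999": 1.0})


class TestSampleMockDataset:
    def test_exact_size_and_valid_ids(self, db):
        community = build_gene_pool(db, n_taxa=5, rank="genus", seed=1)
        dataset = sample_mock_dataset(community, db, n_reads=10_000, seed=2)
        assert len(dataset) == 10_000
        pool_ids = {i for ids in community.pools.values() for i in ids}
        assert set(dataset.record_ids) <= pool_ids

    def test_single_taxon_community(self, db):
        genus = db.taxa_at("genus")[0]
        community = build_env_community(db, {genus: 1.0})
        dataset = sample_mock_dataset(community, db, n_reads=50, seed=0)
        assert set(dataset.truth_at("genus")) == {genus}

    def test_sampling_tracks_proportions(self, db):
        # binomial oracle: n=10,000, p=0.9 -> count within a >6 sigma band
        genera = db.taxa_at("genus")[:2]
        community = build_env_community(db, {genera[0]: 9, genera[1]: 1})
        dataset = sample_mock_dataset(community, db, n_reads=10_000, seed=3)
        count = dataset.truth_at("genus").count(genera[0])
        assert 8700 <= count <= 9300

    def test_deterministic_under_seed(self, db):
        community = build_gene_pool(db, n_taxa=5, rank="genus", seed=1)
        a = sample_mock_dataset(community, db, n_reads=100, seed=9)
        b = sample_mock_dataset(community, db, n_reads=100, seed=9)
        assert a.record_ids == b.record_ids
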