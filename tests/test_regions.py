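import numpy as np
import pandas as pd
import pytest

from nrlkit import (
    AnchorSet,
    DyadTrack,
    EstimationError,
    ParseError,
    RegionSet,
    ValidationError,
    anchored_profile,
    compute_phasogram,
    estimate_nrl_from_track,
    load_anchors,
    load_regions,
    nrl_by_region,
    nrl_from_profile,
    stratified_phasogram,
)


def _regions(rows):
    return RegionSet.from_dataframe(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )


class TestRegionLoading:
    def test_overlapping_intervals_merged_within_label(self):
        rs = _regions([("chr1", 100, 200, "Active"), ("chr1", 150, 300, "Active")])
        assert rs.intervals["Active"][["start", "end"]].values.tolist() == [[100, 300]]

    def test_bookended_intervals_stay_distinct(self):
        rs = _regions([("chr1", 0, 500, "A"), ("chr1", 500, 1000, "A")])
        assert len(rs.intervals["A"]) == 2

    def test_two_labels_two_strata(self):
        rs = _regions([("chr1", 0, 100, "Active"), ("chr1", 200, 300, "Heterochromatin")])
        assert sorted(rs.labels()) == ["Active", "Heterochromatin"]

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("")
        with pytest.raises(ValidationError, match="no regions"):
            load_regions(p)

    def test_missing_label_column_is_error(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t100\n")
        with pytest.raises(ParseError, match="label"):
            load_regions(p)


class TestStratifiedPhasogram:
    def test_containment_enumeration(self):
        track = DyadTrack.from_positions({"chr1": [100, 290, 480, 5000, 5190]})
        rs = _regions([("chr1", 0, 1000, "A")])
        hist = stratified_phasogram(track, rs, "A", 1, 1000)
        assert hist.value_at(190) == 2
        assert hist.value_at(380) == 1
        assert hist.counts.sum() == 3  # the dyads at 5000/5190 are outside

    def test_pairs_across_adjacent_intervals_not_counted(self):
        track = DyadTrack.from_positions({"chr1": [480, 520]})
        rs = _regions([("chr1", 0, 500, "A"), ("chr1", 500, 1000, "A")])
        assert stratified_phasogram(track, rs, "A", 1, 1000).counts.sum() == 0

    def test_unknown_label_rejected(self):
        track = DyadTrack.from_positions({"chr1": [1, 2]})
        with pytest.raises(ValidationError, match="unknown label"):
            stratified_phasogram(track, _regions([("chr1", 0, 10, "A")]), "B")

    def test_partition_histograms_nested_in_unstratified(self):
        rng = np.random.default_rng(12)
        track = DyadTrack.from_positions({"chr1": np.sort(rng.integers(0, 10_000, 400))})
        rs = _regions(
            [("chr1", 0, 2_500, "a"), ("chr1", 2_500, 6_000, "b"), ("chr1", 6_000, 10_000, "c")]
        )
        whole = compute_phasogram(track, 1, 800)
        summed = sum(
            stratified_phasogram(track, rs, lab, 1, 800).counts for lab in "abc"
        )
        # every stratified pair is also a whole-genome pair; boundary pairs are lost
        assert np.all(summed <= whole.counts)
        assert summed.sum() < whole.counts.sum()

    def test_whole_genome_single_label_equals_unstratified(self):
        rng = np.random.default_rng(3)
        track = DyadTrack.from_positions({"chr1": np.sort(rng.integers(0, 50_000, 500))})
        rs = _regions([("chr1", 0, 50_000, "all")])
        np.testing.assert_array_equal(
            stratified_phasogram(track, rs, "all", 1, 800).counts,
            compute_phasogram(track, 1, 800).counts,
        )


class TestNrlByRegion:
    def test_two_state_recovery_with_correct_ordering(self, two_state_sim):
        rs = RegionSet.from_dataframe(two_state_sim["regions"])
        table = nrl_by_region(two_state_sim["dyads"], rs).set_index("label")
        active, repressed = table.loc["Active"], table.loc["Repressed"]
        assert abs(active["nrl"] - 180) <= 1.5
        assert abs(repressed["nrl"] - 195) <= 1.5
        assert active["nrl"] < repressed["nrl"]
        # separation exceeds joint regression uncertainty
        assert active["nrl"] + 2 * active["stderr"] < repressed["nrl"] - 2 * repressed["stderr"]

    def test_label_without_dyads_reported_not_dropped(self, two_state_sim):
        regions = pd.concat(
            [
                two_state_sim["regions"],
                pd.DataFrame({"chrom": ["chrM"], "start": [0], "end": [1000], "label": ["empty"]}),
            ],
            ignore_index=True,
        )
        table = nrl_by_region(two_state_sim["dyads"], RegionSet.from_dataframe(regions))
        row = table.set_index("label").loc["empty"]
        assert row["n_dyads"] == 0
        assert row["status"] != "ok"
        assert np.isnan(row["nrl"])

    def test_whole_genome_label_matches_unstratified_estimate(self, two_state_sim):
        rs = _regions([("chr1", 0, 6_000_000, "genome")])
        table = nrl_by_region(two_state_sim["dyads"], rs).set_index("label")
        est, _, _ = estimate_nrl_from_track(two_state_sim["dyads"])
        assert table.loc["genome", "nrl"] == pytest.approx(est.nrl)


def _phased_track(anchor_positions, nrl=190, n_nuc=10):
    dyads = np.sort(
        np.concatenate([p + 73 + nrl * np.arange(n_nuc) for p in anchor_positions])
    )
    return DyadTrack.from_positions({"chr1": dyads})


class TestAnchoredProfile:
    def test_deterministic_lattice_slope(self):
        anchors_pos = np.arange(0, 500_000, 5_000)
        track = _phased_track(anchors_pos)
        anchors = AnchorSet(
            pd.DataFrame({"chrom": "chr1", "position": anchors_pos, "strand": "+"})
        )
        profile = anchored_profile(track, anchors)
        est, summits = nrl_from_profile(profile)
        np.testing.assert_allclose(summits.positions[:3], [73, 263, 453], atol=1.0)
        assert est.nrl == pytest.approx(190.0, abs=0.2)
        assert est.method == "anchored_profile"

    def test_minus_strand_anchor_mirrors_offset(self):
        track = DyadTrack.from_positions({"chr1": [927]})
        anchors = AnchorSet(pd.DataFrame({"chrom": ["chr1"], "position": [1000], "strand": ["-"]}))
        profile = anchored_profile(track, anchors, flank=100)
        assert profile[100 + 73] == 1  # dyad at p-73 becomes oriented offset +73

    def test_flipping_all_strands_reverses_profile(self):
        rng = np.random.default_rng(5)
        track = DyadTrack.from_positions({"chr1": np.sort(rng.integers(0, 100_000, 2_000))})
        anchors = AnchorSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "position": rng.integers(2_000, 98_000, 300),
                    "strand": rng.choice(["+", "-"], 300),
                }
            )
        )
        fwd = anchored_profile(track, anchors, flank=500)
        rev = anchored_profile(track, anchors.flipped(), flank=500)
        np.testing.assert_array_equal(rev, fwd[::-1])

    def test_jittered_boundary_phased_arrays_recover_nrl(self):
        from nrlkit import GenomeLayout, SimConfig, compute_dyads, filter_by_length, simulate

        cfg = SimConfig(
            genome=GenomeLayout({"chr1": 10_000_000}),
            true_nrl=190,
            n_fragments=400_000,
            seed=9,
            multi_frac=0.0,
            jitter_sd=10.0,
            boundary_rate=1 / 20_000,
        )
        frags, _, truth = simulate(cfg)
        track = compute_dyads(filter_by_length(frags, 100, 200))
        anchors = AnchorSet(
            pd.DataFrame(
                {"chrom": "chr1", "position": truth.boundaries["chr1"], "strand": "+"}
            )
        )
        est, _ = nrl_from_profile(anchored_profile(track, anchors))
        assert abs(est.nrl - 190) <= 2.0

    def test_unphased_anchors_raise_no_significant_periodicity(self, reference_sim):
        rng = np.random.default_rng(8)
        anchors = AnchorSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "position": np.sort(rng.integers(10_000, 4_990_000, 800)),
                    "strand": "+",
                }
            )
        )
        profile = anchored_profile(reference_sim["dyads"], anchors)
        with pytest.raises(EstimationError, match="periodicity"):
            nrl_from_profile(profile)

    def test_few_anchors_logged(self, caplog):
        track = _phased_track([10_000])
        anchors = AnchorSet(pd.DataFrame({"chrom": ["chr1"], "position": [10_000], "strand": ["+"]}))
        with caplog.at_level("WARNING", logger="nrlkit"):
            anchored_profile(track, anchors)
        assert "anchors" in caplog.text

    def test_bed6_anchor_point_is_five_prime_end(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tx\t0\t+\nchr1\t300\t400\ty\t0\t-\n")
        anchors = load_anchors(p)
        assert anchors.anchors["position"].tolist() == [100, 399]

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValidationError):
            AnchorSet(pd.DataFrame({"chrom": ["c"], "position": [1], "strand": ["."]}))
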