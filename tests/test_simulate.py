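import numpy as np
import pandas as pd
import pytest

from nrlkit import (
    ConfigError,
    GenomeLayout,
    SimConfig,
    StateInterval,
    StateMap,
    fragment_lengths,
    simulate,
    simulate_dyad_positions,
    simulate_fragments,
    simulate_state_mixture,
    write_fragments,
)


def _cfg(**kw):
    defaults = dict(
        genome=GenomeLayout({"chr1": 200_000}),
        true_nrl=190,
        n_fragments=5_000,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDyadPlacement:
    def test_zero_jitter_deterministic_lattice(self):
        cfg = _cfg(jitter_sd=0.0, boundary_rate=0.0)
        track, truth = simulate_dyad_positions(cfg)
        pos = track.positions["chr1"]
        # one array anchored at the chromosome start: 73, 263, 453, ...
        assert pos[:3].tolist() == [73, 263, 453]
        assert np.all(np.diff(pos) == 190)

    def test_same_seed_identical_tracks(self):
        t1, _ = simulate_dyad_positions(_cfg())
        t2, _ = simulate_dyad_positions(_cfg())
        assert t1 == t2

    def test_mean_within_array_spacing_matches_truth(self):
        # small jitter keeps steric-clash losses negligible, so the
        # sample mean of within-array spacings estimates the true NRL
        cfg = _cfg(genome=GenomeLayout({"chr1": 4_000_000}), jitter_sd=5.0)
        _, truth = simulate_dyad_positions(cfg)
        sp = truth.nearest_neighbour_spacings().astype(float)
        assert sp.size > 10_000
        sem = sp.std(ddof=1) / np.sqrt(sp.size)
        assert abs(sp.mean() - cfg.true_nrl) <= 3 * sem

    def test_min_spacing_respects_footprint(self):
        cfg = _cfg(jitter_sd=40.0)
        _, truth = simulate_dyad_positions(cfg)
        assert truth.nearest_neighbour_spacings().min() >= cfg.footprint

    def test_mean_spacing_monotone_in_true_nrl(self):
        # moderate jitter: steric exclusion censors few spacings, so the
        # kept-dyad spacing tracks the configured repeat length
        means = []
        for nrl in (167, 185, 200, 212):
            _, truth = simulate_dyad_positions(
                _cfg(genome=GenomeLayout({"chr1": 2_000_000}), true_nrl=nrl, jitter_sd=5.0)
            )
            means.append(truth.nearest_neighbour_spacings().mean())
        assert np.all(np.diff(means) > 0)

    def test_nrl_not_exceeding_footprint_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(true_nrl=147)

    @pytest.mark.parametrize(
        "kw", [{"multi_frac": 1.0}, {"multi_decay": 0.0}, {"jitter_sd": -1.0}, {"seed": None}]
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            _cfg(**kw)


class TestFragmentEmission:
    def test_fragment_count_conserved(self):
        frags, _, _ = simulate(_cfg(n_fragments=1234))
        assert len(frags) == 1234

    def test_mono_only_lengths_unimodal_near_mean(self):
        cfg = _cfg(multi_frac=0.0, n_fragments=20_000)
        frags, _, _ = simulate(cfg)
        lengths = fragment_lengths(frags)
        assert lengths.min() >= int(np.ceil(0.8 * cfg.footprint))
        assert abs(np.median(lengths) - cfg.frag_len_mean) <= 2
        # unimodal: the central window holds the bulk of the mass
        central = np.mean(np.abs(lengths - cfg.frag_len_mean) <= 3 * cfg.frag_len_sd)
        assert central > 0.99

    def test_zero_jitter_multi_lengths_on_ladder(self):
        # a k-nucleosome fragment runs from 73 bp before the first dyad to
        # 74 bp after the last: length = (k-1)*NRL + 147, e.g. 337 for k=2
        cfg = _cfg(jitter_sd=0.0, boundary_rate=0.0, multi_frac=0.8, n_fragments=20_000)
        frags, _, _ = simulate(cfg)
        lengths = np.unique(fragment_lengths(frags))
        multi = lengths[lengths > 250]
        assert multi.size > 0
        assert np.all((multi - 147) % 190 == 0)
        assert 337 in multi

    def test_multi_span_truncated_at_chromosome_end(self, caplog):
        cfg = _cfg(
            genome=GenomeLayout({"chr1": 2_000}),
            multi_frac=0.9,
            multi_decay=0.1,
            n_fragments=2_000,
            jitter_sd=0.0,
            boundary_rate=0.0,
        )
        frags, _, _ = simulate(cfg)
        assert frags["end"].max() <= 2_000
        assert frags["start"].min() >= 0

    def test_fixed_seed_byte_identical_bed(self, tmp_path):
        paths = []
        for name in ("a.bed", "b.bed"):
            frags, _, _ = simulate(_cfg())
            p = tmp_path / name
            write_fragments(frags, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_empty_track_with_fragments_requested_is_error(self):
        cfg = _cfg(genome=GenomeLayout({"chr1": 100}), n_fragments=10)
        track, _ = simulate_dyad_positions(cfg)
        assert track.n == 0
        with pytest.raises(ConfigError):
            simulate_fragments(track, cfg)


class TestStateMixture:
    def test_zero_jitter_per_label_exact_spacing(self):
        sm = StateMap(
            [
                StateInterval("chr1", 0, 200_000, "A", 180),
                StateInterval("chr1", 200_000, 400_000, "B", 195),
            ]
        )
        base = _cfg(genome=GenomeLayout({"chr1": 400_000}), jitter_sd=0.0, boundary_rate=0.0, n_fragments=1000)
        _, _, _, truth = simulate_state_mixture(sm, base)
        pos = truth.dyads.positions["chr1"]
        a, b = pos[pos < 200_000], pos[pos >= 200_000]
        assert np.all(np.diff(a) == 180)
        assert np.all(np.diff(b) == 195)

    def test_overlapping_intervals_across_labels_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            StateMap(
                [
                    StateInterval("chr1", 0, 1000, "A", 180),
                    StateInterval("chr1", 500, 1500, "B", 195),
                ]
            )

    def test_single_label_degenerates_to_plain_simulation(self):
        # deterministic lattice: a one-label map over a whole chromosome
        # places exactly the dyads of the plain generator
        base = _cfg(genome=GenomeLayout({"chr1": 300_000}), jitter_sd=0.0, boundary_rate=0.0)
        sm = StateMap([StateInterval("chr1", 0, 300_000, "only", base.true_nrl)])
        _, regions, table, truth = simulate_state_mixture(sm, base)
        plain, _ = simulate_dyad_positions(base)
        assert truth.dyads == plain
        assert table.iloc[0]["true_nrl"] == base.true_nrl
        assert regions["label"].tolist() == ["only"]

    def test_mixture_deterministic_under_seed(self, two_state_sim):
        frags2, _, _, _ = simulate_state_mixture(
            two_state_sim["state_map"],
            SimConfig(
                genome=GenomeLayout({"chr1": 6_000_000}),
                true_nrl=190,
                n_fragments=100_000,
                seed=3,
                multi_frac=0.0,
            ),
        )
        pd.testing.assert_frame_equal(frags2, two_state_sim["fragments"])
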