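"""Synthetic nucleosome landscapes with known ground-truth repeat length.

The generator builds phased nucleosome arrays: array boundaries are drawn
as a Poisson process (plus one boundary at each chromosome start), and
from each boundary nucleosome dyads are laid down at
``boundary + floor(footprint/2) + i * true_nrl`` with independent
Gaussian positional jitter per nucleosome (no cumulative drift — a
simplification relative to true statistical positioning, sufficient for
validating spacing estimators). Dyads that land closer than one footprint
to the previously kept dyad (steric clash after jitter) are discarded.

A digestion model then emits sequencing-like fragments: mononucleosome
fragments centred on a dyad with Gaussian length, and — with probability
``multi_frac`` — multi-nucleosome fragments spanning k >= 2 consecutive
dyads (k geometric), emulating partial digestion. Per-chromosome and
per-interval random streams are derived from the single seed, so
generation is deterministic and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fragments import DyadTrack, GenomeLayout

logger = logging.getLogger("nrlkit")

# stream-name constants keeping chromosome / fragment / interval draws independent
_FRAG_STREAM = 1_000_003
_STATE_STREAM = 2_000_003


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated nucleosome landscape.

    Defaults reflect a typical well-digested mammalian MNase-seq
    experiment: ~147 bp core footprint, mononucleosome fragments of
    167 +/- 15 bp, ~30% multi-nucleosome fragments with geometrically
    decaying multiplicity, and array-resetting boundaries every ~50 kb.
    """

    genome: GenomeLayout
    true_nrl: int
    n_fragments: int
    seed: int
    footprint: int = 147
    jitter_sd: float = 20.0
    boundary_rate: float = 1.0 / 50_000
    frag_len_mean: float = 167.0
    frag_len_sd: float = 15.0
    multi_frac: float = 0.3
    multi_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ConfigError(f"footprint must be >= 1, got {self.footprint}")
        if self.true_nrl <= self.footprint:
            raise ConfigError(
                f"true_nrl ({self.true_nrl}) must exceed footprint ({self.footprint})"
            )
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if not (0 <= self.multi_frac < 1):
            raise ConfigError("multi_frac must be in [0, 1)")
        if not (0 < self.multi_decay <= 1):
            raise ConfigError("multi_decay must be in (0, 1]")
        if self.boundary_rate < 0:
            raise ConfigError("boundary_rate must be >= 0")
        if self.n_fragments < 0:
            raise ConfigError("n_fragments must be >= 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class SimGroundTruth:
    """What the generator actually placed: dyads, boundaries, array ids."""

    dyads: DyadTrack
    boundaries: dict[str, np.ndarray]
    array_ids: dict[str, np.ndarray]  # parallel to dyads: which array each dyad belongs to
    config: SimConfig

    def nearest_neighbour_spacings(self) -> np.ndarray:
        """Within-array spacings between consecutive kept dyads (bp)."""
        gaps = []
        for chrom, pos in self.dyads.positions.items():
            if pos.size < 2:
                continue
            arr = self.array_ids[chrom]
            same = arr[1:] == arr[:-1]
            gaps.append(np.diff(pos)[same])
        if not gaps:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(gaps)


def _draw_boundaries(rng: np.random.Generator, length: int, rate: float) -> np.ndarray:
    """Poisson-process boundary positions in [0, length), always including 0."""
    positions = [0]
    if rate > 0:
        pos = 0.0
        while True:
            pos += rng.exponential(1.0 / rate)
            if pos >= length:
                break
            positions.append(int(pos))
    return np.unique(np.asarray(positions, dtype=np.int64))


def simulate_dyad_positions(config: SimConfig) -> tuple[DyadTrack, SimGroundTruth]:
    """Place jittered, sterically non-overlapping dyads on every chromosome."""
    half = config.footprint // 2
    rest = config.footprint - half
    tracks: dict[str, np.ndarray] = {}
    all_bounds: dict[str, np.ndarray] = {}
    all_arrays: dict[str, np.ndarray] = {}
    for chrom_idx, (chrom, length) in enumerate(config.genome.items()):
        rng = np.random.default_rng([config.seed, chrom_idx])
        bounds = _draw_boundaries(rng, length, config.boundary_rate)
        seg_ends = np.append(bounds[1:], length)
        kept_pos: list[int] = []
        kept_arr: list[int] = []
        for seg_id, (b, b_end) in enumerate(zip(bounds, seg_ends)):
            n_slots = (b_end - rest - (b + half)) // config.true_nrl + 1
            if n_slots <= 0:
                continue
            ideal = b + half + config.true_nrl * np.arange(n_slots)
            if config.jitter_sd > 0:
                pos = np.rint(ideal + rng.normal(0.0, config.jitter_sd, n_slots)).astype(np.int64)
                np.clip(pos, b + half, b_end - rest, out=pos)
            else:
                pos = ideal.astype(np.int64)
            prev = None
            for p in pos:
                if prev is not None and p - prev < config.footprint:
                    continue  # steric clash: discard the later nucleosome
                kept_pos.append(int(p))
                kept_arr.append(seg_id)
                prev = int(p)
        pos_arr = np.asarray(kept_pos, dtype=np.int64)
        arr_arr = np.asarray(kept_arr, dtype=np.int64)
        order = np.argsort(pos_arr, kind="stable")
        tracks[chrom] = pos_arr[order]
        all_arrays[chrom] = arr_arr[order]
        all_bounds[chrom] = bounds
    track = DyadTrack(tracks)
    truth = SimGroundTruth(track, all_bounds, all_arrays, config)
    return track, truth


def simulate_fragments(dyads: DyadTrack, config: SimConfig) -> pd.DataFrame:
    """Emit sequencing-like fragments from a dyad track.

    Mononucleosome fragments (probability 1 - multi_frac) are centred on a
    uniformly chosen dyad with length ~ N(frag_len_mean, frag_len_sd)
    clipped to >= 0.8 * footprint. Multi-nucleosome fragments span
    k >= 2 consecutive dyads (k - 1 geometric with parameter multi_decay)
    from floor(footprint/2) before the first dyad to the remaining
    footprint after the last; k is truncated (and the truncation logged)
    when fewer dyads remain on the chromosome. Fragments are clipped to
    chromosome bounds. Exactly ``config.n_fragments`` records are
    returned, in generation order.
    """
    dyads.validate_sorted()
    chrom_names = list(dyads.positions)
    lengths = {c: length for c, length in config.genome.items()}
    pos_all = np.concatenate([dyads.positions[c] for c in chrom_names]) if chrom_names else np.empty(0, np.int64)
    if pos_all.size == 0:
        if config.n_fragments > 0:
            raise ConfigError("cannot draw fragments from an empty dyad track")
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)})
    sizes = np.array([dyads.positions[c].size for c in chrom_names])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    chrom_of = np.repeat(np.arange(len(chrom_names)), sizes)
    chrom_last = offsets[1:] - 1  # last dyad index of each chromosome
    chrom_len = np.array([lengths[c] for c in chrom_names], dtype=np.int64)

    rng = np.random.default_rng([config.seed, _FRAG_STREAM])
    n = config.n_fragments
    half = config.footprint // 2
    rest = config.footprint - half

    is_multi = rng.random(n) < config.multi_frac
    first = rng.integers(0, pos_all.size, n)
    k = np.ones(n, dtype=np.int64)
    n_multi = int(is_multi.sum())
    if n_multi:
        k[is_multi] = 1 + rng.geometric(config.multi_decay, n_multi)
    last = first + k - 1
    limit = chrom_last[chrom_of[first]]
    n_trunc = int((last > limit).sum())
    if n_trunc:
        logger.info("truncated %d multi-nucleosome fragments at chromosome ends", n_trunc)
    last = np.minimum(last, limit)

    mono = ~is_multi | (last == first)
    start = np.empty(n, dtype=np.int64)
    end = np.empty(n, dtype=np.int64)
    n_mono = int(mono.sum())
    if n_mono:
        min_len = int(np.ceil(0.8 * config.footprint))
        frag_len = np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, n_mono)).astype(np.int64)
        np.clip(frag_len, min_len, None, out=frag_len)
        centre = pos_all[first[mono]]
        start[mono] = centre - frag_len // 2
        end[mono] = start[mono] + frag_len
    multi = ~mono
    if multi.any():
        start[multi] = pos_all[first[multi]] - half
        end[multi] = pos_all[last[multi]] + rest
    ci = chrom_of[first]
    np.clip(start, 0, None, out=start)
    np.minimum(end, chrom_len[ci], out=end)
    return pd.DataFrame(
        {
            "chrom": pd.Series(np.array(chrom_names, dtype=object)[ci], dtype=str),
            "start": start,
            "end": end,
        }
    )


def simulate(config: SimConfig) -> tuple[pd.DataFrame, DyadTrack, SimGroundTruth]:
    """Full pipeline: dyad placement then fragment emission."""
    track, truth = simulate_dyad_positions(config)
    frags = simulate_fragments(track, config)
    return frags, track, truth


@dataclass(frozen=True)
class StateInterval:
    """One labeled genomic interval with its own true repeat length."""

    chrom: str
    start: int
    end: int
    label: str
    true_nrl: int


@dataclass(frozen=True)
class StateMap:
    """Disjoint labeled intervals, each simulated with its own NRL."""

    intervals: Sequence[StateInterval]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ConfigError("state map has no intervals")
        by_chrom: dict[str, list[StateInterval]] = {}
        for iv in self.intervals:
            if iv.start < 0 or iv.start >= iv.end:
                raise ConfigError(f"invalid interval [{iv.start}, {iv.end}) for label {iv.label!r}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ConfigError(
                        f"overlapping intervals on {chrom}: [{a.start},{a.end}) {a.label!r} "
                        f"and [{b.start},{b.end}) {b.label!r}"
                    )

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.label)
        return list(seen)


def simulate_state_mixture(
    state_map: StateMap, base_config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimGroundTruth]:
    """Simulate a genome whose labeled regions carry different NRLs.

    ``base_config.n_fragments`` is interpreted per label; within a label,
    fragments are allocated to its intervals proportionally to interval
    length. Each interval is simulated as an independent landscape (its
    own boundary process starting at the interval start) so
    multi-nucleosome fragments never bridge intervals.

    Returns (fragments, regions, truth_table, ground_truth): fragments and
    regions as DataFrames ready for the BED writers, a per-label table of
    true NRLs and placement counts, and the merged dyad-level ground truth.
    """
    frames: list[pd.DataFrame] = []
    tracks: dict[str, list[np.ndarray]] = {}
    bound_acc: dict[str, list[np.ndarray]] = {}
    array_acc: dict[str, list[np.ndarray]] = {}
    rows = []
    array_offset = 0
    indexed = list(enumerate(state_map.intervals))
    for label in state_map.labels():
        ivs = [(idx, iv) for idx, iv in indexed if iv.label == label]
        total = sum(iv.end - iv.start for _, iv in ivs)
        n_dyads_label = 0
        n_frags_label = 0
        for idx, iv in ivs:
            share = (iv.end - iv.start) / total
            n_frag = int(round(base_config.n_fragments * share))
            # distinct deterministic stream per interval, derived from the one seed
            sub_seed = int(
                np.random.SeedSequence([base_config.seed, _STATE_STREAM, idx]).generate_state(1)[0]
                % (2**31)
            )
            sub = replace(
                base_config,
                genome=GenomeLayout({iv.chrom: iv.end - iv.start}),
                true_nrl=iv.true_nrl,
                n_fragments=n_frag,
                seed=sub_seed,
            )
            frags, track, truth = simulate(sub)
            frags = frags.copy()
            frags["start"] += iv.start
            frags["end"] += iv.start
            frags["chrom"] = iv.chrom
            frames.append(frags)
            pos = track.positions.get(iv.chrom, np.empty(0, np.int64)) + iv.start
            tracks.setdefault(iv.chrom, []).append(pos)
            bound_acc.setdefault(iv.chrom, []).append(truth.boundaries[iv.chrom] + iv.start)
            array_acc.setdefault(iv.chrom, []).append(
                truth.array_ids[iv.chrom] + array_offset
            )
            array_offset += int(truth.boundaries[iv.chrom].size)
            n_dyads_label += pos.size
            n_frags_label += len(frags)
        rows.append(
            {
                "label": label,
                "true_nrl": ivs[0][1].true_nrl,
                "n_intervals": len(ivs),
                "total_bp": total,
                "n_dyads": n_dyads_label,
                "n_fragments": n_frags_label,
            }
        )
    fragments = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["chrom", "start", "end"])
    regions = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in state_map.intervals],
            "start": [iv.start for iv in state_map.intervals],
            "end": [iv.end for iv in state_map.intervals],
            "label": [iv.label for iv in state_map.intervals],
        }
    )
    merged = {}
    merged_arrays = {}
    merged_bounds = {}
    for chrom, parts in tracks.items():
        pos = np.concatenate(parts)
        arr = np.concatenate(array_acc[chrom])
        order = np.argsort(pos, kind="stable")
        merged[chrom] = pos[order]
        merged_arrays[chrom] = arr[order]
        merged_bounds[chrom] = np.sort(np.concatenate(bound_acc[chrom]))
    truth_all = SimGroundTruth(DyadTrack(merged), merged_bounds, merged_arrays, base_config)
    truth_table = pd.DataFrame(rows)
    return fragments, regions, truth_table, truth_all
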