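"""Fragment I/O and dyad derivation.

Sequenced paired-end fragments (MNase-seq, ATAC-seq, cfDNA) are held as a
pandas DataFrame with columns ``chrom`` (str), ``start`` (int), ``end``
(int). Coordinates are 0-based half-open throughout, following the BED
convention: ``start`` is inclusive, ``end`` exclusive, length =
``end - start``.

The nucleosome dyad — the centre of the protected DNA — is estimated as
the midpoint of each fragment, ``floor((start + end) / 2)``, which for an
odd-length fragment is the unique central base of the half-open interval.
Dyads are collected per chromosome into a :class:`DyadTrack` of sorted
integer positions; duplicate positions are allowed because independent
fragments may share a midpoint.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("nrlkit")

FRAGMENT_COLUMNS = ["chrom", "start", "end"]

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of a genome or simulated genome."""

    chromosomes: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genome layout has no chromosomes")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", dict(self.chromosomes))

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def items(self):
        return self.chromosomes.items()


@dataclass
class DyadTrack:
    """Per-chromosome sorted integer positions (dyads or fragment starts)."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_positions(cls, positions: Mapping[str, Iterable[int]]) -> "DyadTrack":
        out = {}
        for chrom, pos in positions.items():
            arr = np.asarray(list(pos) if not isinstance(pos, np.ndarray) else pos, dtype=np.int64)
            out[chrom] = np.sort(arr)
        return cls(out)

    @property
    def n(self) -> int:
        return int(sum(a.size for a in self.positions.values()))

    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def shifted(self, offset: int) -> "DyadTrack":
        return DyadTrack({c: a + int(offset) for c, a in self.positions.items()})

    def validate_sorted(self) -> None:
        for chrom, arr in self.positions.items():
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValidationError(f"track positions on {chrom} are not sorted")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DyadTrack):
            return NotImplemented
        if set(self.positions) != set(other.positions):
            return False
        return all(np.array_equal(self.positions[c], other.positions[c]) for c in self.positions)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(path):
    """Yield (1-based line number, stripped line) skipping comments/blank lines."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, stripped


def _parse_int(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse {what} {token!r} as integer") from None


def read_fragments(path, dialect: str = "bed3") -> pd.DataFrame:
    """Read fragment intervals from a BED3 or 10-column BEDPE file.

    BEDPE mate pairs are collapsed to the outermost span of the two mates.
    Mates mapped to different chromosomes are rejected with a warning (the
    fragment is dropped, never emitted as a zero-length record). Files
    ending in ``.gz`` are decompressed transparently. Lines starting with
    ``#``, ``track`` or ``browser`` are skipped.
    """
    if dialect not in ("bed3", "bedpe"):
        raise ValidationError(f"unknown dialect {dialect!r}; expected 'bed3' or 'bedpe'")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_interchrom = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if dialect == "bed3":
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            start = _parse_int(fields[1], lineno, "start")
            end = _parse_int(fields[2], lineno, "end")
        else:
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: expected >=6 BEDPE columns, got {len(fields)}")
            chrom = fields[0]
            if fields[3] != chrom:
                n_interchrom += 1
                logger.warning(
                    "line %d: BEDPE mates on different chromosomes (%s vs %s); record rejected",
                    lineno, chrom, fields[3],
                )
                continue
            s1 = _parse_int(fields[1], lineno, "start1")
            e1 = _parse_int(fields[2], lineno, "end1")
            s2 = _parse_int(fields[4], lineno, "start2")
            e2 = _parse_int(fields[5], lineno, "end2")
            start = min(s1, s2)
            end = max(e1, e2)
        if start < 0 or start >= end:
            raise ValidationError(
                f"line {lineno}: invalid interval [{start}, {end}); require 0 <= start < end"
            )
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    if n_interchrom:
        logger.warning("rejected %d inter-chromosomal BEDPE records", n_interchrom)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
        }
    )


def validate_fragments(fragments: pd.DataFrame) -> None:
    """Check the fragment-table invariants: 0 <= start < end on every row."""
    for col in FRAGMENT_COLUMNS:
        if col not in fragments.columns:
            raise ValidationError(f"fragment table lacks required column {col!r}")
    if len(fragments) == 0:
        return
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    bad = (start < 0) | (start >= end)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"fragment row {i}: invalid interval [{start[i]}, {end[i]}); require 0 <= start < end"
        )


def write_fragments(fragments: pd.DataFrame, path, dialect: str = "bed3", read_len: int = 50) -> None:
    """Write fragments as BED3, or as 10-column BEDPE with synthetic mates.

    The BEDPE writer emits, for each fragment, a mate pair whose outermost
    span is the fragment: mate 1 covers the first ``read_len`` bp, mate 2
    the last ``read_len`` bp (capped at the fragment length), so reading
    the file back with ``dialect='bedpe'`` reproduces the fragments.
    Coordinates are 0-based half-open.
    """
    validate_fragments(fragments)
    with _open_text(path, "wt") as fh:
        if dialect == "bed3":
            for chrom, start, end in fragments[FRAGMENT_COLUMNS].itertuples(index=False):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        elif dialect == "bedpe":
            for i, (chrom, start, end) in enumerate(fragments[FRAGMENT_COLUMNS].itertuples(index=False)):
                rl = min(read_len, end - start)
                fh.write(
                    f"{chrom}\t{start}\t{start + rl}\t{chrom}\t{end - rl}\t{end}"
                    f"\tfrag{i}\t0\t+\t-\n"
                )
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")


def filter_by_length(fragments: pd.DataFrame, min_len: int, max_len: int) -> pd.DataFrame:
    """Retain fragments with min_len <= length <= max_len.

    The default mononucleosome window used upstream of dyad analysis is
    [100, 200] bp: the ~147 bp core footprint plus part of a linker.
    Retained/discarded counts are logged; an empty result is legal.
    """
    if not (0 < min_len <= max_len):
        raise ValidationError(f"require 0 < min_len <= max_len, got [{min_len}, {max_len}]")
    validate_fragments(fragments)
    length = fragments["end"] - fragments["start"]
    keep = (length >= min_len) & (length <= max_len)
    out = fragments.loc[keep].reset_index(drop=True)
    n_kept, n_drop = int(keep.sum()), int((~keep).sum())
    logger.info("length filter [%d, %d]: retained %d, discarded %d", min_len, max_len, n_kept, n_drop)
    if n_kept == 0:
        logger.warning("length filter [%d, %d] retained no fragments", min_len, max_len)
    return out


def compute_dyads(fragments: pd.DataFrame) -> DyadTrack:
    """Dyad positions: floor((start + end) / 2) per fragment, sorted per chromosome.

    Permutation-invariant: any ordering of the input rows yields the same
    track, because positions are sorted within each chromosome.
    """
    validate_fragments(fragments)
    dyads = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
    return _group_sorted(fragments["chrom"].to_numpy(), dyads)


def fragment_starts(fragments: pd.DataFrame) -> DyadTrack:
    """Sorted per-chromosome 5' start coordinates, for start-phasogram analysis.

    Useful when only single-end-style information is trusted: the fragment
    start is assumed to sit near the nucleosome entry point.
    """
    validate_fragments(fragments)
    return _group_sorted(fragments["chrom"].to_numpy(), fragments["start"].to_numpy(np.int64))


def _group_sorted(chroms: np.ndarray, positions: np.ndarray) -> DyadTrack:
    out: dict[str, np.ndarray] = {}
    if len(chroms) == 0:
        return DyadTrack(out)
    ser = pd.Series(positions)
    for chrom, grp in ser.groupby(pd.Series(chroms).to_numpy()):
        out[str(chrom)] = np.sort(grp.to_numpy(np.int64))
    return DyadTrack(out)


def fragment_lengths(fragments: pd.DataFrame) -> np.ndarray:
    """Fragment lengths end - start as an int64 array."""
    validate_fragments(fragments)
    return (fragments["end"] - fragments["start"]).to_numpy(np.int64)
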