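"""NRL from the fragment-length distribution — the electrophoresis-ladder analogue.

Partially digested chromatin yields fragments protected by one, two,
three, ... nucleosomes, so the fragment-size histogram shows a ladder of
peaks whose spacing is the nucleosome repeat length. Regressing summit
position on rung order k recovers the NRL as the slope; the intercept
absorbs the mononucleosome offset (a mono fragment is roughly footprint
plus partial linker, not one full NRL, and any global size offset such as
adapter contribution moves the intercept, never the slope).

This estimator needs no dyad positions, so it also applies to ATAC-seq
and to low-coverage cfDNA data where a phasogram is impractical. The
sub-mononucleosome peak of ATAC-seq (linker-sized fragments between
nucleosomes) is excluded by the ``mono_min`` cutoff — those fragments
reflect accessibility, not n-nucleosome protection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .fragments import fragment_lengths
from .phasogram import (
    DEFAULT_MAX_PEAKS,
    DEFAULT_MIN_SIGMA,
    DEFAULT_PERIOD_MAX,
    DEFAULT_PERIOD_MIN,
    DEFAULT_PROMINENCE_FRAC,
    DEFAULT_SMOOTH_WINDOW,
    LagHistogram,
    NRLEstimate,
    SummitSeries,
    detect_ladder_summits,
    fit_nrl,
    smooth_histogram,
)

logger = logging.getLogger("nrlkit")

DEFAULT_MONO_MIN = 120
DEFAULT_MAX_LEN = 2000


@dataclass
class SizeHistogram:
    """Counts per 1 bp fragment length in [1, max_len], plus an overflow bucket."""

    max_len: int
    counts: np.ndarray
    overflow: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.max_len,):
            raise ValidationError(f"counts length {self.counts.size} != max_len {self.max_len}")
        if np.any(self.counts < 0) or self.overflow < 0:
            raise ValidationError("negative counts in size histogram")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.max_len + 1)

    def value_at(self, length: int) -> int:
        if not (1 <= length <= self.max_len):
            raise ValidationError(f"length {length} outside [1, {self.max_len}]")
        return int(self.counts[length - 1])


def fragment_size_histogram(fragments: pd.DataFrame, max_len: int = DEFAULT_MAX_LEN) -> SizeHistogram:
    """Histogram of exact fragment lengths; lengths > max_len go to overflow.

    The default ceiling of 2000 bp accommodates ~10-nucleosome fragments.
    """
    lengths = fragment_lengths(fragments)
    in_range = lengths <= max_len
    overflow = int((~in_range).sum())
    if overflow:
        logger.warning("%d fragments longer than %d bp counted into the overflow bucket", overflow, max_len)
    counts = np.bincount(lengths[in_range], minlength=max_len + 1)[1 : max_len + 1]
    return SizeHistogram(max_len, counts, overflow)


def nrl_from_size_distribution(
    hist: SizeHistogram,
    mono_min: int = DEFAULT_MONO_MIN,
    period_min: int = DEFAULT_PERIOD_MIN,
    period_max: int = DEFAULT_PERIOD_MAX,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    include_mono: bool = False,
) -> tuple[NRLEstimate, SummitSeries]:
    """Fit the multinucleosome ladder of a size histogram; slope = NRL.

    The mononucleosome summit is the argmax in
    [mono_min, mono_min + period_max]; subsequent rungs are searched at
    mono + (k-1) * period. Data without multinucleosome fragments (heavy
    digestion, or short-read libraries that lose long fragments) cannot
    support the fit and raise :class:`EstimationError`.

    By default the mono summit only seeds the ladder search and is
    excluded from the regression (``include_mono=False``): its position is
    footprint plus a digestion-geometry overhang that need not be
    collinear with the multinucleosome rungs, and any residual global
    size offset of the retained rungs is absorbed by the intercept. With
    ``include_mono=True`` the mono summit enters the fit as rung k = 1.
    """
    as_lag = LagHistogram(1, hist.max_len, hist.counts.astype(float), source="size")
    smoothed = smooth_histogram(as_lag, smooth_window)
    try:
        summits = detect_ladder_summits(
            smoothed.counts,
            offset0=1,
            first_lo=mono_min,
            first_hi=mono_min + period_max,
            period_min=period_min,
            period_max=period_max,
            max_peaks=max_peaks,
            prominence_frac=prominence_frac,
            smooth_window=smooth_window,
            min_sigma=min_sigma,
        )
    except EstimationError as err:
        raise EstimationError(
            "insufficient multinucleosome signal: fewer than 3 ladder peaks detected "
            "(heavily digested or short-read data lack multinucleosome fragments)"
        ) from err
    if not include_mono and summits.orders[0] == 1:
        if summits.n < 4:
            raise EstimationError(
                "insufficient multinucleosome signal: fewer than 3 multinucleosome "
                "ladder peaks beyond the mononucleosome summit"
            )
        summits = SummitSeries(summits.orders[1:], summits.positions[1:], summits.heights[1:])
    return fit_nrl(summits, method="fragment_size"), summits
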