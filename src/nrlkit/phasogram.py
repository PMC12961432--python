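"""Phasogram construction and NRL regression.

A phasogram is the histogram of pairwise genomic distances between
nucleosome dyads (or fragment starts) — the empirical autocorrelation of
the dyad track. In chromatin with regularly spaced nucleosomes it shows
peaks at integer multiples of the nucleosome repeat length (NRL); an
ordinary least-squares fit of summit position on peak order k then gives
the NRL as the slope, with the intercept absorbing any constant offset.

Pair counting is windowed: for a sorted track, distances are accumulated
by neighbour rank (pos[i+j] - pos[i] for j = 1, 2, ... until every rank-j
gap exceeds ``max_lag``), so the cost is proportional to the number of
pairs within the lag window rather than to all n^2 pairs. Histograms are
computed per chromosome and summed, which excludes cross-chromosome
pairs by construction.

Two summit detectors are provided:

* :func:`detect_summits` — for phasograms, where summit_k sits near
  k * period; the period is seeded from the dominant peak and refined as
  the running mean of summit_k / k.
* :func:`detect_ladder_summits` — for ladders whose first rung carries an
  arbitrary offset (fragment-size distributions, anchored occupancy
  profiles), where summit_k sits near summit_1 + (k-1) * period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import EstimationError, ValidationError
from .fragments import DyadTrack

logger = logging.getLogger("nrlkit")

DEFAULT_MIN_LAG = 50
DEFAULT_MAX_LAG = 1200
DEFAULT_SMOOTH_WINDOW = 15
DEFAULT_PERIOD_MIN = 120
DEFAULT_PERIOD_MAX = 260
DEFAULT_MAX_PEAKS = 10
DEFAULT_PROMINENCE_FRAC = 0.02
# prominence is a max-over-window, peak-minus-trough statistic: under a
# white-noise null its typical value is ~4 smoothed-noise SDs (each
# search window selects the highest of ~8 independent bumps and
# subtracts a trough), so 6 SDs keeps the false-ladder rate low
DEFAULT_MIN_SIGMA = 6.0


@dataclass
class LagHistogram:
    """Counts of pairwise distances per 1 bp lag in [min_lag, max_lag]."""

    min_lag: int
    max_lag: int
    counts: np.ndarray
    source: str = "dyad"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.max_lag < self.min_lag:
            raise ValidationError(f"max_lag {self.max_lag} < min_lag {self.min_lag}")
        if self.counts.shape != (self.max_lag - self.min_lag + 1,):
            raise ValidationError(
                f"counts length {self.counts.size} != lag span {self.max_lag - self.min_lag + 1}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative counts in lag histogram")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.min_lag, self.max_lag + 1)

    def value_at(self, lag: int) -> float:
        if not (self.min_lag <= lag <= self.max_lag):
            raise ValidationError(f"lag {lag} outside [{self.min_lag}, {self.max_lag}]")
        return float(self.counts[lag - self.min_lag])


@dataclass
class SummitSeries:
    """Accepted peak summits as (order k, position bp) pairs, k ascending."""

    orders: np.ndarray
    positions: np.ndarray
    heights: np.ndarray = None

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.heights is None:
            self.heights = np.full(self.orders.size, np.nan)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.orders.size != self.positions.size:
            raise ValidationError("orders and positions differ in length")
        if self.orders.size > 1:
            if np.any(np.diff(self.orders) <= 0):
                raise ValidationError("peak orders must be strictly increasing")
            if np.any(np.diff(self.positions) <= 0):
                raise ValidationError("summit positions must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.orders.size)


@dataclass
class NRLEstimate:
    """Slope-based NRL estimate with regression diagnostics."""

    nrl: float
    intercept: float
    slope_stderr: float
    r_squared: float
    n_summits: int
    method: str

    def __post_init__(self) -> None:
        if self.n_summits < 3:
            raise ValidationError("an NRL estimate requires at least 3 summits")
        if self.slope_stderr < 0:
            raise ValidationError("negative slope standard error")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


def _pair_lag_counts(pos: np.ndarray, min_lag: int, max_lag: int) -> np.ndarray:
    """Counts of pairwise distances in [min_lag, max_lag] for one sorted array.

    Iterates over neighbour rank j; the minimum rank-j gap is
    non-decreasing in j, so iteration stops as soon as it exceeds max_lag.
    """
    n_bins = max_lag - min_lag + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    n = pos.size
    for j in range(1, n):
        d = pos[j:] - pos[:-j]
        if d.min() > max_lag:
            break
        sel = d[(d >= min_lag) & (d <= max_lag)]
        if sel.size:
            counts += np.bincount(sel - min_lag, minlength=n_bins)
    return counts


def compute_phasogram(
    track: DyadTrack,
    min_lag: int = DEFAULT_MIN_LAG,
    max_lag: int = DEFAULT_MAX_LAG,
    source: str = "dyad",
) -> LagHistogram:
    """Histogram of same-chromosome ordered-pair distances within [min_lag, max_lag].

    Every ordered pair (i < j) on the same chromosome with
    min_lag <= pos_j - pos_i <= max_lag increments the count at that lag.
    The track must be sorted per chromosome. The default lag window
    [50, 1200] bp suppresses sub-nucleosomal digestion artifacts at short
    lags while retaining five or more periodic peaks at typical NRLs.
    """
    if min_lag < 1 or max_lag < min_lag:
        raise ValidationError(f"require 1 <= min_lag <= max_lag, got [{min_lag}, {max_lag}]")
    track.validate_sorted()
    n_bins = max_lag - min_lag + 1
    total = np.zeros(n_bins, dtype=np.int64)
    for chrom, pos in track.positions.items():
        if pos.size > 1:
            total += _pair_lag_counts(pos, min_lag, max_lag)
    return LagHistogram(min_lag, max_lag, total, source=source)


def compute_start_phasogram(
    starts: DyadTrack, min_lag: int = DEFAULT_MIN_LAG, max_lag: int = DEFAULT_MAX_LAG
) -> LagHistogram:
    """Phasogram of fragment 5' starts — the single-end-sequencing variant.

    Identical pair-counting kernel as :func:`compute_phasogram`; a constant
    offset between starts and dyads cancels in pairwise distances, so the
    regression slope is unaffected by which track is used.
    """
    return compute_phasogram(starts, min_lag, max_lag, source="start")


def smooth_histogram(hist: LagHistogram, window: int = DEFAULT_SMOOTH_WINDOW) -> LagHistogram:
    """Centred moving average with truncated windows at the edges.

    ``window`` must be odd; window = 1 is the identity. The default of
    15 bp is wide enough to suppress the 10-bp helical-twist ripple of
    linker-length quantisation while keeping summit positions accurate to
    ~1 bp.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1:
        return replace(hist, counts=hist.counts.copy())
    n = hist.counts.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(hist.counts)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return replace(hist, counts=(csum[hi] - csum[lo]) / (hi - lo))


def _local_max_prominence(values: np.ndarray, idx: int) -> float:
    """Prominence of values[idx] if it is a local maximum, else -1.

    A plateau counts as a local maximum at its left edge (ties broken
    toward the smaller lag).
    """
    n = values.size
    if idx <= 0 or idx >= n - 1:
        return -1.0  # border argmax is a window artifact, not a summit
    v = values[idx]
    if not (values[idx - 1] < v and values[idx + 1] <= v):
        return -1.0
    # walk outwards to the nearest higher points; prominence relative to
    # the higher of the two intervening minima (border sides are ignored)
    bases = []
    if idx > 0:
        left_min = v
        i = idx - 1
        while i >= 0 and values[i] <= v:
            left_min = min(left_min, values[i])
            i -= 1
        bases.append(left_min)
    if idx < n - 1:
        right_min = v
        i = idx + 1
        while i < n and values[i] <= v:
            right_min = min(right_min, values[i])
            i += 1
        bases.append(right_min)
    if not bases:
        return float(v)
    return float(v - max(bases))


def _refine_summit(values: np.ndarray, idx: int, radius: int) -> float:
    """Sub-bin summit position: vertex of a least-squares parabola.

    Fitted to values[idx-radius .. idx+radius]; falls back to the plateau
    centre when the fit is not concave or the vertex leaves the window.
    Averaging over ~2*radius bins suppresses the counting-noise wander of
    a bare argmax on broad peaks; flat-topped peaks (impulses spread by
    box smoothing) resolve to their centre rather than their left edge.
    """
    l = r = idx
    while l > 0 and values[l - 1] == values[idx]:
        l -= 1
    while r < values.size - 1 and values[r + 1] == values[idx]:
        r += 1
    centre = (l + r) / 2.0
    ic = int(round(centre))
    lo = max(ic - radius, 0)
    hi = min(ic + radius, values.size - 1)
    x = np.arange(lo, hi + 1, dtype=float)
    if x.size < 5:
        return centre
    a, b, _ = np.polyfit(x, values[lo : hi + 1], 2)
    if a >= 0:
        return centre
    vertex = -b / (2 * a)
    if not (lo <= vertex <= hi) or abs(vertex - centre) > radius:
        return centre
    return float(vertex)


def _window_argmax(values: np.ndarray, lo: int, hi: int) -> int:
    """Index of the maximum in values[lo:hi+1]; ties go to the smaller index."""
    lo = max(lo, 0)
    hi = min(hi, values.size - 1)
    if hi < lo:
        return -1
    return lo + int(np.argmax(values[lo : hi + 1]))


def detect_summits(
    hist: LagHistogram,
    period_min: int = DEFAULT_PERIOD_MIN,
    period_max: int = DEFAULT_PERIOD_MAX,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    include_first: bool = True,
    refine_radius: int = 15,
) -> SummitSeries:
    """Locate periodic summits of a (smoothed) phasogram.

    The period seed p is the argmax of the histogram in
    [period_min, period_max]. For k = 1..max_peaks the candidate summit is
    the argmax within [k*p - p/3, k*p + p/3] (clipped to the histogram
    range); it is accepted if it is a local maximum with prominence above
    ``prominence_frac`` of the k = 1 peak height. Accepted summits are
    refined to sub-bin precision by a parabola fit within
    ``refine_radius`` bp (0 disables refinement). After each acceptance p
    is re-estimated as the running mean of summit_k / k. Gaps in k are
    allowed. ``include_first=False`` drops k = 1 from the returned series
    (it is the summit most sensitive to smoothing) while still using it to
    seed the period.

    Raises :class:`EstimationError` when fewer than 3 summits are accepted.
    """
    if not (100 <= period_min < period_max):
        raise ValidationError(f"require 100 <= period_min < period_max, got [{period_min}, {period_max}]")
    values = hist.counts
    lag0 = hist.min_lag
    seed_idx = _window_argmax(values, period_min - lag0, period_max - lag0)
    if seed_idx < 0:
        raise EstimationError("insufficient periodicity: period window outside histogram range")
    p_hat = float(seed_idx + lag0)
    orders, positions, heights = [], [], []
    ratios = []
    first_height = None
    for k in range(1, max_peaks + 1):
        lo = int(round(k * p_hat - p_hat / 3)) - lag0
        hi = int(round(k * p_hat + p_hat / 3)) - lag0
        idx = _window_argmax(values, lo, hi)
        if idx < 0:
            continue
        prom = _local_max_prominence(values, idx)
        if prom < 0:
            continue
        height = float(values[idx])
        if first_height is None:
            # k = 1 anchors the prominence scale; require a real local max
            if prom <= 0:
                continue
            first_height = height
        elif prom < prominence_frac * first_height or prom <= 0:
            continue
        pos = (_refine_summit(values, idx, refine_radius) if refine_radius else float(idx)) + lag0
        if positions and pos <= positions[-1]:
            continue
        orders.append(k)
        positions.append(pos)
        heights.append(height)
        ratios.append(pos / k)
        p_hat = float(np.mean(ratios))
    if not include_first and orders and orders[0] == 1:
        orders, positions, heights = orders[1:], positions[1:], heights[1:]
    if len(orders) < 3:
        raise EstimationError(
            f"insufficient periodicity: only {len(orders)} summit(s) detected (need >= 3)"
        )
    return SummitSeries(np.array(orders), np.array(positions), np.array(heights))


def detect_ladder_summits(
    values: np.ndarray,
    offset0: int,
    first_lo: int,
    first_hi: int,
    period_min: int = DEFAULT_PERIOD_MIN,
    period_max: int = DEFAULT_PERIOD_MAX,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    refine_radius: int = 15,
    noise_sd: float | None = None,
) -> SummitSeries:
    """Locate equally spaced summits whose first rung carries an offset.

    ``values[i]`` is the (smoothed) signal at coordinate ``offset0 + i``.
    The first summit is the argmax in [first_lo, first_hi]; the second is
    searched in [s1 + period_min, s1 + period_max]; thereafter summit_k is
    the argmax within s1 + (k-1)*p +/- p/3, with p the running mean of
    (summit_k - summit_1)/(k-1). A summit must be a local maximum with
    prominence above ``prominence_frac`` of the first summit's height AND
    above ``min_sigma`` counting-noise standard deviations, so an
    aperiodic signal (e.g. an occupancy profile around unphased anchors)
    yields an estimation error rather than a spurious ladder.

    ``noise_sd`` is the per-bin noise standard deviation of the RAW
    (pre-smoothing) signal; the smoothed noise scale is then
    noise_sd / sqrt(window). When None, Poisson counting noise is
    assumed: sd = sqrt(level), appropriate for histograms whose bins
    collect independent events.
    """
    values = np.asarray(values, dtype=float)

    def _noise(height: float) -> float:
        raw_sd = noise_sd if noise_sd is not None else float(np.sqrt(max(height, 1.0)))
        return raw_sd / float(np.sqrt(smooth_window))

    def _accept(idx: int, ref_height: float | None) -> bool:
        prom = _local_max_prominence(values, idx)
        if prom <= 0:
            return False
        if prom < min_sigma * _noise(values[idx]):
            return False
        if ref_height is not None and prom < prominence_frac * ref_height:
            return False
        return True

    # the first rung is the LEFTMOST significant local maximum in the
    # window, not the argmax: in heavily digested libraries a higher-order
    # rung can be taller than the first one and must not anchor the ladder
    i1 = -1
    w_lo = max(first_lo - offset0, 1)
    w_hi = min(first_hi - offset0, values.size - 2)
    for i in range(w_lo, w_hi + 1):
        if values[i - 1] < values[i] >= values[i + 1] and _accept(i, None):
            i1 = i
            break
    if i1 < 0:
        raise EstimationError("insufficient periodicity: no significant first summit")
    s1 = (_refine_summit(values, i1, refine_radius) if refine_radius else float(i1)) + offset0
    h1 = float(values[i1])
    orders, positions, heights = [1], [float(s1)], [h1]
    gaps: list[float] = []
    p_hat: float | None = None
    for k in range(2, max_peaks + 1):
        if p_hat is None:
            lo, hi = int(round(s1 + period_min)), int(round(s1 + period_max))
        else:
            centre = s1 + (k - 1) * p_hat
            lo, hi = int(round(centre - p_hat / 3)), int(round(centre + p_hat / 3))
        idx = _window_argmax(values, lo - offset0, hi - offset0)
        if idx < 0 or not _accept(idx, h1):
            if p_hat is None:
                break  # cannot continue without a period estimate
            continue
        pos = (_refine_summit(values, idx, refine_radius) if refine_radius else float(idx)) + offset0
        if pos <= positions[-1]:
            continue
        orders.append(k)
        positions.append(pos)
        heights.append(float(values[idx]))
        gaps.append((pos - s1) / (k - 1))
        p_hat = float(np.mean(gaps))
    if len(orders) < 3:
        raise EstimationError(
            f"insufficient periodicity: only {len(orders)} summit(s) detected (need >= 3)"
        )
    return SummitSeries(np.array(orders), np.array(positions), np.array(heights))


def fit_nrl(summits: SummitSeries, method: str = "dyad_phasogram") -> NRLEstimate:
    """Ordinary least squares of summit position on peak order; slope = NRL.

    The intercept is kept free rather than forced through the origin: the
    first-peak position can carry a method-dependent offset (explicit in
    the fragment-size ladder, harmless for phasograms).
    """
    if summits.n < 3:
        raise EstimationError(f"need >= 3 summits for regression, got {summits.n}")
    k = summits.orders.astype(float)
    if np.ptp(k) == 0:
        raise EstimationError("zero variance in peak order; cannot regress")
    res = stats.linregress(k, summits.positions)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return NRLEstimate(
        nrl=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=stderr,
        r_squared=float(res.rvalue) ** 2,
        n_summits=summits.n,
        method=method,
    )


def estimate_nrl_from_track(
    track: DyadTrack,
    min_lag: int = DEFAULT_MIN_LAG,
    max_lag: int = DEFAULT_MAX_LAG,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    period_min: int = DEFAULT_PERIOD_MIN,
    period_max: int = DEFAULT_PERIOD_MAX,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    include_first: bool = True,
    source: str = "dyad",
) -> tuple[NRLEstimate, LagHistogram, SummitSeries]:
    """Convenience pipeline: phasogram -> smoothing -> summits -> OLS fit."""
    hist = compute_phasogram(track, min_lag, max_lag, source=source)
    smoothed = smooth_histogram(hist, smooth_window)
    summits = detect_summits(
        smoothed, period_min, period_max, max_peaks, prominence_frac, include_first
    )
    method = "dyad_phasogram" if source == "dyad" else "start_phasogram"
    return fit_nrl(summits, method=method), smoothed, summits
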