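# Methods

## The estimation problem

Nucleosomes protect ~147 bp of DNA; consecutive nucleosomes in an array
are spaced by the nucleosome repeat length (NRL = footprint + linker).
Fragmentation assays (MNase digestion, Tn5 tagmentation, endogenous
cfDNA nucleases) release DNA whose coordinates and lengths carry this
periodicity. nrlkit estimates the NRL as the slope of an ordinary
least-squares fit of periodic summit position on peak order. Fitting a
slope over several peak orders, rather than reading off a single peak
position, is what delivers sub-base-pair precision: each summit is
located to ~1 bp, and the regression averages their errors while any
constant offset goes into the intercept.

## Phasogram estimators

The dyad of each fragment is `floor((start + end) / 2)` in 0-based
half-open coordinates — for odd-length fragments the unique central
base. The phasogram counts, per chromosome, every ordered dyad pair at
distance `d` within a lag window (default 50–1200 bp; the lower bound
suppresses sub-nucleosomal digestion artefacts, the upper bound keeps
five or more peak orders at mammalian NRLs). Counting iterates over
neighbour rank in the sorted track, so cost is proportional to the
number of in-window pairs, and an all-pairs quadratic oracle in the test
suite checks exact equivalence. Chromosome histograms are summed;
cross-chromosome pairs cannot occur by construction.

The start-phasogram variant counts fragment 5' starts instead and
exists for single-end-style data. Because a constant start-to-dyad
offset cancels in pairwise distances, the two variants agree on the
slope (verified within 2 bp on shared simulations).

Before fitting, a mononucleosome length filter (default 100–200 bp,
configurable) removes sub-nucleosomal and multi-nucleosome fragments
whose midpoints are not dyad estimates. The exact window is a judgement
call on real data; the default covers footprint plus a partial linker.

## Summit detection

Histograms are smoothed by a centred moving average (default 15 bp, odd,
truncated at the edges; window 1 is the identity). 15 bp is wide enough
to suppress the 10-bp helical-twist ripple of linker quantisation yet
narrow enough to keep summit positions accurate.

For phasograms, the period seed is the argmax in the period window
(default 120–260 bp, covering reported NRLs from ~154 to ~240 bp). For
k = 1..max_peaks (default 10) the candidate summit is the argmax within
`k·p ± p/3`; it must be an interior local maximum with prominence above
2% of the first peak's height, and the period estimate is refined as the
running mean of `summit_k / k`. Missing orders are skipped — OLS accepts
gapped (k, position) pairs.

Accepted summits are refined to sub-bin precision by the vertex of a
least-squares parabola over ±15 bp (plateaus first collapse to their
centre). Without refinement the integer argmax of a broad peak
(positional jitter of 20 bp makes phasogram peaks ~28 bp wide) wanders
several bp under counting noise, which is the difference between ~5 bp
and sub-bp recovery at moderate coverage. Setting `refine_radius=0`
restores the bare argmax.

Ladder-type signals — the fragment-size histogram and anchored profiles
— have an arbitrary first-rung offset, so a second detector anchors the
ladder at the *leftmost* significant local maximum in the first-rung
window (under heavy digestion a higher-order rung can be taller than the
first and must not capture the anchor), finds the second rung in
`s1 + [period_min, period_max]`, and proceeds with the running-mean
period as above.

### Significance of ladder summits

A ladder summit must additionally clear `min_sigma` (default 6) noise
standard deviations of prominence. Prominence is a max-over-window,
peak-minus-trough statistic: under a pure-noise null each ±p/3 search
window selects the highest of roughly eight independent smoothed bumps
and subtracts an intervening trough, so its typical null value is
already ~4 SDs; 6 SDs keeps the false-ladder rate low without touching
genuine rungs, which in practice sit orders of magnitude higher. For
histograms whose bins collect independent events (fragment sizes) the
noise SD is Poisson, `sqrt(level)`. Anchored profiles are overdispersed
— several fragments can share one dyad, so counts arrive in clumps —
and their per-offset noise SD is instead estimated from the
sub-nucleosomal (period < 40 bp) band of the profile's periodogram,
using the median rescaled for the exponential null so that harmonic
lines of a strongly periodic profile do not inflate the estimate.

## Fragment-size ladder

Fragments protected by k nucleosomes populate rungs near
`footprint + (k−1)·NRL` plus end-trimming offsets; regressing rung
position on k gives the NRL without any positional information, which
is why the method extends to ATAC-seq and sparse cfDNA. The
sub-mononucleosome ATAC peak (linker-sized accessible fragments) is
excluded by `mono_min` (default 120 bp) — it reflects accessibility,
not n-nucleosome protection.

By default the mononucleosome summit seeds the ladder search but is
excluded from the regression (`include_mono=False`). The mono mode sits
at footprint plus a single-fragment digestion overhang, and nothing
guarantees that offset matches the end-trimming of multi-nucleosome
rungs; when it does not, forcing the mono point onto the line biases
the slope (about −3 bp under this package's generator, whose mono
fragments average 167 bp while its multi rungs have exact-footprint
ends). When the mono mode is known to be collinear — identical
end-trimming at every rung order — `include_mono=True` adds it back and
the fit is unchanged.

## Region stratification

Labeled intervals are merged per label only where they *strictly*
overlap; bookended intervals stay distinct. The stratified phasogram
counts a pair only when both dyads fall inside the same merged interval:
the NRL is a within-array quantity, and pairs bridging two annotation
blocks (or the gap between them) would contribute phantom long lags.
Consequently the union of per-label histograms over a genome partition
is bounded above by the unstratified histogram, with boundary pairs
lost — an invariant the tests check. Labels that fail summit detection
are reported with the failure reason, never dropped.

## Anchored profiles

Dyad offsets within ±flank (default 2000 bp, about ten nucleosomes —
the extent of well-phased arrays at strong boundaries such as CTCF
sites) are aggregated across anchors, with minus-strand anchors
mirrored. Summit spacing of the downstream half gives the NRL via the
ladder detector. Aggregate-profile peak spacing is only meaningful where
arrays are genuinely phased at the anchors, so before any peak is
accepted the downstream profile must pass a Fisher-style spectral test:
the largest periodogram power at periods 120–260 bp — evaluated by
direct DFT on a 1 bp period grid, so an off-FFT-grid repeat length does
not leak across bins — must exceed the exponential-null critical value
`ln(m/α)` (α = 0.01, m independent band frequencies). One caveat found
during validation: when the underlying chromatin is strongly periodic
genome-wide, even randomly placed anchors yield *incoherent* spectral
power at 1/NRL (per-anchor periodicity survives phase randomisation in
the power domain). The spectral gate may then pass, and it is the 6-SD
prominence rule with the empirical overdispersed noise estimate that
rejects the ladder, because without phase coherence the profile's
oscillation amplitude stays at noise level.

## The simulator

`simulate_dyad_positions` draws array boundaries as a Poisson process
(rate `boundary_rate`, default 1/50 kb; each chromosome start is always
a boundary) and places dyads at
`boundary + floor(footprint/2) + i·true_nrl` with independent Gaussian
jitter (`jitter_sd`, default 20 bp) per nucleosome. Dyads landing closer
than one footprint to the previously kept dyad are discarded (steric
exclusion). `simulate_fragments` emits, per fragment, either a
mononucleosome fragment centred on a uniformly chosen dyad with length
`N(167, 15)` clipped at 0.8·footprint, or — with probability
`multi_frac`, default 0.3 — a fragment spanning k ≥ 2 consecutive dyads
(k−1 geometric with parameter `multi_decay`, default 0.5), truncated at
chromosome ends. Per-chromosome and per-interval random streams derive
from the single seed, so outputs are reproducible and independent of
iteration order. `simulate_state_mixture` simulates each labeled
interval as an independent landscape with its own NRL (`n_fragments` is
per label, split across a label's intervals by length), so
multi-nucleosome fragments never bridge annotation blocks.

What the generator does *not* model: cumulative ("statistical")
positioning drift along arrays, sequence-dependent nucleosome
preference or MNase bias, GC bias, duplicate reads, and single-cell
sparsity. Two further consequences of its design are worth knowing.
First, steric exclusion censors the short tail of the spacing
distribution, so at large jitter the *mean* kept spacing exceeds the
configured NRL (markedly so for short NRLs — at `jitter_sd` 20 and NRL
167, ~24% of placements clash); the lattice positions themselves are
unbiased, which is why phasogram summits, and hence the slope, still
sit at multiples of the true NRL. Mean-spacing ground-truth checks are
therefore run at small jitter where censoring is negligible. Second,
recovery on these synthetics demonstrates estimator correctness and
statistical precision at a given fragment density, not robustness to
the biases of real libraries.

## Problem sizes and precision

The reference validation simulates 20 Mb at 0.065 fragments/bp — the
density of ~200 million paired-end reads on a ~3.1 Gb genome — and
recovers NRL 185 within ~0.2–0.5 bp across seeds (|error| ≤ 1 bp is the
acceptance bound; the whole run takes a few seconds). Cross-method
agreement (size ladder vs dyad phasogram, multi_frac 0.5, 1M fragments)
holds within 2 bp; a two-state 180/195 bp mixture at 100k fragments per
state recovers each state within 1.5 bp. A grid of true NRLs
{167, 185, 200, 212} at 150k fragments each yields strictly increasing
estimates, each within 1 bp of truth.

## Numerical conventions

Coordinates are 0-based half-open everywhere; dyads round down
(`floor`), so no half-base positions exist. Argmax ties break toward
the smaller lag; plateau summits resolve to the plateau centre. OLS
uses `scipy.stats.linregress`; `slope_stderr` is the usual
`sqrt(residual variance / Σ(k−k̄)²)` and degenerates to 0 on an exact
line. Estimation failures (fewer than three accepted summits, no
significant periodicity) raise `EstimationError` with the reason;
invalid inputs raise `ValidationError`/`ParseError` (the latter naming
the offending line); inconsistent simulation parameters raise
`ConfigError`.
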