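# nrlkit

Nucleosome repeat length (NRL) estimation from sequencing fragment data
— MNase-seq, ATAC-seq, or cell-free DNA.

The NRL is the genomic distance between the centres of two neighbouring
nucleosomes: ~147 bp of core-protected DNA plus the linker. It varies
between species, cell types, and — within one cell — between chromatin
states: active promoters pack nucleosomes several base pairs tighter
than repressed chromatin, and shifts of only 1–2 bp are biologically
meaningful. Measuring the NRL to that precision from noisy fragment data
is what this toolkit does.

## Methods

All estimators reduce to the same statistic: locate the periodic peak
summits of a suitable distribution and fit ordinary least squares of
summit position `y_k` on peak order `k`,

```
y_k = NRL * k + b
```

The slope is the NRL; the intercept `b` absorbs any constant offset, so
global biases (adapter contributions, start-vs-dyad offsets) cancel.

| method | input distribution | typical use |
|---|---|---|
| `dyad_phasogram` | pairwise distances between fragment midpoints (dyads) | paired-end MNase-seq; the most precise |
| `start_phasogram` | pairwise distances between fragment 5' starts | single-end data |
| `fragment_size` | fragment-length histogram (the sequencing analogue of a gel ladder) | ATAC-seq, cfDNA, low coverage |
| `anchored_profile` | aggregate dyad profile around oriented anchors | TSS/CTCF-phased arrays |

Region-stratified estimation (`nrl_by_region`) computes a phasogram per
annotation label, counting only dyad pairs inside the *same* annotated
interval, so each chromatin state's estimate reflects internal spacing
only. A simulator with known ground truth (`simulate`,
`simulate_state_mixture`) generates phased, jittered nucleosome arrays
and a partial-digestion fragment model, so every estimator is validated
by parameter recovery.

Genome-wide nucleosome peak calling is deliberately not offered:
incomplete peak-based nucleosome maps are a known source of badly biased
NRL estimates.

## Worked example

```python
from nrlkit import (GenomeLayout, SimConfig, simulate, filter_by_length,
                    compute_dyads, estimate_nrl_from_track)

config = SimConfig(genome=GenomeLayout({"chr1": 10_000_000}),
                   true_nrl=188, n_fragments=500_000, seed=42, multi_frac=0.0)
fragments, track, truth = simulate(config)
mono = filter_by_length(fragments, 100, 200)   # mononucleosome window
estimate, hist, summits = estimate_nrl_from_track(compute_dyads(mono))
print(estimate.nrl, estimate.slope_stderr)
```

This prints (`examples/01_simulate_and_estimate.py` runs the full
version):

```
peak order k -> summit position (bp):
  1     185.9
  2     376.2
  3     563.9
  4     752.3
  5     940.3
  6    1128.6

NRL = 188.40 +/- 0.17 bp (true 188), r^2 = 1.00000
```

The six phasogram summits climb by ~188 bp per order; the regression
slope recovers the configured repeat length to 0.4 bp. The other
capabilities each have a narrative script under `examples/`:
fragment-size ladders (`02`), per-chromatin-state stratification (`03`),
and anchored profiles including the unphased-anchor failure mode (`04`).

The same pipelines are available as a command-line tool:

```bash
nrlkit simulate --chrom chr1:5000000 --true-nrl 190 \
    --n-fragments 150000 --seed 7 --out-fragments frags.bed
nrlkit phasogram --fragments frags.bed --out-prefix run1
# -> run1.phasogram.tsv, run1.summits.tsv, run1.estimate.tsv
```

Every output TSV carries `#`-prefixed header lines with the toolkit
version, the full effective configuration, and an MD5 checksum of each
input, and identical command lines produce byte-identical files.

## Limitations

The simulator places jitter independently per nucleosome (no cumulative
drift) and models no sequence preference, GC bias, or single-cell
sparsity; see `docs/methods.md` for what recovery on synthetic data does
and does not demonstrate about real libraries.
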