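import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nrlkit import (
    GenomeLayout,
    SimConfig,
    StateInterval,
    StateMap,
    compute_dyads,
    filter_by_length,
    simulate,
    simulate_state_mixture,
)

settings.register_profile(
    "nrlkit",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("nrlkit")

MONO_FILTER = (100, 200)


def dyads_of(frags):
    return compute_dyads(filter_by_length(frags, *MONO_FILTER))


@pytest.fixture(scope="session")
def reference_sim():
    """Scaled human-coverage simulation: 20 Mb at 0.065 fragments/bp.

    The fragment density matches ~200 million paired-end reads over a
    ~3.1 Gb genome; NRL 185 bp, 20 bp positional jitter, mononucleosome
    fragments only.
    """
    config = SimConfig(
        genome=GenomeLayout({f"chr{i}": 5_000_000 for i in range(1, 5)}),
        true_nrl=185,
        n_fragments=1_300_000,
        seed=11,
        multi_frac=0.0,
    )
    frags, track, truth = simulate(config)
    return {"config": config, "fragments": frags, "truth": truth, "dyads": dyads_of(frags)}


@pytest.fixture(scope="session")
def multinucleosome_sim():
    """ATAC-like partial digestion: half the fragments span >= 2 nucleosomes."""
    config = SimConfig(
        genome=GenomeLayout({"chr1": 20_000_000}),
        true_nrl=190,
        n_fragments=1_000_000,
        seed=2,
        multi_frac=0.5,
    )
    frags, track, truth = simulate(config)
    return {"config": config, "fragments": frags, "truth": truth, "dyads": dyads_of(frags)}


@pytest.fixture(scope="session")
def two_state_sim():
    """Alternating 300 kb blocks of two chromatin states, NRL 180 vs 195."""
    state_map = StateMap(
        [
            StateInterval(
                "chr1",
                i * 600_000,
                i * 600_000 + 300_000,
                "Active" if i % 2 == 0 else "Repressed",
                180 if i % 2 == 0 else 195,
            )
            for i in range(10)
        ]
    )
    base = SimConfig(
        genome=GenomeLayout({"chr1": 6_000_000}),
        true_nrl=190,
        n_fragments=100_000,
        seed=3,
        multi_frac=0.0,
    )
    frags, regions, truth_table, truth = simulate_state_mixture(state_map, base)
    return {
        "state_map": state_map,
        "fragments": frags,
        "regions": regions,
        "truth_table": truth_table,
        "truth": truth,
        "dyads": dyads_of(frags),
    }


@pytest.fixture
def toy_fragments():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr1"],
            "start": [1000, 50, 10, 290],
            "end": [1147, 250, 160, 440],
        }
    )


def brute_force_phasogram(track, min_lag, max_lag):
    """Quadratic all-pairs oracle for pair-distance counting."""
    counts = np.zeros(max_lag - min_lag + 1, dtype=np.int64)
    for pos in track.positions.values():
        i, j = np.triu_indices(pos.size, k=1)
        d = np.abs(pos[j] - pos[i])
        d = d[(d >= min_lag) & (d <= max_lag)]
        counts += np.bincount(d - min_lag, minlength=counts.size)
    return counts
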