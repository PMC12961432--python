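"""NRL from the aggregate dyad profile around phased-array anchors.

Where nucleosome arrays are phased at boundaries (TSSs, CTCF sites),
averaging dyad counts across anchors produces an oscillating occupancy
profile whose downstream peak spacing is the NRL. The estimator refuses
to fit unphased anchors: without phase coherence the profile carries no
significant periodicity and an error is raised instead of a number.
"""

import numpy as np
import pandas as pd

from nrlkit import (
    AnchorSet,
    EstimationError,
    GenomeLayout,
    SimConfig,
    anchored_profile,
    compute_dyads,
    filter_by_length,
    nrl_from_profile,
    simulate,
)

config = SimConfig(
    genome=GenomeLayout({"chr1": 10_000_000}),
    true_nrl=190,
    n_fragments=400_000,
    seed=9,
    multi_frac=0.0,
    jitter_sd=10.0,
    boundary_rate=1 / 20_000,  # an array boundary every ~20 kb
)
fragments, _, truth = simulate(config)
dyads = compute_dyads(filter_by_length(fragments, 100, 200))

# the true array boundaries act as anchors (as CTCF sites would)
anchors = AnchorSet(
    pd.DataFrame({"chrom": "chr1", "position": truth.boundaries["chr1"], "strand": "+"})
)
profile = anchored_profile(dyads, anchors, flank=2000)
estimate, summits = nrl_from_profile(profile)
print(f"{anchors.n} phased anchors")
print("downstream summit offsets (bp):", np.round(summits.positions, 1).tolist())
print(f"NRL = {estimate.nrl:.2f} +/- {estimate.slope_stderr:.2f} bp (true {config.true_nrl})")

# the same chromatin, but anchors placed at random: no phased signal
rng = np.random.default_rng(0)
random_anchors = AnchorSet(
    pd.DataFrame(
        {
            "chrom": "chr1",
            "position": np.sort(rng.integers(10_000, 9_990_000, anchors.n)),
            "strand": "+",
        }
    )
)
try:
    nrl_from_profile(anchored_profile(dyads, random_anchors, flank=2000))
except EstimationError as err:
    print(f"\nrandom anchors -> {err}")
    print("(peak-spacing NRL estimates require genuinely phased anchors)")
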