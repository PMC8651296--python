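#!/usr/bin/env python
"""Simulate the smFRET dataset used by the rest of the analysis.

Generates a 600-molecule set at the study conditions (100 ms frames,
two-state dynamics near E = 0.3/0.9, per-molecule γ, 7% leakage, acceptor-
then-donor photobleaching) with 10% each of four planted defect classes,
and a small two-channel movie with registration beads for the extraction
stage.  Writes the trace table, ground-truth sidecar and TIFF movies under
results/.
"""

from pathlib import Path

import numpy as np
import tifffile

from stimfret.io import write_traces_tsv
from stimfret.synthetic import (
    MovieConfig,
    SimulationConfig,
    assign_positions,
    plant_defects,
    render_movie,
    render_trace_set,
    simulate_state_paths,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(
        n_molecules=600, n_frames=800, acceptor_bleach_rate=0.03,
        donor_bleach_rate=0.05, seed=SEED,
    )
    truth = simulate_state_paths(cfg)
    truth = plant_defects(
        truth,
        {"multi_step_bleach": 0.1, "donor_first": 0.1,
         "uncorrelated": 0.1, "aggregate": 0.1},
        seed=SEED + 1,
    )
    traces = render_trace_set(truth)
    write_traces_tsv(traces, RESULTS / "traces_raw.tsv")
    truth.to_json(RESULTS / "ground_truth.json")
    print(f"wrote {len(traces)} molecule traces "
          f"({sum(m.defect != 'clean' for m in truth)} with planted defects)")

    # a small movie for the extraction stage: fewer molecules, shorter
    movie_cfg = SimulationConfig(
        n_molecules=15, n_frames=120, total_intensity=800,
        background_level=10.0, background_gradient=0.05,
        acceptor_bleach_rate=0.1, donor_bleach_rate=0.1, seed=SEED + 2,
    )
    movie_truth = simulate_state_paths(movie_cfg)
    mc = MovieConfig(misalignment_offset=np.array([1.5, -1.0]))
    movie_truth = assign_positions(movie_truth, mc)
    movie_traces = render_trace_set(movie_truth)
    stack, (bead_d, bead_a) = render_movie(movie_truth, movie_traces, mc)
    tifffile.imwrite(RESULTS / "movie.tif", stack.astype(np.float32))
    tifffile.imwrite(RESULTS / "beads.tif",
                     np.stack([bead_d, bead_a]).astype(np.float32))
    movie_truth.to_json(RESULTS / "movie_ground_truth.json")
    write_traces_tsv(movie_traces, RESULTS / "movie_traces_reference.tsv")
    print(f"wrote movie: {stack.shape} + bead registration pair")


if __name__ == "__main__":
    main()
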