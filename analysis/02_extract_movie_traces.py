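#!/usr/bin/env python
"""Extract per-molecule traces from the synthetic two-channel movie.

Registers the channels from the bead pair, detects and colocalizes spots,
sums 5×5 apertures per frame and subtracts the local median background,
then compares the extracted traces against the rendered ground truth.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from stimfret.io import read_traces_tsv, write_traces_tsv
from stimfret.movies import process_movie

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    stack = tifffile.imread(RESULTS / "movie.tif")
    beads = tifffile.imread(RESULTS / "beads.tif")
    traces, registration, pairs = process_movie(
        stack, beads[0], beads[1], min_intensity=25
    )
    write_traces_tsv(traces, RESULTS / "movie_traces_extracted.tsv")
    with open(RESULTS / "movie_molecules.json", "w") as fh:
        json.dump(
            {
                "registration": {
                    "matrix": registration.matrix.tolist(),
                    "offset": registration.offset.tolist(),
                    "residual_rms_px": registration.residual_rms,
                },
                "molecules": [
                    {"id": i, "donor_xy": [sd.x, sd.y], "acceptor_xy": [sa.x, sa.y]}
                    for i, (sd, sa) in enumerate(pairs)
                ],
            },
            fh, indent=2,
        )
    print(f"registered channels (residual {registration.residual_rms:.3f} px), "
          f"extracted {len(traces)} molecules")

    reference = read_traces_tsv(RESULTS / "movie_traces_reference.tsv")
    with open(RESULTS / "movie_ground_truth.json") as fh:
        truth = json.load(fh)
    errs = []
    for t, (sd, sa) in zip(traces, pairs):
        best = min(
            truth.items(),
            key=lambda kv: (kv[1]["donor_pos"][0] - sd.x) ** 2
            + (kv[1]["donor_pos"][1] - sd.y) ** 2,
        )
        ref = reference[int(best[0])]
        mask = ref.donor > 50
        if mask.any():
            errs.append(float(np.median(
                np.abs(t.donor[mask] - ref.donor[mask]) / ref.donor[mask]
            )))
    print(f"median relative extraction error vs rendered truth: "
          f"{np.median(errs):.3f} (PSF-tail truncation by the 5x5 aperture)")


if __name__ == "__main__":
    main()
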