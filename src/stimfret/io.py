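"""Tabular I/O for trace sets and histograms.

Trace tables use a long TSV layout (molecule_id, frame, donor, acceptor);
histograms are two-column CSV (bin_left, weight).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stimfret.traces import FretHistogram, MoleculeTrace

__all__ = ["write_traces_tsv", "read_traces_tsv", "write_histogram_csv"]


def write_traces_tsv(traces, path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": np.arange(t.n_frames),
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path, frame_interval: float = 0.1) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            MoleculeTrace(
                molecule_id=int(mid),
                donor=grp["donor"].to_numpy(float),
                acceptor=grp["acceptor"].to_numpy(float),
                frame_interval=frame_interval,
            )
        )
    return out


def write_histogram_csv(hist: FretHistogram, path) -> None:
    pd.DataFrame(
        {"bin_left": hist.edges[:-1], "weight": hist.weights}
    ).to_csv(path, index=False)
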