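"""Per-molecule FRET trace correction, selection and histograms.

The pipeline for a background-corrected two-channel trace is:

1. subtract donor→acceptor spectral leakage (≈7% of the donor signal),
2. detect photobleaching changepoints in both channels and classify their
   step counts,
3. estimate the per-molecule detection-efficiency factor γ from the
   intensity changes across the acceptor bleach,
4. compute the FRET efficiency series E = I_A / (I_A + γ·I_D) over the
   frames where both dyes are active,
5. apply the five-point selection filter (SNR, bleach order and step
   counts, γ range, donor/acceptor anticorrelation),
6. build per-trace and ensemble FRET histograms (30 bins over [−0.25, 1.25]).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MoleculeTrace",
    "SelectionCriteria",
    "FretHistogram",
    "BleachEvent",
    "subtract_leakage",
    "detect_bleach_steps",
    "estimate_gamma",
    "compute_fret",
    "apply_selection",
    "build_histograms",
    "process_trace",
]

HISTOGRAM_RANGE = (-0.25, 1.25)
HISTOGRAM_BINS = 30


@dataclass
class MoleculeTrace:
    """One molecule's donor/acceptor intensity time series (counts/frame)."""

    molecule_id: int
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float = 0.1
    acceptor_bleach_frame: int | None = None
    donor_bleach_frame: int | None = None
    gamma: float | None = None
    fret: np.ndarray | None = None  # E over pre-acceptor-bleach frames
    qc_pass: bool | None = None
    qc_reason: str | None = None
    acceptor_event: "BleachEvent | None" = None
    donor_event: "BleachEvent | None" = None  # post-acceptor-bleach segment
    donor_event_full: "BleachEvent | None" = None  # full-trace donor fit

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor series must have equal length")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.donor)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the five-point trace selection filter."""

    snr_min: float = 5.0
    gamma_range: tuple = (0.5, 2.5)
    correlation_max: float = -0.1
    min_prebleach_frames: int = 10

    def __post_init__(self) -> None:
        if not self.snr_min > 0:
            raise ValueError("snr_min must be positive")
        if not self.gamma_range[0] < self.gamma_range[1]:
            raise ValueError("gamma_range must be ordered")


# ---------------------------------------------------------------------------
# leakage


def subtract_leakage(trace: MoleculeTrace, leakage: float = 0.07) -> MoleculeTrace:
    """Remove donor bleed-through from the acceptor channel.

    ``I_A ← I_A − leakage·I_D`` per frame; the default 7% is the measured
    spectral leakage of the donor emission into the acceptor detection band.
    """
    if not 0.0 <= leakage <= 0.5:
        raise ValueError(f"leakage fraction must lie in [0, 0.5], got {leakage}")
    return replace(trace, acceptor=trace.acceptor - leakage * trace.donor)


# ---------------------------------------------------------------------------
# changepoint / bleach-step detection


def _segment_costs(y: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of fitting a constant to y[i:j+1] (upper triangle)."""
    t = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y**2)])
    i = np.arange(t)[:, None]
    j = np.arange(t)[None, :]
    n = (j - i + 1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = (c2[j + 1] - c2[i]) - (c1[j + 1] - c1[i]) ** 2 / n
    sse[n <= 0] = np.inf
    return sse


def _best_piecewise_constant(y: np.ndarray, n_steps: int):
    """Optimal piecewise-constant fit with exactly ``n_steps`` changepoints.

    Returns ``(sse, changepoints, levels)`` where each changepoint index ``c``
    means the new plateau starts at frame ``c``.  Dynamic programming over
    the full segment-cost matrix; exact, not greedy.
    """
    t = len(y)
    cost = _segment_costs(y)
    if n_steps == 0:
        return float(cost[0, t - 1]), [], [float(np.mean(y))]
    # dp[k][j] = best SSE for y[0:j+1] using k changepoints
    dp = cost[0, :].copy()
    arg: list[np.ndarray] = []
    for _ in range(n_steps):
        # candidate[j, c-1] = dp_prev[c-1] + cost[c, j] for 1 <= c <= j
        cand = dp[None, : t - 1] + cost[1:, :].T
        cand = np.where(np.arange(1, t)[None, :] <= np.arange(t)[:, None], cand, np.inf)
        arg.append(np.argmin(cand, axis=1) + 1)
        dp = np.min(cand, axis=1)
    sse = float(dp[t - 1])
    cps = []
    j = t - 1
    for k in range(n_steps - 1, -1, -1):
        c = int(arg[k][j])
        cps.append(c)
        j = c - 1
    cps = cps[::-1]
    bounds = [0, *cps, t]
    levels = [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    return sse, cps, levels


def _step_bic(sse: float, t: int, n_steps: int, floor: float = 1e-12) -> float:
    # plateau levels, σ, and changepoint locations; each changepoint carries
    # an inflated cost (3 ln t) because its location is itself optimized
    # over ~t positions — the plain BIC count overfits pure-noise plateaus
    k = 2 + 3 * n_steps
    return t * np.log(max(sse, floor) / t) + k * np.log(t)


@dataclass(frozen=True)
class BleachEvent:
    """Changepoint analysis of one channel."""

    n_steps: int  # BIC-selected number of changepoints (0, 1 or 2)
    changepoints: tuple  # frame indices where a new plateau starts
    levels: tuple  # plateau means
    bleach_frame: int | None  # first frame of the terminal dark plateau
    single_step: bool


def detect_bleach_steps(
    y: np.ndarray, max_steps: int = 2, dark_fraction: float = 0.25
) -> BleachEvent:
    """Classify the photobleaching behaviour of one intensity channel.

    Fits optimal piecewise-constant models with 0..``max_steps`` downward
    changepoints and selects by BIC.  A bleach event is the changepoint
    entering the terminal plateau, provided that plateau is dark (below
    ``dark_fraction`` of the brightest plateau).  ``single_step`` is true
    when the one-step model wins and its step is a bleach.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("trace too short to classify bleaching (<10 frames)")
    fits = {}
    for k in range(max_steps + 1):
        sse, cps, levels = _best_piecewise_constant(y, k)
        fits[k] = (_step_bic(sse, len(y), k), cps, levels)
    n_model = min(fits, key=lambda k: (fits[k][0], k))
    _, cps, levels = fits[n_model]
    # count only steps whose amplitude clears the local noise floor (shot
    # noise scales with the level, so the noise is estimated per segment);
    # tiny fitted plateaus on pure noise are not bleaching structure
    bounds = [0, *cps, len(y)]
    seg_noise = [
        _noise_sd(y[a:b]) if b - a >= 6 else np.inf
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    finite = [s for s in seg_noise if np.isfinite(s)]
    fallback = max(finite) if finite else _noise_sd(y)
    sig = []
    for j, c in enumerate(cps):
        # the larger adjacent estimate guards against short segments whose
        # own noise estimate collapses by chance (shot noise scales with
        # the level, so the dark tail must not set the scale either)
        local = [s for s in (seg_noise[j], seg_noise[j + 1]) if np.isfinite(s)]
        local = max(local) if local else fallback
        if abs(levels[j + 1] - levels[j]) > 4 * max(local, 1e-12):
            sig.append((c, levels[j], levels[j + 1]))
    n_steps = len(sig)
    bleach_frame = None
    if n_steps >= 1:
        peak = max(levels)
        if peak > 0 and sig[-1][2] < dark_fraction * peak:
            bleach_frame = sig[-1][0]
    return BleachEvent(
        n_steps=n_steps,
        changepoints=tuple(c for c, *_ in sig),
        levels=tuple(levels),
        bleach_frame=bleach_frame,
        single_step=(n_steps == 1 and bleach_frame is not None),
    )


def _noise_sd(y: np.ndarray) -> float:
    """Per-frame noise SD from the median absolute first difference."""
    d = np.diff(np.asarray(y, float))
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def dark_onset(y: np.ndarray, min_dark_frames: int = 5) -> int | None:
    """First frame of a channel's terminal dark plateau, or None.

    The channel is considered bleached when its trailing level is dark
    relative to the active signal; the onset is the frame after the last
    excursion above a threshold placed between dark and the active range.
    Robust to FRET-state fluctuations, which stay above the threshold.
    """
    y = np.asarray(y, float)
    if len(y) < 2 * min_dark_frames:
        return None
    dark = float(np.median(y[-min_dark_frames:]))
    # active level from a smoothed trace, so brief active periods at the
    # start of long recordings still register
    from scipy.ndimage import uniform_filter1d

    smooth = uniform_filter1d(y, size=min(10, len(y)), mode="nearest")
    peak = float(smooth.max())
    noise = _noise_sd(y)
    if peak - dark < max(6 * noise, 1e-12):  # never goes dark
        return None
    if dark > 0.25 * peak:
        return None
    thr = dark + max(4 * noise, 0.2 * (peak - dark))
    above = np.flatnonzero(y > thr)
    if len(above) == 0:
        return None
    onset = int(above[-1]) + 1
    if len(y) - onset < min_dark_frames:
        return None
    return onset


def uncompensated_acceptor_drops(
    acceptor: np.ndarray,
    donor: np.ndarray,
    stop: int,
    gamma: float = 1.0,
    max_steps: int = 2,
) -> list[int]:
    """Acceptor losses not explained by FRET before frame ``stop``.

    A genuine FRET transition redistributes intensity between the channels
    but conserves the γ-corrected total S = I_A + γ·I_D, so S is constant
    over the active region whatever the state dynamics.  An extra
    photobleaching step (a second acceptor in an aggregate) removes its
    contribution from S permanently.  Significant down-steps in S, found by
    the changepoint/BIC fit, are therefore extra bleach steps; their frames
    are returned.
    """
    acceptor = np.asarray(acceptor, float)[:stop]
    donor = np.asarray(donor, float)[:stop]
    if stop < 20:
        return []
    s = acceptor + gamma * donor
    scale = 1
    if len(s) > 400:  # decimate long traces; steps survive averaging
        scale = int(np.ceil(len(s) / 400))
        n_keep = (len(s) // scale) * scale
        s = s[:n_keep].reshape(-1, scale).mean(axis=1)
    fits = {}
    for k in range(max_steps + 1):
        sse, cps, levels = _best_piecewise_constant(s, k)
        fits[k] = (_step_bic(sse, len(s), k), cps, levels)
    n_model = min(fits, key=lambda k: (fits[k][0], k))
    _, cps, levels = fits[n_model]
    bounds = [0, *cps, len(s)]
    seg_noise = [
        _noise_sd(s[a:b]) if b - a >= 6 else np.inf
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    finite = [x for x in seg_noise if np.isfinite(x)]
    fallback = max(finite) if finite else _noise_sd(s)
    drops = []
    for j, c in enumerate(cps):
        local = [x for x in (seg_noise[j], seg_noise[j + 1]) if np.isfinite(x)]
        local = max(local) if local else fallback
        if levels[j + 1] - levels[j] < -4 * max(local, 1e-12):
            drops.append(int(c * scale))
    return drops


def _acceptor_event(trace: MoleculeTrace, f_a: int, gamma: float) -> BleachEvent:
    drops = uncompensated_acceptor_drops(
        trace.acceptor, trace.donor, max(f_a - 5, 0), gamma=gamma
    )
    pre = float(np.mean(trace.acceptor[max(0, f_a - 10) : f_a])) if f_a else 0.0
    post = float(np.mean(trace.acceptor[f_a : f_a + 10]))
    return BleachEvent(
        n_steps=1 + len(drops),
        changepoints=tuple([*drops, f_a]),
        levels=(pre, post),
        bleach_frame=f_a,
        single_step=len(drops) == 0,
    )


def detect_trace_bleaching(trace: MoleculeTrace, gamma: float = 1.0) -> MoleculeTrace:
    """Locate bleach events and classify their step structure.

    Bleach frames are the dark onsets of each channel, which tolerate
    FRET-state dynamics in the active region.  The acceptor bleach counts
    as single-step when no uncompensated acceptor drop precedes it (the
    test sharpens once the per-molecule γ is known); the donor is analyzed
    from the acceptor bleach onward (where it holds the full excitation
    budget and is dynamics-free) with the changepoint/BIC step classifier.
    """
    if trace.n_frames < 10:
        raise ValueError("trace too short to classify bleaching (<10 frames)")
    f_a = dark_onset(trace.acceptor)
    f_d_full = dark_onset(trace.donor)

    acc_event = _acceptor_event(trace, f_a, gamma) if f_a is not None else None

    donor_frame = f_d_full
    don = None
    # start a few frames past the acceptor onset: the onset can sit a frame
    # or two early when the last active dwell is a low-FRET state
    start = f_a + 3 if f_a is not None else 0
    if trace.n_frames - start >= 10:
        try:
            don = detect_bleach_steps(trace.donor[start:])
        except ValueError:
            don = None
        if don is not None and don.bleach_frame is not None:
            donor_frame = start + don.bleach_frame
    return replace(
        trace,
        acceptor_bleach_frame=f_a,
        donor_bleach_frame=donor_frame,
        acceptor_event=acc_event,
        donor_event=don,
        donor_event_full=BleachEvent(
            n_steps=0 if f_d_full is None else 1,
            changepoints=() if f_d_full is None else (f_d_full,),
            levels=(),
            bleach_frame=f_d_full,
            single_step=f_d_full is not None,
        ),
    )


# ---------------------------------------------------------------------------
# gamma


def estimate_gamma(trace: MoleculeTrace, window: int = 10) -> float:
    """Per-molecule γ from intensity changes across the acceptor bleach.

    γ = ΔI_A / ΔI_D with ΔI_A = mean I_A(pre) − mean I_A(post) and
    ΔI_D = mean I_D(post) − mean I_D(pre), in windows of ``window`` frames on
    either side of the acceptor bleach, excluding the changepoint frame.
    Raises ``ValueError`` when no usable bleach or when ΔI_D ≤ 0.
    """
    f = trace.acceptor_bleach_frame
    if f is None:
        raise ValueError("no acceptor bleach frame; cannot estimate gamma")
    end = trace.donor_bleach_frame if trace.donor_bleach_frame is not None else trace.n_frames
    guard = 3  # frames skipped around the changepoint itself
    pre = slice(max(0, f - guard - window), max(0, f - guard))
    post = slice(f + guard, min(end, f + guard + window))
    if (pre.stop - pre.start) < 5 or (post.stop - post.start) < 5:
        raise ValueError("need >=5 frames on each side of the acceptor bleach")
    d_ia = float(np.mean(trace.acceptor[pre]) - np.mean(trace.acceptor[post]))
    d_id = float(np.mean(trace.donor[post]) - np.mean(trace.donor[pre]))
    if d_id <= 0:
        raise ValueError("donor does not recover at acceptor bleach; gamma undefined")
    gamma = d_ia / d_id
    if gamma <= 0:
        raise ValueError("non-positive gamma estimate")
    return gamma


# ---------------------------------------------------------------------------
# FRET


def compute_fret(trace: MoleculeTrace) -> MoleculeTrace:
    """Attach the FRET efficiency series E = I_A / (I_A + γ·I_D).

    E is defined only over frames before the acceptor bleach; frames where
    the total corrected intensity is non-positive are masked (NaN).  Values
    outside the histogram range are retained.
    """
    if trace.gamma is None:
        raise ValueError("gamma must be set before computing FRET")
    stop = (
        trace.acceptor_bleach_frame
        if trace.acceptor_bleach_frame is not None
        else trace.n_frames
    )
    i_a = trace.acceptor[:stop]
    i_d = trace.donor[:stop]
    total = i_a + trace.gamma * i_d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, i_a / total, np.nan)
    return replace(trace, fret=e)


# ---------------------------------------------------------------------------
# selection filter


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the median absolute first difference (transition-robust)."""
    d = np.diff(y)
    if len(d) == 0:
        return np.inf
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def trace_snr(trace: MoleculeTrace) -> float:
    """Mean γ-corrected total intensity over noise SD, pre-bleach frames."""
    stop = (
        trace.acceptor_bleach_frame
        if trace.acceptor_bleach_frame is not None
        else trace.n_frames
    )
    gamma = trace.gamma if trace.gamma is not None else 1.0
    total = trace.acceptor[:stop] + gamma * trace.donor[:stop]
    sd = _robust_noise_sd(total)
    if not np.isfinite(sd) or sd == 0:
        return np.inf
    return float(np.mean(total) / sd)


def _prebleach_correlation(trace: MoleculeTrace) -> float:
    stop = (
        trace.acceptor_bleach_frame
        if trace.acceptor_bleach_frame is not None
        else trace.n_frames
    )
    # guard margin: a dark-onset estimate that sits a frame or two late
    # would otherwise let the bleach transition itself (donor up, acceptor
    # down) masquerade as anticorrelated fluctuation
    stop = max(stop - 3, 0)
    d = trace.donor[:stop]
    a = trace.acceptor[:stop]
    if len(d) < 3 or np.std(d) == 0 or np.std(a) == 0:
        return 0.0
    return float(np.corrcoef(d - d.mean(), a - a.mean())[0, 1])


def process_trace(
    trace: MoleculeTrace,
    leakage: float = 0.07,
    gamma_window: int = 10,
) -> MoleculeTrace:
    """Leakage correction, bleach detection, γ and E for one trace.

    Failures (no acceptor bleach, undefined γ, short trace) are recorded on
    the returned trace rather than raised, so the selection filter can
    assign reason codes.
    """
    t = subtract_leakage(trace, leakage)
    try:
        t = detect_trace_bleaching(t)
    except ValueError:
        t.qc_reason = "too_short"
        return t
    try:
        t = replace(t, gamma=estimate_gamma(t, window=gamma_window))
    except ValueError:
        pass
    if t.gamma is not None:
        # refine the step-count test with the molecule's own γ
        if t.acceptor_bleach_frame is not None:
            t = replace(
                t, acceptor_event=_acceptor_event(t, t.acceptor_bleach_frame, t.gamma)
            )
        t = compute_fret(t)
    return t


def apply_selection(
    traces,
    criteria: SelectionCriteria = SelectionCriteria(),
):
    """Run the five-point selection filter over processed traces.

    Criteria, in order: (1) SNR ≥ ``snr_min``; (2) the acceptor bleached in
    a single step before the donor; (3) γ within ``gamma_range``;
    (4) pre-bleach donor/acceptor fluctuations negatively correlated;
    (5) any observed donor bleach occurred in a single step.  Each rejected
    molecule carries the code of the first criterion it failed.

    Returns ``(accepted, reasons)`` with ``reasons`` mapping molecule id to
    the acceptance/rejection code.
    """
    accepted = []
    reasons: dict[int, str] = {}
    for t in traces:
        code = _selection_code(t, criteria)
        reasons[t.molecule_id] = code
        t.qc_pass = code == "accepted"
        t.qc_reason = code
        if t.qc_pass:
            accepted.append(t)
    return accepted, reasons


def _selection_code(t: MoleculeTrace, criteria: SelectionCriteria) -> str:
    if t.qc_reason == "too_short":
        return "too_short"
    acc_event = t.acceptor_event
    don_full = t.donor_event_full
    don_event = t.donor_event

    # (1) signal-to-noise
    if trace_snr(t) < criteria.snr_min:
        return "snr"
    # (2) single-step acceptor bleach, before the donor.  A donor that went
    # dark while the acceptor was still active bleached first, whether or
    # not the acceptor bleach itself fell inside the recording.
    donor_dark = don_full.bleach_frame if don_full is not None else None
    if donor_dark is not None and (
        t.acceptor_bleach_frame is None or donor_dark < t.acceptor_bleach_frame
    ):
        return "bleach_order"
    if acc_event is None or t.acceptor_bleach_frame is None:
        return "no_acceptor_bleach"
    if t.acceptor_bleach_frame < criteria.min_prebleach_frames:
        return "bleach_order"
    if acc_event.n_steps != 1 or not acc_event.single_step:
        return "acceptor_multistep"
    f = t.acceptor_bleach_frame
    pre_w = t.donor[max(0, f - 10) : f]
    post_w = t.donor[f + 1 : f + 11]
    if len(pre_w) == 0 or len(post_w) == 0 or np.mean(post_w) <= np.mean(pre_w):
        return "bleach_order"  # donor does not recover at the acceptor bleach
    # (3) gamma window
    if t.gamma is None:
        return "gamma_undefined"
    if not criteria.gamma_range[0] <= t.gamma <= criteria.gamma_range[1]:
        return "gamma_range"
    # (4) anticorrelation of spontaneous fluctuations
    if _prebleach_correlation(t) >= criteria.correlation_max:
        return "correlation"
    # (5) single-step donor bleach, when observed
    if don_event is not None and don_event.bleach_frame is not None:
        if don_event.n_steps != 1:
            return "donor_multistep"
    return "accepted"


# ---------------------------------------------------------------------------
# histograms


@dataclass(frozen=True)
class FretHistogram:
    """Normalized FRET histogram: 30 bins over [−0.25, 1.25]."""

    edges: np.ndarray
    weights: np.ndarray
    n_molecules: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def peak(self) -> float:
        """Center of the modal bin."""
        return float(self.bin_centers[np.argmax(self.weights)])


def _hist_edges() -> np.ndarray:
    return np.linspace(HISTOGRAM_RANGE[0], HISTOGRAM_RANGE[1], HISTOGRAM_BINS + 1)


def trace_histogram(e_series: np.ndarray) -> np.ndarray:
    """Per-trace normalized histogram; out-of-range values go to end bins."""
    e = np.asarray(e_series, dtype=float)
    e = e[np.isfinite(e)]
    if len(e) == 0:
        raise ValueError("empty FRET series")
    lo, hi = HISTOGRAM_RANGE
    width = (hi - lo) / HISTOGRAM_BINS
    clipped = np.clip(e, lo, hi - 0.5 * width)
    counts, _ = np.histogram(clipped, bins=_hist_edges())
    return counts / counts.sum()


def build_histograms(accepted):
    """Per-trace and ensemble FRET histograms for selected molecules.

    The ensemble histogram is the mean of the per-trace normalized
    histograms, so each molecule carries equal weight regardless of trace
    length; both levels sum to one.
    """
    per_trace = {}
    for t in accepted:
        if t.fret is None:
            continue
        e = t.fret[np.isfinite(t.fret)]
        if len(e) == 0:
            continue
        per_trace[t.molecule_id] = trace_histogram(t.fret)
    if not per_trace:
        return {}, FretHistogram(_hist_edges(), np.zeros(HISTOGRAM_BINS), 0)
    stack = np.array(list(per_trace.values()))
    ensemble = FretHistogram(
        edges=_hist_edges(),
        weights=stack.mean(axis=0),
        n_molecules=len(per_trace),
    )
    per = {
        mid: FretHistogram(_hist_edges(), w, 1) for mid, w in per_trace.items()
    }
    return per, ensemble
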