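"""Per-trace HMM kinetics, ensemble state clustering, dwells and TDPs.

Each selected molecule's FRET series (the stretch where both dyes are
active) is fit with Gaussian-emission hidden Markov models of 1..max_states
states; the Bayesian information criterion picks the state count.  To
compare FRET levels across molecules, all fitted state means in the
ensemble are clustered by 1-D k-means; dwell times between cluster-level
transitions give rate constants, and transition density plots summarize the
ensemble's kinetic connectivity with one point per molecule per kind of
transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import chi2

__all__ = [
    "HmmFit",
    "ClusterModel",
    "DwellSet",
    "TransitionDensity",
    "fit_hmm_bic",
    "cluster_states",
    "dwell_analysis",
    "transition_density",
]

TDP_RANGE = (-0.25, 1.25)
TDP_GRID = 50
TDP_KERNEL_SD = 2.0  # grid cells


@dataclass
class HmmFit:
    """BIC-selected Gaussian HMM for one molecule's FRET series."""

    molecule_id: int
    n_states: int
    means: np.ndarray  # state FRET means
    sds: np.ndarray
    transmat: np.ndarray  # per-frame transition probabilities
    path: np.ndarray  # most-likely state index per frame (Viterbi)
    log_likelihood: float
    bic: float
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.path) and self.transmat.size:
            rows = self.transmat.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-6):
                raise ValueError("transition matrix rows must sum to 1")


def _hmm_n_parameters(n: int) -> int:
    # n(n−1) transition + (n−1) initial + n means + n variances
    return n * n + 2 * n - 1


def _fit_single_gaussian(e: np.ndarray, molecule_id: int) -> HmmFit:
    mu, sd = float(np.mean(e)), float(max(np.std(e), 1e-6))
    ll = float(np.sum(-0.5 * np.log(2 * np.pi * sd**2) - (e - mu) ** 2 / (2 * sd**2)))
    bic = -2 * ll + _hmm_n_parameters(1) * np.log(len(e))
    return HmmFit(
        molecule_id=molecule_id, n_states=1, means=np.array([mu]),
        sds=np.array([sd]), transmat=np.ones((1, 1)),
        path=np.zeros(len(e), dtype=int), log_likelihood=ll, bic=bic,
    )


def fit_hmm_bic(
    e_series: np.ndarray,
    max_states: int = 5,
    n_restarts: int = 5,
    molecule_id: int = -1,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> HmmFit:
    """Fit Gaussian HMMs with 1..max_states states and select by BIC.

    Each state count is fit by EM with ``n_restarts`` seeded restarts and
    quantile-based mean initialization; BIC = −2 logL + p ln(T) with
    p = n² + 2n − 1 free parameters.  Ties favour fewer states.  The
    most-likely path is the Viterbi decoding of the winning model.
    """
    import logging

    from hmmlearn.hmm import GaussianHMM

    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    e = np.asarray(e_series, dtype=float)
    e = e[np.isfinite(e)]
    if len(e) < 10:
        raise ValueError("FRET series too short for HMM fitting (<10 frames)")
    x = e.reshape(-1, 1)
    t = len(e)

    best: HmmFit | None = None
    for n in range(1, max_states + 1):
        if n == 1:
            fit = _fit_single_gaussian(e, molecule_id)
        elif n > len(np.unique(e)):
            continue
        else:
            fit = None
            for r in range(n_restarts):
                rng = np.random.default_rng((seed, n, r))
                model = GaussianHMM(
                    n_components=n, covariance_type="diag", n_iter=max_iter,
                    tol=tol, init_params="stc", random_state=int(rng.integers(2**31)),
                )
                # quantile-spread means, jittered across restarts
                q = np.quantile(e, (np.arange(n) + 0.5) / n)
                model.means_ = (q + rng.normal(0, 0.02 * (r > 0), n)).reshape(-1, 1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        model.fit(x)
                        ll = float(model.score(x))
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                cand_bic = -2 * ll + _hmm_n_parameters(n) * np.log(t)
                if fit is None or cand_bic < fit.bic:
                    path = model.predict(x)
                    fit = HmmFit(
                        molecule_id=molecule_id, n_states=n,
                        means=model.means_.ravel().copy(),
                        sds=np.sqrt(model.covars_.ravel().copy()),
                        transmat=model.transmat_.copy(), path=path,
                        log_likelihood=ll, bic=cand_bic,
                        converged=bool(model.monitor_.converged),
                    )
            if fit is None:
                continue
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# ensemble clustering


@dataclass
class ClusterModel:
    """k-means clustering of all HMM state means in an ensemble."""

    k: int
    centers: np.ndarray  # cluster centers in FRET units, ascending
    assignments: dict  # (molecule_id, state_index) → cluster id
    representative_levels: np.ndarray  # modal-bin center of each cluster's E points
    point_counts: np.ndarray  # FRET measurement points per cluster
    predominant: int  # cluster id with the most points


def cluster_states(fits, fret_series: dict, k: int, seed: int = 0,
                   n_init: int = 10, bin_width: float = 0.05) -> ClusterModel:
    """Cluster HMM state means across molecules with 1-D k-means.

    ``fret_series`` maps molecule id to its E series (same frames the HMM
    was fit on).  Every state mean in the ensemble enters unweighted.  Each
    cluster's representative FRET level is the center of the modal
    ``bin_width``-wide histogram bin of all E points decoded into that
    cluster's states; the predominant cluster holds the most points.
    """
    from sklearn.cluster import KMeans

    state_keys = []
    state_means = []
    for f in fits:
        for s in range(f.n_states):
            state_keys.append((f.molecule_id, s))
            state_means.append(f.means[s])
    state_means = np.asarray(state_means)
    if len(np.unique(state_means)) < k:
        raise ValueError(
            f"only {len(np.unique(state_means))} distinct state means in the "
            f"ensemble; choose k smaller than or equal to that"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(state_means.reshape(-1, 1))
    # relabel clusters in ascending FRET order
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers = km.cluster_centers_.ravel()[order]

    assignments = {key: int(lab) for key, lab in zip(state_keys, labels)}
    lo, hi = TDP_RANGE
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rep = np.full(k, np.nan)
    counts = np.zeros(k, dtype=int)
    cluster_points: dict[int, list] = {c: [] for c in range(k)}
    for f in fits:
        e = np.asarray(fret_series[f.molecule_id], dtype=float)
        e = e[np.isfinite(e)]  # the HMM was fit on the finite frames
        m = min(len(e), len(f.path))
        for frame_state, ei in zip(f.path[:m], e[:m]):
            cluster_points[assignments[(f.molecule_id, int(frame_state))]].append(ei)
    for c in range(k):
        pts = np.asarray(cluster_points[c])
        counts[c] = len(pts)
        if len(pts):
            h, _ = np.histogram(np.clip(pts, lo, hi - bin_width / 2), bins=edges)
            rep[c] = edges[np.argmax(h)] + bin_width / 2
    return ClusterModel(
        k=k, centers=centers, assignments=assignments,
        representative_levels=rep, point_counts=counts,
        predominant=int(np.argmax(counts)),
    )


def cluster_path(fit: HmmFit, clusters: ClusterModel) -> np.ndarray:
    """Map a molecule's decoded state path to cluster ids."""
    lut = np.array(
        [clusters.assignments[(fit.molecule_id, s)] for s in range(fit.n_states)]
    )
    return lut[fit.path]


# ---------------------------------------------------------------------------
# dwell times


@dataclass
class DwellSet:
    """Dwell durations grouped by (from-cluster, to-cluster) transition."""

    dwells: dict  # (from, to) → np.ndarray of durations (s)
    rates: dict  # (from, to) → (rate /s, ci_low, ci_high)
    n_traces_used: int


def _exponential_rate_ci(durations: np.ndarray, alpha: float = 0.05):
    """MLE rate with exact chi-square confidence interval."""
    n = len(durations)
    total = durations.sum()
    rate = n / total
    lo = chi2.ppf(alpha / 2, 2 * n) / (2 * total)
    hi = chi2.ppf(1 - alpha / 2, 2 * n) / (2 * total)
    return float(rate), float(lo), float(hi)


def dwell_analysis(fits, clusters: ClusterModel, frame_interval: float = 0.1) -> DwellSet:
    """Cluster-level dwell times and exponential rate estimates.

    Consecutive same-cluster runs become dwells (run length × frame
    interval); the first and last dwell of each trace are censored by the
    observation window and are discarded, which excludes traces with fewer
    than two cluster transitions.  Rates are 1/mean(dwell) (exponential
    MLE) with exact chi-square CIs.  No correction is applied for frame
    discretization, which shortens apparent dwells by up to one frame.
    """
    dwells: dict[tuple, list] = {}
    n_used = 0
    for f in fits:
        cp = cluster_path(f, clusters)
        change = np.flatnonzero(np.diff(cp)) + 1
        if len(change) < 2:  # fewer than two transitions → no interior dwell
            continue
        n_used += 1
        bounds = np.concatenate([[0], change, [len(cp)]])
        for i in range(1, len(bounds) - 2):
            start, stop = bounds[i], bounds[i + 1]
            key = (int(cp[start]), int(cp[stop]))
            dwells.setdefault(key, []).append((stop - start) * frame_interval)
    out = {k: np.asarray(v) for k, v in dwells.items()}
    rates = {k: _exponential_rate_ci(v) for k, v in out.items() if len(v) > 0}
    return DwellSet(dwells=out, rates=rates, n_traces_used=n_used)


# ---------------------------------------------------------------------------
# transition density plots


@dataclass
class TransitionDensity:
    """Smoothed 2-D map of (E before, E after) over ensemble transitions."""

    grid: np.ndarray  # (50, 50) density, rows = E_post, cols = E_pre
    edges: np.ndarray
    n_points: int  # deduplicated transition points
    n_molecules: int


def transition_density(
    fits,
    clusters: ClusterModel,
    dedupe: str = "first",
    use_cluster_levels: bool = False,
) -> TransitionDensity:
    """Build the transition density plot for an ensemble.

    Each state-path transition contributes the point (E_pre, E_post) given
    by the fitted state means flanking it (or the cluster representative
    levels when ``use_cluster_levels``).  To stop busy molecules dominating,
    points are deduplicated to one per molecule per ordered cluster pair:
    ``dedupe='first'`` keeps the first occurrence, ``'mean'`` averages the
    occurrences.  Points are binned on a 50×50 grid over [−0.25, 1.25]² and
    convolved with a normalized Gaussian kernel (SD two cells, truncated at
    4 SD), so the total density equals the point count up to edge loss.
    """
    if dedupe not in ("first", "mean"):
        raise ValueError("dedupe must be 'first' or 'mean'")
    lo, hi = TDP_RANGE
    edges = np.linspace(lo, hi, TDP_GRID + 1)
    points = []
    n_mol = 0
    for f in fits:
        cp = cluster_path(f, clusters)
        change = np.flatnonzero(np.diff(cp)) + 1
        if len(change) == 0:
            continue
        n_mol += 1
        seen: dict[tuple, list] = {}
        for c in change:
            kind = (int(cp[c - 1]), int(cp[c]))
            if use_cluster_levels:
                pt = (
                    clusters.representative_levels[kind[0]],
                    clusters.representative_levels[kind[1]],
                )
            else:
                pt = (f.means[f.path[c - 1]], f.means[f.path[c]])
            seen.setdefault(kind, []).append(pt)
        for kind, pts in seen.items():
            if dedupe == "first":
                points.append(pts[0])
            else:
                points.append(tuple(np.mean(pts, axis=0)))
    grid = np.zeros((TDP_GRID, TDP_GRID))
    if points:
        pre = np.array([p[0] for p in points])
        post = np.array([p[1] for p in points])
        h, _, _ = np.histogram2d(post, pre, bins=[edges, edges])
        grid = ndimage.gaussian_filter(h, sigma=TDP_KERNEL_SD, mode="constant",
                                       truncate=4.0)
    return TransitionDensity(grid=grid, edges=edges, n_points=len(points),
                             n_molecules=n_mol)
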