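"""Two-channel movie processing: registration, spots, traces, background.

The raw data are side-by-side donor/acceptor image stacks.  A pre-recorded
bead image pair yields an affine registration between the halves; molecules
are detected as strict local maxima in a five-pixel-diameter neighborhood,
colocalized by mutual nearest neighbors through the registration, and their
per-frame intensities summed over a small square aperture.  Background is
the median pixel value in a 35-px-diameter annulus around each molecule
(excluding the aperture), scaled by the aperture pixel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from stimfret.traces import MoleculeTrace

__all__ = [
    "RegistrationMap",
    "Spot",
    "detect_spots",
    "estimate_registration",
    "match_spots",
    "extract_traces",
    "correct_background",
    "split_channels",
    "process_movie",
]

logger = logging.getLogger(__name__)

DETECTION_DIAMETER = 5  # pixels, strict-maximum neighborhood
APERTURE_SIZE = 5  # square summation aperture, pixels per side
BACKGROUND_DIAMETER = 35  # pixels, median annulus


@dataclass
class RegistrationMap:
    """Affine map from donor-half to acceptor-half pixel coordinates."""

    matrix: np.ndarray  # 2×2
    offset: np.ndarray  # (2,)
    residual_rms: float  # pixels
    warning: bool = False  # residual above 1 px

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("registration transform must be invertible")
        if not np.isfinite(self.residual_rms):
            raise ValueError("registration residual must be finite")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, float) @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "RegistrationMap":
        return cls(matrix=np.eye(2), offset=np.zeros(2), residual_rms=0.0)


@dataclass(frozen=True)
class Spot:
    x: float
    y: float
    intensity: float


def _disk_offsets(diameter: float) -> np.ndarray:
    r = diameter / 2.0
    n = int(np.floor(r))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    mask = (dx**2 + dy**2 <= r**2) & ~((dx == 0) & (dy == 0))
    return np.stack([dy[mask], dx[mask]], axis=1)


def detect_spots(image: np.ndarray, min_intensity: float,
                 diameter: float = DETECTION_DIAMETER) -> list[Spot]:
    """Strict local maxima within a ``diameter``-px disk, above threshold.

    A pixel is a spot iff it exceeds ``min_intensity`` and is at least as
    bright as every other pixel in the disk centered on it; among equal-
    valued neighbors the lexicographically smallest (row, col) wins.
    """
    image = np.asarray(image, dtype=float)
    offsets = _disk_offsets(diameter)
    footprint = np.zeros(
        (int(np.floor(diameter / 2)) * 2 + 1,) * 2, dtype=bool
    )
    c = footprint.shape[0] // 2
    footprint[offsets[:, 0] + c, offsets[:, 1] + c] = True
    neigh_max = ndimage.maximum_filter(image, footprint=footprint, mode="constant",
                                       cval=-np.inf)
    candidates = np.argwhere((image >= neigh_max) & (image > min_intensity))
    spots = []
    h, w = image.shape
    for y, x in candidates:
        ny = offsets[:, 0] + y
        nx = offsets[:, 1] + x
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        vals = image[ny[ok], nx[ok]]
        ties = vals == image[y, x]
        if np.any(ties):
            # lexicographic tie-break on (row, col)
            tie_coords = np.stack([ny[ok][ties], nx[ok][ties]], axis=1)
            if any((ty, tx) < (y, x) for ty, tx in tie_coords):
                continue
        if np.any(vals > image[y, x]):
            continue
        sx, sy = _centroid_refine(image, y, x)
        spots.append(Spot(x=sx, y=sy, intensity=float(image[y, x])))
    return spots


def _centroid_refine(image: np.ndarray, y: int, x: int, half: int = 2):
    """Sub-pixel peak position from the intensity-weighted centroid."""
    h, w = image.shape
    ys = slice(max(0, y - half), min(h, y + half + 1))
    xs = slice(max(0, x - half), min(w, x + half + 1))
    patch = image[ys, xs] - image[ys, xs].min()
    total = patch.sum()
    if total <= 0:
        return float(x), float(y)
    yy, xx = np.mgrid[ys, xs]
    return float((patch * xx).sum() / total), float((patch * yy).sum() / total)


def estimate_registration(
    bead_donor: np.ndarray,
    bead_acceptor: np.ndarray,
    min_intensity: float | None = None,
    max_match_dist: float = 5.0,
) -> RegistrationMap:
    """Least-squares affine registration from a bead image pair.

    Beads are detected in both halves, matched by nearest neighbor, and a
    full 6-parameter affine transform is fit.  Requires ≥ 3 matches; a
    residual RMS above 1 px sets the warning flag.
    """
    def auto_thresh(img):
        # beads are sparse and bright: a fraction of the dynamic range
        # above the (background) median is robust, unlike SD-based rules
        return float(np.median(img) + 0.2 * (np.max(img) - np.median(img)))

    sd = detect_spots(bead_donor, min_intensity or auto_thresh(bead_donor))
    sa = detect_spots(bead_acceptor, min_intensity or auto_thresh(bead_acceptor))
    if len(sd) < 3 or len(sa) < 3:
        raise ValueError("need at least 3 beads detectable in both images")
    pd_ = np.array([[s.x, s.y] for s in sd])
    pa = np.array([[s.x, s.y] for s in sa])
    tree_a = cKDTree(pa)
    tree_d = cKDTree(pd_)
    dist, idx = tree_a.query(pd_)
    _, back = tree_d.query(pa)
    keep = (dist <= max_match_dist) & (back[idx] == np.arange(len(pd_)))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 bead matches within gate")
    src, dst = pd_[keep], pa[idx[keep]]

    def fit(s, d):
        a = np.hstack([s, np.ones((len(s), 1))])
        coef, *_ = np.linalg.lstsq(a, d, rcond=None)
        matrix, offset = coef[:2].T, coef[2]
        resid = s @ matrix.T + offset - d
        return matrix, offset, np.linalg.norm(resid, axis=1)

    matrix, offset, r = fit(src, dst)
    # one robust pass: a single wrong pairing otherwise skews the fit
    good = r <= max(3 * np.median(r), 0.5)
    if good.sum() >= 3 and good.sum() < len(r):
        matrix, offset, r = fit(src[good], dst[good])
    rms = float(np.sqrt(np.mean(r**2)))
    reg = RegistrationMap(matrix=matrix, offset=offset, residual_rms=rms,
                          warning=rms > 1.0)
    if reg.warning:
        logger.warning("registration residual RMS %.2f px exceeds 1 px", rms)
    return reg


def match_spots(
    donor_spots,
    acceptor_spots,
    registration: RegistrationMap,
    max_dist: float = 2.0,
):
    """Mutual nearest-neighbor colocalization through the registration.

    Donor spots are mapped into the acceptor frame; a pair is kept only if
    each spot is the other's nearest neighbor and they lie within
    ``max_dist`` px.  Unmatched donor spots are discarded.
    """
    if not donor_spots or not acceptor_spots:
        return []
    pd_ = registration.apply(np.array([[s.x, s.y] for s in donor_spots]))
    pa = np.array([[s.x, s.y] for s in acceptor_spots])
    tree_a = cKDTree(pa)
    tree_d = cKDTree(pd_)
    dist, nearest_a = tree_a.query(pd_)
    _, nearest_d = tree_d.query(pa)
    pairs = []
    for i, (d, j) in enumerate(zip(dist, nearest_a)):
        if d <= max_dist and nearest_d[j] == i:
            pairs.append((donor_spots[i], acceptor_spots[j]))
    return pairs


def split_channels(frame_or_stack: np.ndarray):
    """Split a side-by-side image (or stack) into donor/acceptor halves."""
    w = frame_or_stack.shape[-1]
    return frame_or_stack[..., : w // 2], frame_or_stack[..., w // 2 :]


def detection_image(stack: np.ndarray, n_frames: int = 10) -> np.ndarray:
    """Average of the first donor-excitation frames, for spot detection."""
    return np.asarray(stack[:n_frames], dtype=float).mean(axis=0)


def _aperture_slices(x: float, y: float, size: int, shape):
    half = size // 2
    y0, x0 = int(round(y)), int(round(x))
    ys = slice(y0 - half, y0 + half + 1)
    xs = slice(x0 - half, x0 + half + 1)
    if ys.start < 0 or xs.start < 0 or ys.stop > shape[0] or xs.stop > shape[1]:
        return None
    return ys, xs


def extract_traces(
    stack: np.ndarray,
    pairs,
    frame_interval: float = 0.1,
    aperture: int = APERTURE_SIZE,
):
    """Sum pixel values in a square aperture around each matched molecule.

    Returns ``(traces, kept_pairs)``; molecules whose aperture falls off
    either half-image are dropped with a log entry.
    """
    donor_stack, acceptor_stack = split_channels(np.asarray(stack, dtype=float))
    traces, kept = [], []
    for mid, (sd, sa) in enumerate(pairs):
        loc_d = _aperture_slices(sd.x, sd.y, aperture, donor_stack.shape[1:])
        loc_a = _aperture_slices(sa.x, sa.y, aperture, acceptor_stack.shape[1:])
        if loc_d is None or loc_a is None:
            logger.info("molecule %d dropped: aperture off image", mid)
            continue
        donor = donor_stack[:, loc_d[0], loc_d[1]].sum(axis=(1, 2))
        acceptor = acceptor_stack[:, loc_a[0], loc_a[1]].sum(axis=(1, 2))
        traces.append(
            MoleculeTrace(molecule_id=mid, donor=donor, acceptor=acceptor,
                          frame_interval=frame_interval)
        )
        kept.append((sd, sa))
    return traces, kept


def _annulus_mask(shape, x, y, outer_diameter, aperture):
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    r2 = (xx - round(x)) ** 2 + (yy - round(y)) ** 2
    outer = r2 <= (outer_diameter / 2.0) ** 2
    half = aperture // 2
    in_aperture = (np.abs(xx - round(x)) <= half) & (np.abs(yy - round(y)) <= half)
    return outer & ~in_aperture


def correct_background(
    traces,
    stack: np.ndarray,
    pairs,
    aperture: int = APERTURE_SIZE,
    annulus_diameter: float = BACKGROUND_DIAMETER,
):
    """Subtract the local median background from each trace, per frame.

    For each molecule, channel and frame, the median pixel value within a
    35-px-diameter region around the molecule — excluding the summation
    aperture — is scaled by the aperture pixel count and subtracted.  The
    region is clipped at image edges (logged).
    """
    donor_stack, acceptor_stack = split_channels(np.asarray(stack, dtype=float))
    n_px = aperture * aperture
    out = []
    for t, (sd, sa) in zip(traces, pairs):
        md = _annulus_mask(donor_stack.shape[1:], sd.x, sd.y, annulus_diameter, aperture)
        ma = _annulus_mask(acceptor_stack.shape[1:], sa.x, sa.y, annulus_diameter, aperture)
        for nm, m, (x, y) in (("donor", md, (sd.x, sd.y)), ("acceptor", ma, (sa.x, sa.y))):
            r = annulus_diameter / 2
            if x - r < 0 or y - r < 0 or x + r > m.shape[1] or y + r > m.shape[0]:
                logger.info("molecule %d: %s background region clipped at edge",
                            t.molecule_id, nm)
        bg_d = np.median(donor_stack[:, md], axis=1)
        bg_a = np.median(acceptor_stack[:, ma], axis=1)
        corrected = MoleculeTrace(
            molecule_id=t.molecule_id,
            donor=t.donor - n_px * bg_d,
            acceptor=t.acceptor - n_px * bg_a,
            frame_interval=t.frame_interval,
        )
        out.append(corrected)
    return out


def process_movie(
    stack: np.ndarray,
    bead_donor: np.ndarray,
    bead_acceptor: np.ndarray,
    min_intensity: float,
    frame_interval: float = 0.1,
    max_match_dist: float = 2.0,
):
    """Movie → background-corrected molecule traces, end to end.

    Returns ``(traces, registration, pairs)``.
    """
    registration = estimate_registration(bead_donor, bead_acceptor)
    donor_stack, acceptor_stack = split_channels(np.asarray(stack, dtype=float))
    det_d = detection_image(donor_stack)
    det_a = detection_image(acceptor_stack)
    spots_d = detect_spots(det_d, min_intensity)
    spots_a = detect_spots(det_a, min_intensity)
    pairs = match_spots(spots_d, spots_a, registration, max_dist=max_match_dist)
    raw, kept = extract_traces(stack, pairs, frame_interval=frame_interval)
    corrected = correct_background(raw, stack, kept)
    return corrected, registration, kept
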