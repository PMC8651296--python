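# Methods

`stimfret` implements a complete single-molecule FRET analysis chain and a
FRET-restrained coarse-grained modeling stage for the STIM1 CC1–CAD
inhibitory clamp: two-channel TIRF movies (or synthetic equivalents with
known ground truth) are turned into γ-corrected FRET trajectories, hidden
Markov kinetics and transition density plots; measured FRET peaks are
converted through Förster theory into distance restraints; and symmetric
CC1 node chains are grown around the CAD dimer by a constraint-satisfaction
chain-growth sampler. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Signal model and corrections

A surface-tethered dimer carries one donor and one acceptor dye. Under
donor excitation at 100 ms frames the detected intensities follow

    I_D = I·(1 − E),        I_A = γ·I·E   (before leakage and noise)

where `I` is the total excitation budget (photons/frame), `E` the FRET
efficiency, and γ the per-molecule ratio of acceptor to donor detection and
quantum efficiencies, modeled as an acceptor-side gain. Measured traces add,
in physical order: 7% donor→acceptor spectral leakage, background (movies),
Poisson shot noise and Gaussian read noise; a 3% common-mode excitation
fluctuation multiplies both channels (shared laser/focus noise — without it
the leakage correction itself induces a small spurious anticorrelation
between otherwise independent channels). Corrections are applied in reverse:
local median background subtraction (movies), then `I_A ← I_A − 0.07·I_D`.

FRET efficiency is `E = I_A / (I_A + γ·I_D)` over the frames where both
dyes are active. With γ as an acceptor gain, the intensity changes across
the acceptor bleach satisfy ΔI_A/ΔI_D = γ exactly in the noiseless limit;
γ is estimated per molecule from 10-frame means on either side of the
acceptor bleach, skipping 3 frames around the changepoint.

## Photobleach detection

FRET dynamics defeat a naive step fit — a fluctuating acceptor looks
multi-step. The package therefore separates two questions:

* **When did a channel bleach?** The *dark onset*: the frame after the last
  excursion above a threshold placed between the terminal dark level and
  the smoothed active peak. This tolerates state dynamics, which stay above
  the threshold.
* **Was the bleach single-step?** For the acceptor, the γ-corrected total
  `S = I_A + γ·I_D` is invariant under FRET transitions, so any significant
  down-step in S before the bleach is an *uncompensated* acceptor loss — a
  second acceptor in an aggregate. S is fit with optimal piecewise-constant
  models (dynamic programming over all changepoints, 0–2 steps) selected by
  a BIC whose per-changepoint cost is inflated to 3 ln T (the location is
  itself optimized over ~T positions; the textbook count overfits pure
  noise). A fitted step counts only if its amplitude exceeds 4× the local
  per-segment noise (median absolute first difference / √2), taking the
  larger of the two adjacent segment estimates so that short segments or
  the quiet dark tail cannot set the scale. The donor is analyzed the same
  way on the post-acceptor-bleach segment, where it is dynamics-free.

## Trace selection

Five criteria, checked in order; a rejected molecule carries the first
failed code: (1) SNR ≥ 5, with SNR = mean(I_A + γ·I_D)/noise SD from robust
first differences; (2) single-step acceptor bleach before the donor (a
donor that went dark while the acceptor was active fails here whether or
not the acceptor bleach was recorded); (3) γ ∈ [0.5, 2.5]; (4) Pearson
correlation of pre-bleach donor/acceptor fluctuations < −0.1 (a guard
margin of 3 frames before the bleach keeps the bleach transition itself out
of the statistic); (5) single-step donor bleach when observed. The −0.1
threshold needs ≥ ~270 pre-bleach frames for 95% specificity on truly
uncorrelated channels (sampling SD of r is n^−1/2), which is why the
selection-filter recovery tests simulate 800-frame recordings and score
molecules with ≥ 120 pre-bleach frames and an observable bleach cascade.

Histograms: 30 bins over [−0.25, 1.25] (width 0.05), per-trace normalized
to 1; the ensemble histogram is the equal-weight mean over molecules.
Out-of-range E values clip into the end bins.

## Kinetics

Each accepted E series is fit with Gaussian-emission HMMs of 1–5 states
(EM, 5 seeded restarts, quantile-initialized means, tolerance 1e-6); BIC
−2·lnL + p·ln T with p = n² + 2n − 1 selects the state count, ties to fewer
states; Viterbi decoding gives the path. State means across the ensemble
are clustered by 1-D k-means (k chosen per dataset from the histogram
shape); each cluster's representative level is the modal 0.05-wide bin of
its decoded E points, and the predominant cluster holds the most points.

Dwells are consecutive same-cluster runs × 0.1 s; the first and last dwell
of each trace are censored and dropped, excluding traces with fewer than
two transitions. Rates are exponential MLEs 1/mean with exact chi-square
CIs. No correction is applied for frame discretization or decoder
smoothing; both lengthen apparent dwells slightly, and two-state
simulations at 1/s recover rates ~10–15% low — within the documented 20%
envelope.

Transition density plots bin one (E_before, E_after) point per molecule
per ordered cluster pair (first occurrence; averaging the occurrences is a
config option) on a 50×50 grid over [−0.25, 1.25]², smoothed with a
normalized Gaussian kernel of 2 cells SD truncated at 4 SD, so the total
density equals the deduplicated point count up to edge loss.

## Structures, dyes and distance restraints

Coordinates are nm throughout (PDB Å converted on I/O, via biotite). The
Förster relation `R = R0·(1/E − 1)^(1/6)` with R0 = 5.1 nm (Alexa 555/647,
isotropic averaging) converts peak efficiencies to distances.

Dye centers are simulated with a geometric accessible-volume sampler: 100
positions uniform in the tether-length ball around the label site's Cα,
rejecting positions within 0.3 nm of any protein atom or 0.2 nm of the Cα.
Tether lengths (donor-like 1.35 nm, acceptor-like 1.50 nm) are calibrated
so the mean Cα→center distance of the sample cloud over exposed sites —
(3/4)·L for an unobstructed site, slightly larger near a surface because
clash rejection removes inward samples — lands near the 0.99/1.10 nm
protrusions reported for explicit-dye simulated annealing. This sampler is
the package's loosest approximation: it has no dye shape, no torsional
preferences and no energetics. Because labeling is stochastic, donor and
acceptor mean centers at a site are averaged into one *effective* center,
and model distances are measured between effective centers (or to bare CC1
nodes).

Constraint windows around `D_FRET`: the peak is uncertain by ± one
histogram bin (0.05 in E), giving `ub = R(E−0.05)` and a lower bound
`R(E+0.05)` deepened by 1 nm for CC1:CAD pairs (one unmodeled dye linker)
or 2 nm for CC1:CC1´ pairs (two), floored at zero.

The dimer is made exactly two-fold symmetric by superposing (Kabsch) chain
A's proximal-CC2 (345–378) and CC3 (408–436) Cα atoms onto chain B's and
replacing B with the transformed copy; the A→B rigid transform also
generates the partner CC1 chain during building. The apex relaxes by
rotating the distal CC2 helix (379–391) rigidly about the G379 Cα — the
tilt is parameterized by two angles (axis orientation in the plane normal
to the helix, and magnitude) — with the apex loop (392–407) re-closed by
the rigid displacement tapered linearly to zero at 407, the move mirrored
onto the partner subunit, clashing poses (< 0.2 nm non-bonded) rejected,
and Σ(model distance − D_FRET)² minimized by a coarse grid plus
Nelder–Mead. A torsion-space force-field treatment would re-close the loop
physically; the taper is a documented geometric stand-in.

## CC1 chain growth

CC1 (residues 344→233) grows as one node per residue from the CAD
N-terminus: linker steps of 0.38 nm in a random direction turning at most
90° per step; each helix (CC1α1 246–271, CC1α2 275–305, CC1α3 310–337)
placed as a single rigid straight run at 0.15 nm per residue (boundary
steps use linker spacing — the boundary spacing is a convention this
package fixes). After each placement the mirrored partner node is created
through the dimer transform and both are checked against steric exclusion
(no center within 0.25 nm of any CAD atom or non-adjacent node, own mirror
included) and every distance constraint whose sites are now all placed
(node-to-effective-center for CC1:CAD, node-to-partner-node for CC1:CC1´).

Candidate directions for a placement unit are evaluated as one vectorized
batch of 150 (equivalent to sequential rejection sampling — the first
acceptable candidate in sample order wins). On exhaustion the builder
backtracks; a unit that keeps failing unwinds progressively more
predecessors (1 + failures/8 units), because a blocked helix usually means
earlier decisions — not the immediate predecessor — were wrong. A build
fails after 250 backtracks. If no solution emerges over repeated attempts,
the constraint implicated most often in rejections (ties: the one triggered
deepest in growth) has its upper bound raised by 1 nm, repeatedly, until
building succeeds; the relaxed set is then frozen and 50 independent
seeded solutions are collected. Every accepted solution is re-validated by
an independent checker (`stimfret.validate`) that shares no geometry code
with the builder: exact spacings to 1e-9 nm, helix collinearity, bend
angles, mirror symmetry, sterics and constraint bounds.

Topology: a solution is *stacked* when the CC1α2 axis of one subunit packs
antiparallel against the partner's CC1α3´ — axis angle > 135° and minimal
helix–helix distance < 1.5 nm (both config defaults fixed a priori;
~1 nm is the node-to-node distance of touching coarse-grained helices) —
else *wedged*. Class averages are per-residue means with RMS spread;
averaged chains do not satisfy spacing invariants and carry the `average`
kind.

## Synthetic ground truth, and what passing tests show

Everything downstream is tested against generators with known truth:
exact continuous-time Markov state paths discretized by frame-start
occupancy (exact for dwells long against the 100 ms frame; no within-frame
averaging), geometric bleach frames (acceptor before donor for clean
molecules), planted defect classes (second-acceptor two-step bleaches,
donor-first bleaches, statically uncorrelated channels, aggregates with γ
outside [0.5, 2.5]), Gaussian-PSF movies with affine channel misalignment
and bead pairs, a synthetic Cα-only CAD-like dimer (parallel CC2/CC3
helix pair at 0.95 nm axis separation with an apex hairpin, residues
344–443, exactly C2-symmetric about z), a deterministic planted CC1 chain
in a stacked configuration, and constraint tables forward-simulated from
that chain through the inverse Förster relation (±0.02 jitter in E by
default).

These emulations omit real-data features on purpose: no camera EM gain,
drift, triplet blinking, spectral crosstalk beyond constant leakage, or
non-exponential photophysics; the synthetic CAD has ideal helix geometry
and no side chains; the constraint table's 36 site pairs are a synthetic
layout, not a measured one. Passing tests therefore demonstrate internal
correctness and recoverability under the stated noise model — not
instrument-specific robustness.

Two known limitations follow. First, trace extraction through a finite
5×5 aperture truncates ~7% of a σ = 1.2 px PSF; rendering conserves total
intensity to 1e-3 (tested against full half-image sums), but extracted
absolute intensities sit systematically below the rendered truth by the
truncated fraction — E, which is a ratio, is unaffected to first order.
Second, ensembles built from a constraint table forward-simulated from a
single stacked chain form one solution cloud (~1.4 nm per-residue spread)
straddling the stacked/wedged classifier boundary: the stacked fraction
lands near 30–50% depending on the jitter realization, whereas ensembles
restrained by the experimentally measured table report ~70%. The split is
a property of the constraint table, and the synthetic table is not that
table.

## Problem sizes

Default test/analysis scales, chosen as the package's standard working
sizes: 600-molecule trace sets of 800 frames (with 120 pre-bleach frames
required for selection-filter scoring, per the correlation power analysis);
100 two-state traces of 300 frames for HMM/BIC recovery; 100-sample dye
clouds per site; 50-solution builder ensembles; 4-node lattice instances
with 26 directions for the exhaustive-enumeration cross-check.
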