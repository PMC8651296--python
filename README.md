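# stimfret

Single-molecule FRET trace analysis and FRET-restrained coarse-grained
modeling of the STIM1 CC1–CAD inhibitory clamp.

In resting cells, the cytosolic coiled-coil 1 region (CC1) of STIM1 holds
the CRAC activation domain (CAD) in an inhibited conformation. smFRET
between dye pairs placed across the dimer reports the distances that
constrain this clamp: two-channel TIRF movies yield per-molecule donor and
acceptor intensities, whose ratio — after leakage and per-molecule γ
correction — gives the FRET efficiency

    E = I_A / (I_A + γ·I_D),

hidden Markov models with BIC state selection turn E trajectories into
state levels and dwell-time rate constants, and Förster theory converts
peak efficiencies into inter-dye distances

    R = R0 · (1/E − 1)^(1/6),      R0 = 5.1 nm.

Those distances, widened into bounds that absorb the dye-linker geometry,
restrain a chain-growth model of CC1: one node per residue (233–344),
grown from the CAD N-terminus under spacing, bend-angle, steric-exclusion
and distance constraints, with backtracking and bound relaxation, to
produce a 50-solution ensemble classified into *stacked* and *wedged*
CC1α2/α3 topologies.

The package is aimed at smFRET practitioners and structural modelers who
want every stage — including the photobleach-step classifier, the
selection filter, the accessible-volume dye model and the chain builder —
as tested, reusable code. Every downstream stage runs against synthetic
data with known ground truth (`stimfret.synthetic`), so nothing requires a
download or an instrument.

## Layout

| | |
|---|---|
| `src/stimfret/` | library: `synthetic`, `movies`, `traces`, `kinetics`, `forster`, `structure`, `chain`, `builder`, `validate`, `io` |
| `analysis/` | numbered drivers reproducing the full analysis, writing under `results/` |
| `docs/methods.md` | models, parameters, numerical choices, limitations |

## Worked example

Run the analysis chain end to end (about five minutes in total):

```
python analysis/01_simulate_dataset.py
python analysis/02_extract_movie_traces.py
python analysis/03_select_traces.py
python analysis/04_fit_kinetics.py
python analysis/05_model_distances.py
python analysis/06_build_cc1_ensemble.py
```

Stage 03 filters the 600 simulated molecules with the five-point selection
rule (SNR ≥ 5, single-step acceptor-before-donor bleach, γ ∈ [0.5, 2.5],
anticorrelated channels, single-step donor bleach) and prints, per planted
defect class, how many molecules carry the expected rejection code:

```
accepted 265/600 molecules
mean γ of accepted molecules: 0.98
  aggregate         : 51/60 carry the expected code (85%)
  clean             : 260/360 carry the expected code (72%)
  donor_first       : 60/60 carry the expected code (100%)
  multi_step_bleach : 55/60 carry the expected code (92%)
  uncorrelated      : 53/60 carry the expected code (88%)
ensemble FRET histogram peak at E = 0.925 (265 molecules)
```

(The sub-100% rates are dominated by molecules whose bleach cascade falls
outside the recording window; conditioned on an observable cascade the
per-class rates exceed 95% — that conditioning is what the test suite
scores.) Stage 04 recovers the planted kinetics — the simulation switches
between E = 0.3 and E = 0.9 at 0.5 s⁻¹:

```
fitted 251 molecules; state-count distribution {1: 2, 2: 249}
cluster representative FRET levels: [0.325, 0.925]
  0→1: 0.51 /s  (95% CI 0.49–0.54, n=1447)
  1→0: 0.52 /s  (95% CI 0.50–0.55, n=1460)
```

Stages 05–06 prepare the symmetric dimer, simulate dye centers (mean
Cα→center protrusions 1.04 nm donor-like, 1.17 nm acceptor-like), verify
the apex optimizer on a planted 30° rotation (recovered to 0.00°), and
grow the restrained CC1 ensemble:

```
collected 50 solutions (0 failed attempts, 0 constraints relaxed)
topology split: 32% stacked
CC1α1 centroid of the ensemble average sits 1.46 nm from the planted chain
```

The ensemble, class averages and manifest land in `results/` as
multi-model pseudo-atom PDBs and JSON.

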