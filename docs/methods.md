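# Methods

This note documents the models and numerical choices behind `dualflit`: what
the synthetic generator emulates, how the signal treatment and classifier
are defined, which parameters matter, and what the package's tests do and do
not demonstrate about real microscopy data.

## The measurement model

A clonal stem-cell colony confined in a hydrogel microwell is imaged in two
fluorescence channels — a stemness reporter (Pax7/GFP) and a commitment
reporter (myogenin/mCherry) — every 20 minutes for 72 h (217 frames at
346×260 after 4×4 binning). Tracking provides per-frame cell masks and
parent links; the analysis converts masked pixel intensities into per-cell
reporter traces, per-division feature vectors, and division-type labels.

## Signal treatment

**Homogenization.** Global illumination fluctuates frame to frame
(flicker) and drifts over the run. The per-frame mean intensity `m_t` is
fitted with a temporal trend — `g(t) = a·t^b + c` for the GFP channel,
where residual ambient autofluorescence decays toward a floor `c` (hence
the additive offset; `t` is 1-based so `t^b` is finite at the first frame),
and `g(t) = a·t + b` for mCherry, which shows no autofluorescence — and
every frame is shifted by the scalar `g(t) − m_t`. Addition rather than
multiplication avoids amplifying pixel noise; corrected frames are kept in a
real-valued representation without clipping so the identity
`mean(F′_t) = g(t)` holds exactly (to float precision), which the tests
assert on arbitrary input. The power-law fit is nonlinear least squares
initialized from a log–log linear fit; on non-convergence it falls back to
a linear trend with a warning.

**Overexposure.** A frame is discarded (marked missing, never interpolated)
when at least 1% of its pixels sit at the saturation value; trend fitting
excludes flagged frames but is evaluated on the full frame grid.

**Traces.** The raw trace is the mean corrected pixel value inside the
cell's mask per frame; smoothing is a centered window-5 moving average that
truncates at track ends and skips missing frames (each output value is the
mean of the available window members). Normalization is per sequence and
channel: minimum over all smoothed track values, maximum the larger of the
observed maximum and the 99th percentile of the post-differentiation
validation image when one is supplied. Per-sequence (rather than per-cell)
bounds were chosen because normalization exists to make colonies comparable;
users should be aware that a sequence's brightest cell sets the scale for
its siblings. Quintile codes are five fixed-width bins of the normalized
[0, 1] range (`q = min(⌊5s⌋+1, 5)`), not empirical 20th-percentile cuts —
fixed bins keep the coding stable across clones and experiments.

## Division features and classification

Each division is described by 38 features computed on normalized traces
over each track's full lifetime: min/max/mean/variance of both reporters
for the parent and both daughters (24), lifetimes of all three cells and
the absolute daughter lifetime difference (4), whether each daughter
divides again (2), absolute daughter contrasts in mean stemness and mean
commitment (2), terminal commitment values (2), least-squares commitment
slopes per hour (2), parent generation and division time (2). The registry
is data-driven (`features.FEATURE_NAMES`), so individual features can be
renamed or replaced while the count stays 38. Daughters are canonically
ordered by descending lifetime-mean commitment signal (ties broken by track
id), which makes asymmetric divisions well-posed and the vector invariant
to raw daughter order. Slopes over fewer than two frames are 0.

Features are z-scored column-wise with the population (n-denominator)
standard deviation — any consistent convention works, but it is fixed and
stored with the classifier — zero-variance columns standardize to 0, and
each column is multiplied by a non-negative weight (default 1; a weight
file can encode empirically tuned importances).

Clustering is K-means with k = 3, Lloyd's algorithm, 50 random restarts
keeping the lowest within-cluster sum of squares, squared-Euclidean
distance in scaled space; an emptied cluster is re-seeded at the point
farthest from its assigned centroid; everything is deterministic for a
fixed seed. k is fixed at 3 even though elbow curves on mixed data can
favor 4 — the fourth cluster would only capture divisions whose daughters
cannot be scored for further division at the end of a window, which is
deliberately not modeled as a class. Cluster → label attachment uses a
small anchor set of manually annotated, unambiguous divisions (12 by
default): per-cluster anchor majority, with explicit errors for clusters
holding no anchors, tied majorities, or two clusters sharing a label.
Assignment of new divisions is nearest-centroid ("1-NN to the cluster
centroids"), not 1-NN over training points — the centroids are the class
prototypes; exact ties go to the lowest cluster index.

## Lineage statistics

Trees are rooted at founders (generation 0; a display offset is available
since conventions differ), internal nodes carry the classified division
label, and leaves end as died or survived-to-end. A division is registered
on the first frame its daughters exist; a death on the frame after the
dying track's last frame, so the conservation law
`live(t) + deaths(t) = founders + divisions(t)` holds at every frame and is
asserted in the tests. Cohort curves are rescaled to represent 100 starting
clones (real-valued rescaled counts, not re-binned integers); per-generation
division-type fractions are computed over labeled divisions only, with the
generation of a division defined as parent generation + 1. The infection
rate is the exact ratio `n_infected_wells / n_live_wells`; dead colonies are
excluded because an early-dying clone cannot express the commitment
reporter, making false and true negatives indistinguishable. Clones whose
post-differentiation validation shows no commitment-reporter expression are
excluded via an explicit founder-exclusion list before statistics.

## Tracking

The built-in tracker is deliberately simple: Otsu threshold on the summed
channels, connected components filtered by minimum area, greedy
nearest-centroid frame-to-frame linking within a step limit, and purely
topological division detection (two objects claiming one predecessor). It
recovers lineages exactly when cells stay separated by more than twice the
step limit — the regime the tests exercise — and degrades without guarantees
in dense colonies, where touching cells merge under a global threshold. The
supported route for production data is importing externally produced (and
manually corrected) Cell-Tracking-Challenge-style track files: a text table
of `label first_frame last_frame parent` plus 16-bit per-frame label
images, round-tripped losslessly by `tracking.read_ctc`/`write_ctc`.
Cells leaving the field are not modeled (microwells confine clones).

## The synthetic generator

The simulator provides ground truth for every stage. Its defaults define
the benchmark conditions:

- **Lineage.** Stem cells cycle with log-normal cycle times (PGE2 preset:
  mean 10 h, sd 2 h), die with probability 0.05 per cycle (death strikes
  before division; dying cells vanish from subsequent frames and are shown
  as deaths in trees), and otherwise divide with per-generation probability
  `p_divide` (PGE2: 0.9). Division types are drawn per generation from a
  (p_SR, p_A, p_SC) triple; the PGE2 preset uses the reported 0.60/0.15/0.25
  split held constant across generations. Control (0.45/0.20/0.35,
  `p_divide` 0.8) and OSM (control-like at generation 1 with `p_divide`
  halving each generation) are qualitative defaults, not reported values.
  Committed cells are terminal: they persist or die but never divide, so
  committed cells never produce stem descendants and the division-type
  frequencies equal the generating triple — the property the parameter-
  recovery benchmark measures.
- **Reporters.** A two-state switch at division time: stem cells hold the
  stemness reporter at 0.80 (normalized scale) with the commitment reporter
  at a 0.05 baseline; committed daughters follow a logistic commitment rise
  (delay 4 h, rate 1.5/h, plateau 0.90) from birth while stemness decays
  exponentially (0.30/h). Per-frame Gaussian noise (sd 0.02) is added and
  values are clipped to [0, 1]. These kinetic forms and numbers are modeling
  stand-ins chosen to reproduce the qualitative ordering (stemness reporter
  on first, commitment reporter rising later); no measured kinetics are
  implied. Intra-lifetime commitment without division is excluded, matching
  the five-scenario fate scheme (no division, A, SR, SC, death).
- **Rendering.** 346×260 frames every 20 min for 72 h: per channel,
  pixel = background trend (power-law for GFP at ~280–400 counts, linear
  for mCherry) + global flicker (sd 15) + cell disks (radius 6 px) scaled
  by 1500 × trace value + Gaussian pixel noise (sd 8), clipped at a
  saturation of 4095 (12-bit camera). Cells start near the microwell
  center, take Brownian steps (sd 1.2 px/frame) integrated frame by frame
  with reflection at the microwell boundary and deterministic pairwise
  repulsion, so ground-truth masks are always disjoint. Daughters separate
  in opposite directions from the parent's last position. Motion is
  plumbing, not biology. Brightfield rendering is omitted; the analysis
  here runs on fluorescence frames and label masks.

What the simulator does **not** emulate: real segmentation errors, touching
or overlapping cells, uneven illumination *within* a frame (only the
temporal mean is corrected, matching the analysis), photobleaching beyond
the fitted trend, focus drift, and cell morphology beyond disks. Passing
tests therefore demonstrate the correctness and internal consistency of the
analysis pipeline under its stated model, not tracker robustness on real
images.

## Benchmark problem sizes

The parameter-recovery benchmark (scripts/acceptance.py and the
corresponding test) simulates 1000 founder clones — comfortably above the cohort floor of
200 — so that each of generations 1–4 carries several
hundred divisions and per-generation percentages are estimated with
sub-2-point standard errors; the run takes a few seconds. Anchor divisions
(4 per class, 12 total) are picked deterministically by an "obvious
division" rule mirroring manual annotation: for SR the divisions whose two
daughters have the lowest summed terminal commitment, for SC the highest,
for A the largest daughter commitment contrast. Trace-fidelity checks on
rendered fixtures compare extracted normalized traces against the noiseless
generative reporter levels and are restricted to tracks with at least 8
frames and a true dynamic range of at least 0.1 — Pearson correlation is
undefined on constant traces, and near-constant ones measure only noise.

## Known limitations

- The 38-feature registry reconstructs the published feature categories;
  an exact external feature list and empirically tuned weights can be
  dropped in via the data-driven registry and weight files without code
  changes.
- The greedy tracker is a testing substrate, not a competitor to
  probabilistic track linking; dense colonies need externally corrected
  tracks.
- Per-sequence normalization couples a cell's scale to its brightest
  sibling; sequences with a single saturating cell compress the rest.
- Borderline divisions (weak commitment contrast) are assigned to the
  nearest centroid without a confidence measure; no soft assignment is
  provided.
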