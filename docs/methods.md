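# Methods

`vgerp` implements a visibility-graph feature pipeline for discriminating
clinical groups from event-related EEG, together with a synthetic ERP
cohort generator used for validation.  This note documents the model at
each stage, the defaults and why they were chosen, and what the synthetic
validation does and does not establish.

## Signal model and preprocessing

Input is an epoched voltage tensor: subject × condition × channel × trial
× time, sampled at 250 Hz over a −2…+2 s window around stimulus onset.
Three linear reductions turn each (subject, condition, band, channel) cell
into one short series:

1. **Trial averaging.** The evoked (phase-locked) response is the mean
   over trials.  Because averaging and FIR filtering are both linear, the
   implementation averages first and filters once per average; this is
   exactly equivalent to filtering every trial and averaging, at a
   fraction of the cost.
2. **Band filtering.** Five canonical bands (δ 1–4, θ 4–8, α 8–13,
   β 13–30, γ 30–45 Hz) plus the unfiltered "raw" signal.  Filters are
   zero-phase Hamming-windowed FIR (high-pass then low-pass, via
   `mne.filter.filter_data`), with transition bandwidths of 25 % of the
   passband edge above 4 Hz, 2 Hz at a 4 Hz edge and 1 Hz at a 1 Hz edge;
   the −6 dB point sits at the centre of each transition band, and the
   filter order follows the standard Hamming design rule.  The 4 s epoch
   is mirror-padded by 2 s on each side before filtering (reflection
   without edge duplication) and unpadded after, to control edge
   artefacts.
3. **Binning and cropping.** Consecutive non-overlapping 80 ms windows
   (20 samples) are replaced by their means, then bins whose *start* time
   lies in [−1 s, +2 s) are kept.  −1 s is not a bin boundary of the
   −2…+2 s epoch, so the realisable window closest to the nominal 3 s
   retains 37 bins (starts −0.96 … +1.92 s).  The interval is half-open
   at the top so no bin extends past +2 s.

## Visibility graphs

Each 37-bin series becomes a natural visibility graph: node *i* is bin
*i*, and nodes *m < n* are joined iff every strictly intermediate sample
lies strictly below the chord between them.  Ties block visibility (a
sample exactly on the chord is not "below" it), so collinear runs map to
bare paths.  Adjacent samples are always joined, making every VG
connected.  Construction is O(n²) via a running-maximum-slope sweep —
asymptotically better algorithms exist but are irrelevant at n = 37 —
and is invariant under positive affine voltage transforms, which all
downstream features inherit.

## Graph features

Eleven single-channel features per VG:

| feature | definition | range |
|---|---|---|
| clustering | mean of C_i = 2\|E_i\| / (k_i(k_i−1)); C_i = 0 when k_i < 2 | [0, 1] |
| global efficiency | mean over ordered pairs of 1/d_ij | (0, 1] |
| local efficiency | per node, mean inverse **full-graph** distance over ordered neighbour pairs, normalised by \|V_gi\|(\|V_gi\|−1); nodes with < 2 neighbours contribute 0 | [0, 1] |
| small-worldness | S = (C/C_r)/(L/L_r) against a fixed ER reference | > 0 |
| graph index complexity | 4c(1−c), c = (λ_max − 2cos(π/(n+1)))/(n−1−2cos(π/(n+1))) | [0, 1] |
| max clique | size of the clique found by the Ramsey-type approximation | ≤ ω |
| TSP cost | double-tree tour in the BFS metric closure, rooted at bin 0 | [n, 2·opt] |
| density | 2\|E\|/(\|V\|(\|V\|−1)) | [0, 1] |
| independence number | Ramsey approximation on the complement | ≤ α |
| min cut | exact Stoer–Wagner global minimum cut | ≥ 1 |
| coloring number | greedy, largest degree first | ≥ clique |

Notes on the choices that were genuinely open:

* **Local efficiency** uses full-graph shortest paths between neighbours
  (paths may leave the neighbourhood), not subgraph distances; on P₃ this
  gives 1/6, not the subgraph value 0.
* **Small-world reference.** One Erdős–Rényi graph normalises every VG of
  a cohort: n = the common VG size, edge probability = the mean density
  of all cohort VGs, seed fixed, resampled (advancing the seed) until
  connected.  Density matching makes C_r and L_r commensurate with the
  graphs being normalised; using a single shared reference keeps the
  feature comparable across subjects.  L is the mean distance over
  unordered pairs in both numerator and denominator, so the convention
  cancels.
* **NP-hard statistics.** Max clique and independence number use the
  deterministic Boppana–Halldórsson Ramsey recursion (pivot = lowest
  node index, clique removal on the complement/graph respectively),
  implemented natively for speed; the returned value is always the size
  of a verified clique/independent set, hence a lower bound on the true
  optimum.  The TSP tour is the classic MST-preorder 2-approximation in
  the metric closure, rooted at the first time point, with lowest-index
  tie-breaking in Prim's algorithm, so the whole feature set is
  bit-reproducible.  The exact min cut uses Stoer–Wagner.  Exhaustive
  solvers (branch-and-bound clique, Held–Karp) appear only as test
  oracles.
* **Degenerate cases.** Zero-variance clustering sequences give CCSS = 0;
  nodes of degree < 2 contribute 0 to clustering and local efficiency.

The single cross-channel feature builds, per (subject, band, condition),
a network over channels with an edge where the clustering-coefficient
sequence similarity (absolute Pearson correlation of the two VGs'
clustering sequences) exceeds θ = 0.25; the feature is that network's
edge count.  Channel networks need ≥ 2 channels and are omitted below
that.

At the full grid — 15 channels × 6 bands × 11 features × 6 conditions
plus 6 × 6 cross-channel cells — the feature matrix has 5976 columns.

## Screening, reduction, classification

Each column is screened with an independent two-sample Student t-test
(pooled variance — the library-default flavour; Welch is available via a
flag), two-tailed, at α = 0.01.  No multiple-testing correction is
applied by design: at α = 0.01 about 1 % of null columns pass
(≈ 60 of 5976; ≈ 10 per condition), and this false-positive burden is
absorbed by the PCA step rather than corrected away.  Columns whose
pooled within-group variance is zero are reported as t = 0, p = 1.
`alpha ≥ 1` selects every column (boundary contract for pipeline
smoke-runs).

Selected columns are z-scored and projected onto the top k = 11 principal
components (roughly 10 % of the published selection size).  The
normalisation statistics and the eigendecomposition come from the
*training rows only* of each evaluation split, so no information leaks
from held-out subjects; a property test asserts that full-fit and
train-only-fit projections genuinely differ.

Four classifiers are compared: L2 logistic regression (C = 1), a linear
soft-margin SVM (C = 1), LDA, and a one-hidden-layer (32 ReLU units)
neural network trained full-batch with L-BFGS, at most 200 iterations,
reseeded per repeat.  The regularisation strengths and the network
width/optimizer are this package's documented defaults, exposed in
`vgerp.evaluate`.  The protocol repeats 100 stratified 85/15 splits
(stratification avoids single-class test sets in cohorts of ~26–41
subjects) and reports mean ± SD of accuracy (%), precision, recall and
ROC AUC; a stratified 5-fold variant is available.

The generalisation path screens on one group pair (patients vs controls)
and applies the resulting mask unchanged to a different pair (prodromal
vs controls), mirroring the transfer question the pipeline is designed to
answer.

## Synthetic cohorts

The generator emulates the word-repetition study layout: 250 Hz, −2…+2 s
epochs, 15 channels (midline, lateral, Broca/Wernicke/BA41 approximations),
six word conditions, 72 trials per condition, groups RNE/AD/pAD of
11/15/15 subjects.  Per trial and channel the signal is

* 1/f-amplitude-shaped Gaussian noise plus white noise, each carrying half
  of `noise_sd`² (default 10 µV total — a typical single-trial EEG
  background);
* optional band-limited sinusoids at band-centre frequency, with uniform
  random phase per trial (induced activity) or zero phase (evoked,
  `phase_locked=True`), power scaled per group;
* Gaussian-windowed half-sine deflections (N400-like negative at 400 ms,
  P600-like positive at 600 ms in the reference studies) whose peak
  amplitudes are scaled multiplicatively per group — "diminished"
  components in patient groups — with optional trial-level latency jitter
  shared across channels.

Channels are independent by default so per-channel feature attribution
stays interpretable.  What the generator does *not* emulate: volume
conduction / channel covariance, eye-blink or muscle artefacts,
non-stationary background, latency (rather than amplitude) group effects.
Passing tests on these cohorts therefore demonstrate that the pipeline's
statistics and code behave as specified — calibrated type-I error,
perfect separation of a large planted effect, transfer to an intermediate
group — not that any particular accuracy would be attained on clinical
recordings.

## Validation study sizes

The reference studies in `vgerp.cohorts` run the full pipeline at a
reduced grid — 3 channels, 2 conditions, 2 bands — with the clinical
group sizes (11/15/15) and trial counts (72) retained.  The properties
validated (t-test calibration, separability, intermediacy) do not depend
on grid size, and the reduction keeps a complete study, including the
100-repeat evaluation, in the tens of seconds.  Significance-level
calibration averages the selected fraction over 50 independent null
cohorts (10+10 subjects, 8 trials, noise only; trial count does not
affect the null distribution of the between-subject test).

## Numerical notes and limitations

* Chord tests compare slopes; with float input, ties that are exact in
  real arithmetic remain exact in IEEE (correct rounding maps equal reals
  to equal floats), but affine transforms of *nearly*-tied float series
  can flip a strict inequality — a floating-point artefact, not a model
  property.  Integer-valued series are exact under power-of-two scalings.
* GIC is guaranteed in [0, 1] only for connected graphs (the path graph
  minimises λ_max among connected graphs); VGs are always connected.
* Average clustering is **not** monotone under edge addition (the new
  edge inflates the endpoints' degree denominators), unlike density and
  global efficiency.
* The evaluation caps k at min(11, informative columns, n_train − 1) when
  a split leaves fewer usable dimensions than requested.
* Reports, CSVs and manifests are written with sorted keys and no
  timestamps, so a rerun with the same config and seed is byte-identical.
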