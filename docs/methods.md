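# Methods

This note documents the models, conventions and numerical choices behind
`tdcsgraph`, and what the synthetic-data experiments do and do not show.

## Analysis pipeline

The pipeline evaluates how cathodal transcranial direct current stimulation
(ctDCS) reorganizes resting-state functional brain networks in focal
epilepsy, and whether that reorganization predicts treatment response.

1. **Inputs.** Per subject and condition (pre/post stimulation), a
   region-averaged BOLD time-series matrix (regions x time) from a
   90-region AAL-style parcellation, plus a metadata table with trial arm,
   4-week baseline/follow-up seizure counts, and stimulation-site electrode
   labels (10-10 system).
2. **Response labeling.** A subject responds when the follow-up count is at
   least 20% below baseline. The comparison uses exact rational arithmetic
   on the integer counts, so a reduction of exactly one fifth (e.g. 5 -> 4)
   counts as a response; float thresholds like 0.2 are converted through
   their decimal literal.
3. **Augmentation.** Each 230-timepoint scan is cropped into overlapping
   windows of length T = 90 with stride 35 (overlap 55), yielding five
   windows per scan. Pre and post windows of a subject are paired by window
   index for all paired statistics and change rates; the pairing rule is a
   design choice (the index pairing is the only order-preserving one).
4. **Connectivity.** Pearson correlation between all region pairs, Fisher
   r-to-z. Correlations of magnitude 1 (degenerate inputs) are capped at
   1 - 1e-7 with a warning rather than producing infinite weights.
5. **Thresholding.** Proportional density thresholding retains the
   round(d * N(N-1)/2) strongest-z edges as an undirected weighted graph, so
   every sample has identical node and edge counts at a given density d.
   Conventions: rounding is half-away-from-zero (N = 90, d = 0.3 gives
   exactly 1202 edges); ties at the cut weight keep the lexicographically
   smallest (i, j) pairs; densities are generated from integer hundredths to
   avoid float drift. Retaining a non-positive weight is an error (negative
   connections are discarded by design; the density is too high for that
   matrix). A disconnected graph is a recorded flag, not an error: global
   efficiency remains well defined (unreachable pairs contribute zero) while
   path length becomes infinite and is handled downstream.
6. **Graph measures.** Weighted degree K_i = sum_j w_ij; Onnela clustering
   with weights normalized by the network maximum,
   C_i = 2 e_i / (k_i (k_i - 1)) with e_i the geometric-mean triangle
   intensity and k_i the *binary* neighbor count (a weighted-degree
   denominator would be dimensionally inconsistent and can divide by zero
   for sub-unit weights); shortest paths on lengths 1/w_ij (the standard
   convention for connectivity-strength weights), giving nodal mean path
   length L_i, characteristic path length L_net, global efficiency E_net,
   and local efficiency E_i = E_net of the neighbor-induced subgraph;
   small-worldness sigma = (C_net/C_R)/(L_net/L_R) against degree-preserving
   rewired nulls. Stimulation-site measures average the nodal values over
   the regions mapped to a subject's electrodes (unweighted mean across one
   or two foci).
7. **Statistics.** For each (group, measure, density) cell, Shapiro-Wilk
   (alpha = 0.05) on the paired differences gates a paired t-test versus a
   Wilcoxon signed-rank test; Benjamini-Hochberg FDR is applied within each
   (group, measure) family across the densities of the sweep; cells are
   flagged at q < 0.05 and q < 0.01.
8. **Prediction.** Features are the per-window change rates
   (post - pre)/pre of C_net, L_net, E_net and site L_local at one density
   (default 0.3 on the full-scale grid), active-arm samples only (sham
   subjects carry no response label). Features are ranked by the maximal
   information coefficient against the label, a sequential forward search
   keeps the accuracy-maximizing prefix (ties favor fewer features), and an
   RBF-kernel SVM is evaluated by nested cross-validation (outer folds for
   ACC/SN/SP/AUC, inner grid search over C and gamma).

## Null models

Rewired nulls use Maslov-Sneppen double-edge swaps: the binary degree
sequence is preserved exactly and weights travel with their originating
edge, so the weight multiset is preserved too (whether nulls should also
preserve weights is ambiguous in the field; we preserve the multiset). The
sampler targets 10 accepted swaps per edge with an attempt cap of 10x that
budget; on graphs with no acceptable swap (e.g. complete graphs) it
terminates at the cap with a warning and every null equals the original
graph, so sigma = 1. Rewiring can disconnect a connected graph; nulls with
infinite L_net are excluded from the L_R mean, and sigma is reported as
missing (NaN) when no finite null remains or C_R = 0. Null computations are
seeded per (sample, density) from the master seed via counter-based
`SeedSequence` entropy, so results are independent of evaluation order.

## MIC

MIC is the maximum over p-by-q grids (p*q <= B(n), B(n) = max(4,
floor(n^0.6))) of grid mutual information normalized by log2 min(p, q).
For each grid shape one axis's partition is enumerated exhaustively when
the number of candidate partitions is small (cuts can only fall at value
boundaries); otherwise that axis is equipartitioned — the published
approximation. The other axis is then optimized *exactly* by dynamic
programming over cut positions (mutual information decomposes into additive
per-bin scores once one axis is fixed). Both orientations are searched, so
the statistic is symmetric. Two consequences worth knowing:

* when one variable is binary (the response label), the binary axis admits
  exactly one two-bin partition, so the DP gives the exact MIC; the
  redundant enumeration of the continuous axis is skipped;
* MIC(x, x) = 1 requires a balanced 2x2 grid; at odd tiny n the best split
  is one point off balance and the value falls marginally short of 1.

## Cross-validation modes

Default folds are **group-aware**: `StratifiedGroupKFold` keeps all windows
of one subject on the same side of every split, preventing the leakage that
overlapping-window augmentation otherwise causes. `paper_mode=True`
switches to sample-level `StratifiedKFold` splits and disables class
weighting, replicating the augmented-sample analysis (documented as
leakage-prone). Class imbalance (roughly 1:2 responders to non-responders)
is handled with inverse-frequency class weights in the default mode.
Standardization is fitted on training folds only. The SFS evaluator uses a
fixed RBF-SVM (C = 1, gamma = 1/p) so feature selection is decoupled from
the hyperparameter grid; the default grid is C in 2^-5..2^15, gamma in
2^-15..2^3 (steps of 2^2).

Windows whose graph disconnects at the feature density have undefined
path-based change rates; they are excluded with a warning (the real-data
analogue of scan exclusion), or raise in `on_nonfinite="error"` mode.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
raw fMRI. Signals are multivariate Gaussian with AR(1) coloring: x_t =
a x_{t-1} + sqrt(1 - a^2) L eps_t with L the Cholesky factor of a
block-modular correlation matrix, so the stationary cross-correlation
equals the target exactly while a = 0.4 supplies the temporal smoothness a
0.01-0.08 Hz band implies. The target matrix has unit diagonal, rho_within
= 0.6 inside modules (six modules of 15 regions at full scale) and
rho_between = 0.15 across them. The responder effect multiplies
within-module correlations by 1 - effect (default effect 0.4) in the
post-stimulation covariance: weakening the strongest (retained) edges
provably lowers clustering and efficiency and lengthens shortest paths —
the direction of the treatment effect in responders. Non-responders and
sham subjects draw fresh post noise from the unchanged covariance.

Seizure diaries are Poisson: baseline mean 30 per 4 weeks (conditioned on
>= 1, matching the inclusion criterion), follow-up mean scaled by 0.3 for
true responders and unchanged otherwise. These defaults are deliberately at
the high-frequency end of a focal-epilepsy clinic so the operational 20%
label is informative about the generator's ground truth: with them a true
responder is labeled correctly almost surely while a non-responder's counts
cross the threshold by chance with probability ~0.16. Subjects whose counts
disagree with the ground-truth flag are *kept* — downstream labels always
come from the counts, mirroring the operational definition — so group
assignments carry realistic label noise.

What the generator does **not** emulate: volumetric artifacts (motion,
physiology, scanner drift), spatial autocorrelation of the parcellation,
heavy-tailed or subject-specific connectivity profiles, and any
relationship between seizure biology and connectivity beyond the planted
modular effect. Passing tests therefore demonstrate that the pipeline
recovers effects of the assumed form at realistic sample sizes — not that
the clinical effect exists or that real patients' values are reproduced.

## Problem sizes used in tests and the acceptance script

Full-scale runs (90 regions, 30 densities, 100 rewired nulls per graph,
200 augmented samples) are expensive mainly through the rewired nulls, so
the shipped experiments downscale while keeping the study's arm structure
(12 active / 4 responders / 8 sham): a 20-region parcellation with four
modules of five regions, rho_between raised to 0.2, and the density sweep
shifted to 0.35-0.45 — small graphs disconnect at the full-scale range, and
the sweep range was chosen (as in the original design) to keep networks
connected. The acceptance script uses 10 rewired nulls per graph and an
abbreviated hyperparameter grid with 3-fold outer/inner CV (group-aware
5-fold CV needs at least five responder subjects per fold, which a
12-subject arm cannot supply).

## Measured behaviors worth knowing

* **Sample-level pairing is anticonservative.** With overlapping windows as
  paired units, differences are correlated within subject; under a null
  generator the sweep comparison rejects ~13% of cells at the nominal
  q < 0.05 level in small cohorts. The subject-level mode (windows averaged
  per subject first) is calibrated (~2-3% measured) and is the mode whose
  type-I behavior the test suite asserts. Conclusions drawn from the
  sample-level replication mode should be treated accordingly.
* **The planted effect also moves sigma slightly.** Because the effect
  lowers C_net and raises L_net, their ratio against rewired nulls shifts
  in responders, and sigma occasionally reaches significance in synthetic
  sweeps — a property of the generator's covariance effect, not of the
  statistics.
* **L_net has the least power** of the three global measures under the
  planted effect; at downscaled sizes its significance fraction across the
  sweep varies considerably from seed to seed, while E_net and C_net are
  consistently detected.

## Known limitations

* The electrode-to-region map is a documented convention; the package
  cannot know the clinician-vetted assignments for a given montage.
  Downscaled parcellations use an explicitly synthetic evenly-spaced map.
* Measures on disconnected graphs mix finite (E_net, clustering, degree)
  and infinite (path-based) values; cells with fewer than five usable pairs
  are reported as missing rather than tested.
* The exact-MIC branch is limited by enumeration cost; beyond it the
  equipartition approximation can underestimate MIC for adversarial
  continuous-continuous pairs (binary-label uses are always exact).
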