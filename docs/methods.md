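# Methods

`pecnet` implements a source-space task-EEG network pipeline: orthogonalized
power-envelope connectivity (PEC) between cortical regions, binary
graph-topology metrics against a degree-preserving random-network null, the
associated group statistics, and a leave-one-subject-out (LOOCV)
classification framework with in-fold feature selection.  Because no public
dataset accompanies the problem, the package ships a synthetic cohort
generator that plants known envelope couplings and group differences; every
downstream stage is validated against that ground truth.

## Signal model and the synthetic cohort

Each cortical region (ROI; 68 by default, mirroring the Desikan–Killiany
parcellation) carries one band-limited oscillatory signal

    x_r(t) = exp(s · e_r(t)) · c_r(t),

where `c_r` is unit-variance band-passed white noise (default beta band,
13–30 Hz) and `e_r` is a smooth standard-normal *latent log-envelope*
(white noise low-passed at one tenth of the band centre, ≈2.15 Hz for
beta).  Carrier phases are independent across ROIs, so no genuine zero-lag
coupling exists — any zero-lag sensor correlation is pure volume
conduction.  Envelope coupling is planted pairwise: for a requested pair
(i, j, ρ), the latent processes are combined so that corr(e_i, e_j) = ρ.

Two implementation choices matter here:

- **Exact second moments.** Smooth processes have few effective degrees of
  freedom per minute, so the naive shared-plus-private construction leaves
  sample-correlation noise of ~0.06 at 60 s.  The generator instead
  empirically whitens the latent processes (Cholesky of the sample
  covariance) and mixes them through the Cholesky factor of the target
  correlation matrix, making the realized latent correlations equal the
  request to machine precision.  Unplanted pairs are exactly uncorrelated.
- **Modulation depth** `env_log_std` (default **s = 2.0**, dimensionless
  log-amplitude SD).  The PEC estimator carries an irreducible noise floor
  from the carrier's Rayleigh envelope and from the orthogonalization
  residual; the planted correlation is recovered within ±0.05 only when
  the latent log-power variance (2s)² dominates that floor.  s = 2.0 is
  deep modulation — burst-like activity rather than stationary
  oscillation — and was chosen for estimator fidelity, not physiological
  realism.

Dipoles (default 3 per ROI) replicate their ROI signal plus small private
band-limited noise (`dipole_noise`, default 0.1 relative SD), which
exercises the vertex-pair averaging of the ROI aggregation stage.  Sensors
are an instantaneous mix through a random lead field (random orthonormal
3-orientation triads per dipole, mildly smoothed topographies) plus white
noise scaled to a target mean-power SNR (default 3).  Group effects
multiply planted ρ values per group (e.g. halved couplings in one patient
group).  All randomness derives from one master seed via
`numpy.random.SeedSequence`; regeneration is byte-identical.

What the generator does **not** emulate: ocular/muscle artifacts, 1/f
broadband background, realistic head geometry, non-stationarity across the
recording, or physiologically calibrated effect sizes.  Passing tests show
the *machinery* is correct and calibrated, not that the effect sizes match
any patient population.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth filters throughout;
polyphase resampling to 256 Hz with built-in anti-aliasing; common-average
re-referencing; band splitting into delta (1–4), theta (4–7), alpha (8–12)
and beta (13–30 Hz).  Epochs are closed intervals [−100, 500] ms around
stimulus onset with nearest-sample boundaries (155 samples at 256 Hz) and
are baseline-corrected by the [−100, 0] ms mean.  Filtering happens on the
continuous record before epoching; per-epoch filtering of 155-sample
windows would distort band edges.  Visual bad-epoch rejection is replaced
by an automatic rule: reject an epoch when any sample deviates from the
channel median by more than k·1.4826·MAD (k = 8).

## Source estimation (wMNE)

The inverse operator is K = R L′ (L R L′ + λI)⁻¹ with depth weights
R = diag(1/‖column block‖²) shared across each dipole's three orientation
columns, identity noise covariance, and λ = δ · trace(L R L′)/n_sensors
with δ = 1/100.  Scaling λ by the trace makes δ dimensionless and the
operator invariant to the overall lead-field gain.  Free-orientation
estimates are collapsed per dipole by the Euclidean norm over the three
components, which is rectifying (non-negative output); an SVD-based signed
collapse (`svd_orientation_collapse`) is provided as a clearly non-default
alternative for users who prefer an unrectified series.

## Power-envelope connectivity

Per epoch, the analytic signal is computed by Hilbert transform with
full-length mirror padding.  For a node pair with analytic signals X, Y,
the component of Y orthogonal to X at each sample is
imag(Y·X*/|X|); samples where |X| vanishes (relative threshold 1e−12)
contribute zero.  Power envelopes are squared magnitudes; the log is taken
after adding a floor of 1e−12 times the mean power; log-power envelopes
are then low-pass smoothed (2nd-order Butterworth, zero-phase, default
**2 Hz**) and pooled across epochs; each direction contributes one Pearson
correlation and the pair value is the average of the two directions.  ROI
matrices average all dipole pairs between two ROIs; the 68-ROI upper
triangle gives the 2278-feature vector per band.

Numerical and design notes:

- **Why smooth the log-envelope:** the per-sample log-power of the
  orthogonalized signal carries variance ≈ π²/6 from the carrier envelope
  plus ≈ π²/2 from the sin²(phase difference) factor.  Smoothing to the
  slow timescale on which envelope coupling lives removes most of it;
  correlations are unchanged by a common filter for jointly stationary
  series.  With smoothing, planted ρ ∈ {0.2, 0.5, 0.8} is recovered to
  ≈ {0.19, 0.48, 0.77} at 60 s — within ±0.05, with a small residual
  attenuation that is a property of the estimator.
- **Residual leakage under additive noise:** a pure zero-lag duplicate
  (Y a real multiple of X) is suppressed exactly — the orthogonalized
  component is identically zero and contributes a correlation of 0 by
  convention.  When two sensors see one source *plus independent noise*,
  however, the orthogonalized residual's power is σ²(1 + |x|²/|X|²): it
  doubles when the common signal is strong, and this slow modulation
  correlates with the envelope.  With the smoothed estimator the spurious
  PEC is ≈ 0.2–0.3 at SNR 3–10 under deep modulation; with per-sample
  (unsmoothed) envelopes it stays below 0.1.  This trade-off is inherent
  to pairwise orthogonalization; the tests assert each regime where it
  holds and this note is the caveat for real data.
- A degenerate direction (zero-variance input envelope) yields NaN; an
  orthogonalized residual at floating-point noise level (mean power below
  1e−20 of the signal) is treated as identically zero.

## Graph topology

The ROI matrix is binarized by keeping the top 10% of upper-triangle
weights (K = ceil(0.10 · N(N−1)/2) = 228 edges for N = 68); ties at the
cutoff break deterministically by (i, j) order.  Metrics: mean local
clustering CC (degree-<2 nodes contribute 0), characteristic path length L
over reachable ordered pairs (the unreachable fraction is reported — at
10% density disconnection is possible), global efficiency with 1/∞ = 0,
local efficiency as the mean global efficiency of neighbour subgraphs, and
small-worldness σ = (CC/CC_rand)/(L/L_rand) where the references are means
over 100 Maslov–Sneppen randomizations (10·|E| attempted double-edge
swaps each) constrained to preserve the degree sequence and connectedness
(disconnected draws are re-randomized, up to 100 restarts).  σ is reported
as NaN when the thresholded graph itself is disconnected.  Sanity
calibration: σ ≈ 1 for Erdős–Rényi graphs against their own null and
σ > 1.5 for Watts–Strogatz rings.

## Group statistics

Shapiro–Wilk per group and Levene across groups gate parametric versus
non-parametric branches.  Network metrics are compared by the
Kruskal–Wallis test with Dunn-style pairwise rank-sum post hocs,
Bonferroni-corrected by the number of group pairs.  Edge-wise PEC features
are compared by one-way ANOVA per edge with Bonferroni correction over the
edges of the table (2278 for a full band — the narrowest family consistent
with per-band reporting); an edge with zero within-group variance but
different group means is reported significant with a `degenerate` flag.
Significant-edge counts are summarized on a 7-region grouping of the 68
ROIs (frontal, temporal, parietal, occipital, posterior cingulate,
anterior cingulate, insula).  Calibration: on null cohorts the family-wise
error of the corrected edge-wise branch is at the nominal 5%.

## Classification (LOOCV with in-fold feature selection)

For each held-out subject, features are ranked on the training subjects
only — by |Pearson r| with the label, Fisher score (population group
variances), ReliefF (k = 10 neighbours, range-normalized Manhattan
distances, all training instances, fully deterministic), or order of entry
into the LARS active set — then for each candidate count j the classifier
(L2 logistic regression, AdaBoost with 50 stumps, decision tree, or
100-tree random forest, all seeded) is trained on the top-j features and
scored on the held-out subject.  The optimal K is the argmax of the mean
accuracy curve (smallest K on ties) and the reported feature set contains
the K features most frequent among folds' top-K lists (ties: better mean
training rank, then index).  Sensitivity/specificity come from the
confusion matrix at K; the SEM is the population SD of the 0/1 fold
accuracies over √N, which equals √(p(1−p)/N).

Two caveats are inherent to the published procedure and documented rather
than silently altered: (1) K is selected on the same cross-validated curve
that is reported, a mild optimism — `fixed_k` bypasses the argmax for an
unbiased read-out; (2) balanced LOOCV is slightly pessimistic on null data
(the held-out subject's class is always the training minority), so
label-permutation nulls centre just below 0.5; chance-level checks use a
fixed feature count and a single-run binomial standard error.

## Pipeline

`pecnet run --config cfg.yaml --out dir/` (or `pecnet.pipeline.run_pipeline`)
chains simulate → preprocess → inverse → pec → graph → stats → classify.
Each stage writes its outputs (HDF5 containers for signals, delimited text
for matrices and tables, JSON for classification results) plus a manifest
entry containing its parameters, seed, elapsed time and output hashes; a
stage's signature chains its parameter hash with its upstream signature,
so re-running with one changed parameter recomputes exactly that stage and
everything downstream.  Default run scale is 3 groups × 5 subjects, 68
ROIs with one dipole each, 20 epochs, beta band — sized so a full run
completes in well under a minute on a laptop-class machine.

## Problem sizes used in the checks

Monte-Carlo checks run at: envelope recovery 100 replicates × 60 s at
256 Hz; leakage 50 replicates × 40 s; small-world calibration 20 graphs
per family × 100-network nulls; ANOVA calibration 200 null cohorts × 200
edges (a scaled-down stand-in for the 2278-edge family; the Bonferroni
family matches the table width either way); classification nulls 150
permutations at N = 16.  These sizes keep the whole suite in a few
minutes while leaving Monte-Carlo error well inside the stated
tolerances.
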