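# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `netsig` pipeline, in the order data flow through it.

## Preprocessing

Recordings are re-referenced to the common average (subtracting the
across-channel mean at every sample; idempotent by construction) and
filtered with linear-phase windowed-sinc FIR kernels (Hamming window)
applied centred, so the group delay is fully compensated and the
filtered signal is zero-phase. The band-pass is 0.5–70 Hz with a
0.25 Hz transition at the high-pass edge (≈3381 taps at 256 Hz); the
notch is a 48–52 Hz FIR band-stop (the mains frequency sits ≥50 dB down
in its stopband). Edge transients extend roughly one half-kernel
(~8 s) into the recording; the default 180 s analysis epochs make this
negligible, and tests compare filtered signals only outside guard
bands.

Epoch selection is deterministic: with no artifact mask, the earliest
contiguous samples up to the target (180 s) are taken; a boolean keep
mask reproduces manual artifact exclusion, with fragments shorter than
one Welch window (2 s) discarded and the last epoch trimmed so the
total hits the target exactly. Totals outside target ± 25 s set a
warning flag (or raise, in strict mode). Sample intervals are 0-based
and half-open throughout. Whether epochs are consecutive or pooled
across the session is a configuration matter, not an assumption.

## Spectral estimation

The PSD is a Welch estimate: 2 s Hann-tapered segments, 50 % overlap,
density normalization in µV²/Hz on a 0.5 Hz grid; segments never
straddle epoch boundaries. Relative band power integrates the PSD
(trapezoid rule) over the closed bands δ (2–4), θ (5–7), α (8–12) and
β (13–29 Hz) and divides by the integral over 2–29 Hz. Two consequences
of taking the printed band edges literally: the grid points 4.5, 7.5
and 12.5 Hz belong to no band, so the four relative powers sum to
slightly less than 1; and the denominator range (2–29 Hz, the union of
the analysed bands) is a configurable choice, since γ is excluded as
muscle-contaminated in clinical recordings.

The aperiodic component is a straight-line fit of log10 PSD on log10 f
over 2–29 Hz with the α window (7.5–12.5 Hz) excluded, refined by three
iterations of Tukey bisquare re-weighting (c = 4.685, MAD scale) so
residual oscillatory peaks are down-weighted. The slope is the spectral
exponent χ (dimensionless, ≤ 0 physiologically), the intercept the
offset (log10 µV²/Hz at 1 Hz). The fit is exact on peak-free power
laws. Full peak parameterization (center/width/height) is deliberately
out of scope: only χ and offset enter the analysis. Note that on
signals with strong band oscillations inside the fit range (the δ band
in particular) the fitted exponent absorbs part of the oscillatory
power; in the synthetic cohort this steepens fitted slopes beyond their
generative values, in the same direction for both groups. Group
contrasts in the fitted exponent therefore combine the generative slope
difference with the band-power difference — which is also true of any
identically-fitted empirical data.

## Connectivity

wPLI per frequency bin is |E[Im S_ij]| / E[|Im S_ij|], with S_ij the
Hann-tapered segment cross-spectra on the same Welch segmentation as
the PSD, and 0/0 defined as 0. The band value averages the bins inside
the closed band (averaging bin-wise ratios, not ratio of band sums —
standard practice; the alternative is a one-line change). A debiased
squared estimator is available behind a flag. Because only the
imaginary cross-spectrum enters, any instantaneous linear mixing
(volume conduction) contributes zero in expectation; the test suite
verifies both that property and exact equality with a brute-force
evaluation of the defining ratio. The finite-sample floor of the plain
estimator is not zero: with ~180 half-overlapping 2 s segments and
narrowband (2 Hz bandwidth) sources, whose relative phase decorrelates
slowly, uncoupled pairs average wPLI ≈ 0.08–0.10 — well separated from
coupled-pair values (≥ 0.4 in the cohort) but worth remembering when
reading global means. The global scalar is the mean over
the strictly-upper triangle of the matrix; a node-strength mean over
channels is proportional and would change nothing statistically.

## Graph topology

Connectivity matrices are binarized by keeping the ⌈0.05 · 171⌉ = 9
largest pair weights (rank-based "95th percentile" rule, deterministic
with lexicographic tie-breaks; percentile-interpolation variants differ
by at most one edge). At this density 19-node graphs are almost always
disconnected, so the conventions matter and are fixed as: λ averages
over mutually reachable ordered pairs; gE uses 1/∞ = 0 over all pairs;
SWI is computed on the largest connected component (≥ 4 nodes) as
(C/⟨C_rand⟩)/(λ/⟨λ_rand⟩) against 20 degree-preserving rewired nulls
(10·|E| attempted double-edge swaps each, seeded; sparse path-like
degree sequences admit few valid swaps, so swaps are best-effort and a
graph with no valid swap is returned unchanged with a warning).
Undefined metrics (edgeless graphs, ⟨C_rand⟩ = 0) are recorded as NaN
at the pipeline level and median-imputed only inside the classifier.
Modularity uses greedy agglomerative optimization (deterministic given
node order; global optimality not claimed) and is retained in the
feature set but excluded from headline claims. Graph computations are
backed by networkx; every metric is cross-checked against exhaustive
brute-force implementations on all graphs with n ≤ 7 in the tests.

## Statistics

Two-sample comparisons use a two-sided permutation test on the mean
difference with label shuffling without replacement and the +1
correction, p = (1 + #{|T_perm| ≥ |T_obs|})/(n_perm + 1), so p is never
0 and never below 1/(n_perm + 1). When the number of label splits is
small the test switches to exhaustive enumeration and returns the exact
p. The modal-p procedure repeats the seeded test 100 times and reports
the most frequent p after rounding to 3 decimals (ties resolve to the
smaller p); with the +1-corrected estimator this stabilization is
statistically redundant, but it is implemented literally as part of the
procedure this pipeline follows.

The band × group ANOVA is the classical split-plot decomposition:
between-subject SS splits into Group and subject-within-group error;
within-subject SS into Band, Group × Band and Band × subject error;
unbalanced groups are handled with cell-mean weighted sums of squares.
Greenhouse–Geisser ε comes from the double-centred pooled within-group
covariance (group cell means removed; pingouin, used as a cross-check
oracle in the tests, pools the total covariance instead — F statistics
agree exactly, ε to ~0.01). Mauchly's W is computed from the k−1
nonzero eigenvalues of that centred covariance, Bartlett's test from
the per-group subject means. A caveat worth knowing: for relative
measures that sum to ≈1 within subject (relative band power), a group
contrast appears as a Group × Band interaction, not a Group main
effect, because opposite band shifts cancel in the subject mean.

BH-FDR is the step-up procedure with adjusted p_i = min over ranks
j ≥ rank(i) of m·p_(j)/j. Channel-wise maps run one permutation test
per channel and correct across channels × bands jointly.

## Classification

Logistic models are fitted by Newton–Raphson/IRLS on the Bernoulli
log-likelihood (tolerance 1e-8 on the log-likelihood). Quasi-complete
separation — diverging coefficients with all fitted probabilities
saturated on the correct side — triggers a ridge-stabilized refit
(penalty 1e-4) with a loud warning; on strongly separable synthetic
cohorts this keeps fits finite but inflates |β| and voids Wald
p-values, which the salience table inherits. Cross-validation is
stratified 5-fold with shuffling; standardization parameters are
learned on training folds only (a property the tests verify
explicitly). AUC is computed as the normalized Mann–Whitney U (exactly
the ROC area, midranks under ties); the mean ROC is vertical averaging
on a fixed 101-point FPR grid; threshold metrics use probability 0.5
and report the median and sd across folds, with undefined ratios as
NaN. The default qEEG block is δ- and α-relative power, exponent,
offset, δ- and α-BtwC, δ-SWI and δ-gE; a significance-screened
selection (screening on training folds only) is available as an
alternative.

The model comparison permutes the subject rows of the qEEG block,
breaking its link to the outcome while preserving the clinical–outcome
structure, and compares ΔAUC = CV-AUC(clinical+qEEG) − CV-AUC(clinical)
against that null with the +1-corrected p. A label-permutation scheme
is available behind a flag. Type-I calibration of both tests is part of
the acceptance checks (200 null cohorts at n_perm = 500).

## The synthetic cohort

The generator defines the study conditions; its defaults are the
package's calibrated choices, not measurements of any clinical cohort.
Each channel is the sum of (i) an aperiodic background built by
spectral shaping — white Gaussian noise whose rFFT amplitudes are
scaled by sqrt(10^offset f^χ · fs/2), so the expected one-sided PSD is
exactly 10^offset f^χ; (ii) narrowband Gaussian oscillations (band-pass
filtered white noise at a target RMS) in δ, θ and α; and (iii) for
coupled channels, shared δ-band sources, one copy per edge with the
second endpoint phase-rotated by the edge lag via the analytic signal.
The whole channel stack is then mixed with an instantaneous matrix
I + ε·Z/√n (ε = 0.12), which creates zero-lag correlations only — the
volume-conduction emulator that wPLI must reject.

Coupling detectability is degree-balanced: a channel of degree d splits
its shared variance across d sources, so edges between high-degree
nodes would otherwise be much harder to detect; per-channel source
weights are rebalanced multiplicatively until every edge has equal
coherent amplitude, and the per-group shared-source strength is derived
from a single target coherent-variance fraction (0.22) so both group
topologies produce comparable edge wPLI. Lags are drawn uniformly from
(0.5, π − 0.5), avoiding the near-zero/near-π region where the
imaginary cross-spectrum vanishes.

Group topologies at the clinical-montage density of 9 retained edges
per graph: the DRE-like group couples a 1-D lattice segment (a simple path
over 10 nodes — regular, long paths, high betweenness, no triangles),
the comparison group a ten-node double star plus one closing triangle
edge (10 edges; binarization keeps 9, so most realizations remain
integrated with nonzero clustering). This pair was chosen because, at 9
edges on 19 nodes, ring-lattice-vs-rewired constructions become
statistically indistinguishable after binarization; the path/double-star
contrast reproduces the directional pattern of interest — lower gE,
lower SWI, higher BtwC, longer λ in the DRE-like group — at n = 60 per
group. Each backbone edge is independently rewired to a random pair
with probability 0.15 per subject, providing topological heterogeneity.

Spectral group conditions (group means; between-subject jitter in
parentheses): exponent −1.75 vs −1.55 (sd 0.15), offset 0.50 vs 0.70
(sd 0.12) log10 µV²/Hz, δ RMS 3.4 vs 2.9 µV, α RMS 4.6 vs 5.7 µV
(sd 0.9), θ equal at ~2 µV. Effect magnitudes were calibrated once so
the directional contrasts are significant and the qEEG block adds
classification value at n = 60/group; they are configuration
parameters, stated here as the package's own study conditions. Clinical
covariates are Bernoulli draws with group-specific rates for the binary
predictors (e.g. response to the first medication 0.183 vs 0.433,
structural etiology 0.433 vs 0.167) and Gaussian draws for age, onset
age and disease duration; baseline seizure frequency is log-normal
around group medians 3 vs 2. Determinism is counter-based: every
subject stream derives from SeedSequence((master, stream, group,
subject)), so cohorts are bitwise reproducible and extensible without
reshuffling earlier subjects.

What the generator does **not** emulate: biophysical head geometry and
realistic electrode leadfields, epileptiform transients/spikes,
non-stationarity, muscle/ocular artifacts, and oscillatory peak
structure beyond single Gaussian bands. Passing tests therefore
demonstrate that the estimators and inference machinery behave
correctly under the stated statistical structure — not that the
pipeline's clinical conclusions transfer to real EEG.

## Problem sizes and runtime

Default analyses use 60 subjects/group at 180 s, extracted in about a
minute; the calibration checks use 200 null datasets at n_perm = 500
and the exponent-recovery check 50 subjects — sizes chosen so the whole
suite and the acceptance script each complete in minutes on one CPU
while keeping every estimate's Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The fitted exponent/offset conflate aperiodic slope with band power
  (no peak modeling), as discussed above.
* SWI is undefined on a nontrivial fraction of 9-edge graphs (largest
  component < 4 nodes or zero-clustering nulls); it is NaN-recorded and
  the statistics drop, the classifier imputes, those subjects.
* The greedy modularity optimizer is a heuristic; Q values are lower
  bounds.
* Wald inference from ridge-stabilized fits after separation is not
  calibrated; saliences remain interpretable as magnitudes only.
* The significance-screened feature selection inside CV and the fixed
  default feature block can disagree on small cohorts; both are
  exposed.
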