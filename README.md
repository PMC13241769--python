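# netsig — resting-state EEG spectral–topological network analysis

`netsig` is an analysis pipeline for quantitative resting-state EEG
(qEEG) biomarker studies of drug-resistant epilepsy (DRE). People with
epilepsy whose seizures persist after two adequate anti-seizure
medication trials form a clinically distinct group, and their
resting-state EEG shows a characteristic signature: a shift of spectral
power toward low frequencies, a steeper aperiodic (1/f) spectral decay,
and a functional network topology that is more regular and less
integrated than the healthy small-world configuration. This package
implements the complete measurement and inference chain needed to
quantify that signature and to ask whether qEEG features add
discriminative value over clinical predictors — exercised end to end on
a synthetic multichannel EEG cohort generator with known ground truth,
since clinical EEG cohorts of this kind are not publicly deposited.

## What it computes

For each 19-channel, ~180 s recording (10–20 montage, 256 Hz):

* **Preprocessing** — common-average re-reference; zero-phase FIR
  band-pass 0.5–70 Hz with a 50 Hz notch; selection of 180 ± 25 s of
  analysis epochs (mask-driven artifact exclusion).
* **Spectral features** — Welch PSD (2 s Hann windows, 50 % overlap);
  relative band power for δ (2–4), θ (5–7), α (8–12) and β (13–29 Hz),
  i.e. band power / total (2–29 Hz) power; the aperiodic component of
  the PSD via a robust log–log fit, PSD(f) ≈ 10^offset · f^χ, giving the
  spectral exponent χ and offset.
* **Connectivity** — the weighted phase lag index per band,
  wPLI = |E[Im S_ij]| / E[|Im S_ij|] over Welch segments, which is
  insensitive to instantaneous volume conduction; global wPLI is the
  mean over channel pairs.
* **Graph topology** — wPLI matrices binarized at the 95th percentile of
  the edge-weight distribution (top 5 % of pairs, exactly 9 of 171
  edges at 19 channels), then modularity Q, small-world index
  SWI = (C/C_rand)/(λ/λ_rand), mean betweenness centrality BtwC, global
  efficiency gE, mean clustering coefficient C, and characteristic path
  length λ, with degree-preserving rewired null graphs.
* **Statistics** — two-sided label-permutation tests (10 000 iterations,
  modal-p stabilization over 100 repetitions), χ² tests for categorical
  tables, band × group split-plot ANOVA with Greenhouse–Geisser
  correction, Mauchly's and Bartlett's checks, and Benjamini–Hochberg
  FDR control, including channel-wise significance maps.
* **Classification** — maximum-likelihood logistic regression, stratified
  5-fold cross-validated ROC/AUC with Sens/Spec/PPV/NPV/Acc/F1, and a
  permutation comparison of the clinical-only model (REG_qEEG−) against
  the clinical + qEEG model (REG_qEEG+): the qEEG feature rows are
  permuted to build the null for ΔAUC.

The synthetic cohort generator (`netsig.synth`) produces recordings as
1/f^|χ| background + band-limited oscillations + lagged delta-band
coupling over a group-specific backbone (lattice-like for the DRE-like
group, integrated for the comparison group) + zero-lag channel mixing,
plus a matched clinical covariate table and full ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study:

```
python analysis/01_simulate_and_extract.py --seed 1
python analysis/02_group_statistics.py --seed 1
python analysis/03_classification.py --seed 1
python analysis/04_estimator_validation.py --seed 1
```

On the default study conditions (60 subjects per group, 180 s, 256 Hz)
this prints, among other lines:

```
significant global features after BH-FDR (q=0.05):
  exponent:              lower in DRE-like  p=0.0000  p_adj=0.0000
  rel_power:alpha        lower in DRE-like  p=0.0000  p_adj=0.0000
  rel_power:delta        higher in DRE-like  p=0.0000  p_adj=0.0000
  btwc:delta             higher in DRE-like  p=0.0010  p_adj=0.0031
  ge:delta               lower in DRE-like  p=0.0010  p_adj=0.0031
  swi:delta              lower in DRE-like  p=0.0020  p_adj=0.0057
ANOVA rel_power: group F=0.28 p=0.6; interaction F=19.40 p_GG=5.8e-06 (eps=0.397)
clinical-only model      AUC = 0.608 ± 0.059
clinical + qEEG model    AUC = 0.986 ± 0.024
added value of qEEG:     dAUC = +0.378, permutation p = 0.000999 (1000 permutations)
```

Reading this: the DRE-like group shows higher relative δ power, lower
relative α power, a more negative spectral exponent, and a δ-band
network with lower global efficiency, lower small-world index and
higher betweenness centrality — the regular, less integrated topology —
and adding the qEEG features to the clinical logistic model raises the
cross-validated AUC significantly. The relative-power ANOVA shows the
group effect as a band × group interaction (relative powers sum to ~1
within subject, so a uniform group shift cancels; the contrast lives in
the band profile). The validation script confirms the estimator
physics: a π/4-lagged coupled pair yields wPLI ≈ 1.00 while zero-lag
mixed independent narrowband sources stay at the estimation noise
floor (≈ 0.10 with 179 Welch segments), and known 1/f exponents are
recovered to 0.013 on average.

A command-line interface over the same library is also available:

```
netsig all --config cfg.yaml --out rundir/   # simulate|extract|stats|classify
```

reading/writing EDF, CSV and JSON intermediates so stages are resumable.

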