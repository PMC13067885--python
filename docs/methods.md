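# Methods

This package reimplements, end to end, an analysis that couples static
balance posturography with fNIRS brain-network topology in a two-group
(mild cognitive impairment, MCI, vs cognitively normal, CN) by
two-condition (eyes open vs eyes closed) design. Because no participant
data are available, a synthetic cohort generator with known ground-truth
effect structure stands in for the experiment; every downstream stage is
validated against it.

## Balance (center-of-pressure) indices

A trial is a 30 s, 1 kHz trajectory of the center of pressure (COP) in the
medio-lateral (ML, x) and anterior-posterior (AP, y) directions, in mm.
Trials are smoothed with a zero-phase 4th-order Butterworth low-pass at
10 Hz (the filter order is a convention of posturography practice; the
zero-phase forward–backward application avoids phase lag and squares the
magnitude response). Seven indices are computed per trial and averaged
over the three trials of a condition:

* RMS displacement about the trial mean, per axis and resultant
  (`RMS² = ML_RMS² + AP_RMS²`, exact per trial, not preserved by
  averaging);
* mean velocity: total path length divided by `T = (n−1)/fs`, per axis
  (`Σ|Δx|/T`) and planar (`Σ√(Δx²+Δy²)/T`); the `(n−1)` convention makes
  constant-speed paths exact;
* sway area: the 95 % confidence ellipse of the (ML, AP) cloud,
  `AREA = π·q·√det(S)` with `S` the 2×2 sample covariance and
  `q = 5.991465` the 0.95 χ² quantile at 2 df. Whether the original
  analysis used a confidence ellipse, a prediction ellipse or a hull is not
  documented; the covariance ellipse is the common choice and is what this
  package means by AREA. Degenerate clouds return 0 with a warning.

Units are mm, mm/s, mm²; magnitudes of the synthetic defaults were chosen
so RMS lands in the published range.

## fNIRS preprocessing

Raw data are two-wavelength (730/850 nm) intensities from 48 channels at
11 Hz with ~3 cm source–detector separation. The chain is:

1. **Optical density**: `ΔOD = −log10(I/Ī)` per channel and wavelength
   (base-10, matching conventional extinction-coefficient units); a
   channel-wise intensity scale cancels exactly.
2. **Motion scrubbing**: a sample is flagged when any 0.5 s window
   containing it has peak-to-peak ΔOD exceeding `sd_factor` (default 10)
   channel standard deviations; flagged runs are linearly interpolated
   (deleting them would break the uniform sampling the filter and
   correlations require), and channels flagged beyond a configurable
   fraction (default 0.5) are marked bad and excluded from ROI averages.
   The underlying published rule ("signal changes exceeding 10 % standard
   deviation within 0.5 s") is ambiguous; this windowed-change reading is
   documented here, not claimed to be bit-identical to the original
   software.
3. **Band-pass 0.01–0.1 Hz**, 3rd-order Butterworth, zero-phase. Two
   finite-window subtleties dominate the numerics at a 0.01 Hz edge whose
   impulse response is as long as the recording: a linear drift, though
   nominally out of band, leaks throughout the passband *coherently across
   channels* (time is shared), so each channel is linearly detrended
   first; and pad-based forward–backward filtering leaks edge transients
   that inflate downstream correlation noise several-fold, so initial
   conditions are chosen by Gustafsson's method instead. With both fixes
   the empirical correlation noise of independent filtered signals matches
   the intrinsic narrowband bound (`sd ≈ 1/√(2BT)`).
4. **Modified Beer–Lambert law**: per channel the 2×2 system
   `ΔOD_λ = d·DPF(λ)·(ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR)` is solved for the
   chromophore changes in μM. Shipped constants are the standard tabulated
   extinction coefficients (ε in mM⁻¹cm⁻¹: 730 nm → 0.390/1.1022, 850 nm
   → 1.058/0.69132) and typical adult differential pathlength factors
   (6.2/5.6); all are configurable. The forward model is exposed so the
   generator can synthesize raw intensities, and forward∘inverse is
   identity to machine precision.
5. **Per-channel mean subtraction** of the concentration series.

ΔHbR is computed and carried, but all downstream analysis uses ΔHbO only.

## ROI connectivity

The 48 channels map onto 10 regions of interest (prefrontal, primary
somatosensory, primary motor, premotor/supplementary motor, visual; left
and right), with channel counts (10, 9, 3, 3, 2, 2, 5, 5, 5, 4) in the
fixed ROI order `L_PFC, R_PFC, L_S1, R_S1, L_M1, R_M1, L_PMC, R_PMC, L_V,
R_V` used for every matrix and nodal output. ROI series are arithmetic
means of member channels (bad channels excluded; a fully-bad ROI is an
error). Functional connectivity is pairwise Pearson correlation with
negatives set to 0 and a Fisher z transform; r is clipped at 0.999999 so
duplicate series stay finite. Zeroing before or after the transform is
equivalent (z(0)=0); it is applied before.

## Network topology over a sparsity sweep

Binary undirected graphs are built by proportional thresholding: keep the
`K = round(s·45)` strongest-z edges (half-up rounding; ties broken by
lexicographic node-pair order, which makes edge sets nested across the
sweep and the whole computation deterministic). The sweep runs
`s = s_min, s_min+0.01, … ≤ 0.50`; with the published minimum 0.2667 that
is 24 thresholds (0.2667…0.4967; the grid never contains 0.50 itself
because 0.2667 + k·0.01 never reaches it). The minimum is determined from
data as the smallest sparsity at which the strongest-edge graph of every
matrix is connected (per matrix: incremental union–find over
weight-ranked edges; cohort: the maximum over matrices — 12 edges of 45 is
exactly 0.2667).

Per threshold the package computes global efficiency
(`Eg = mean 1/d_ij`, with `1/∞ = 0`), local efficiency (mean over nodes of
the neighbour-subgraph global efficiency; degree < 2 contributes 0), nodal
efficiency per ROI, and small-worldness
`σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩)`, where C is the mean binary clustering
coefficient, L the mean shortest path over connected ordered pairs, and
the null ensemble consists of degree-preserving double-edge-swap
randomizations (10× the edge count of attempted-successful swaps;
disconnected nulls are redrawn, cap 100, so L stays finite; for graphs
admitting no swap, e.g. complete graphs, σ = 1 exactly). The ensemble
default is 1,000 nulls; the scaled cohort experiments use 100. The hot
ensemble loop is numba-compiled with a pure-python fallback. Each metric
is summarized over the sweep as `AUC = 0.01 · Σ_k value_k`; all group
statistics operate on these AUCs. Note that per-threshold σ of 1.1–1.5
over a 0.24-wide grid yields AUCs of ~0.27–0.35, the scale on which these
values are reported.

**Connectivity QC.** On noisy 10-node estimates a small fraction of
matrices cannot form a connected graph below the 0.50 density ceiling; the
pipeline excludes such recordings from the network stage (default cap
0.40, logged in the run manifest) and keeps complete cases for the
repeated-measures analyses. The engine itself refuses disconnected graphs
at any grid threshold and directs the caller to the minimum-sparsity
computation.

## Group statistics

* Demographics: pooled-variance independent t (df = n₁+n₂−2) — required
  to reproduce the published values; Welch is available as an option — and
  Pearson χ² without continuity correction (with Yates the published sex
  statistic 2.720 would instead be ≈1.889). One published demographic
  statistic (the cognitive-score t of −9.623) is not reproducible from its
  printed summaries under either pooled or Welch formulas (both give
  ≈ −12.8) and is treated as a typo; no corrected value is asserted.
* Homogeneity: Levene's test, mean-centred (Brown–Forsythe via
  `center="median"`).
* The 2×2 mixed ANOVA uses the classical sums-of-squares partition:
  between stratum SS(group) vs SS(subjects within group); within stratum
  SS(condition) and SS(interaction) vs SS(condition × subjects within
  group); all F at df (1, N−2). With two conditions the within stratum
  reduces exactly to an analysis of per-subject condition differences,
  which is how it is implemented; contrasts are unweighted (cell-mean)
  and coincide with the classical partition for equal group sizes.
  Partial eta squared is `SS_effect/(SS_effect+SS_error)`, identically
  `F/(F+df2)` at df1 = 1 — the identity that lets every published
  (F, η²p) pair be checked arithmetically.
* Simple effects (after a significant interaction): independent t between
  groups within each condition and paired t between conditions within each
  group, two-sided, Bonferroni-adjusted within each two-test family. The
  original adjustment method is unstated; this is a documented choice.
* Multiplicity: Bonferroni with family size 3 across the global metrics
  (σ, Eg, Eloc) and Benjamini–Hochberg FDR across the 10 ROIs for nodal
  efficiency, within each effect. The published text states the split but
  not the family sizes; these are the natural readings.
* Brain–behavior association: sample Pearson r with the two-sided p from
  `t = r√((n−2)/(1−r²))` at n−2 df, computed per group × condition between
  the behavioral indices (AREA, AP-RMS) and the network summaries (σ AUC,
  R-S1 nodal-efficiency AUC).

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested; what it does and does not emulate bounds what the tests show.

**COP.** Sway is a per-axis Ornstein–Uhlenbeck process,
`x ← x − λx·dt + D√dt·ε`, simulated exactly as an AR(1) recursion and
started in its stationary distribution. Mean reversion keeps 30 s trials
stationary (sway is bounded in standing); pure Brownian motion would not
be. Defaults: `λ = 1.0 s⁻¹`; `D = (4.7, 8.2) mm/√s` for (ML, AP), chosen
so stationary RMS (`D/√(2λ)`) is ≈ 3.3/5.8 mm, the published magnitude.
The process has broader velocity bandwidth than human sway, so mean
velocities run high relative to published tables; orderings, not
magnitudes, are the calibration target. Heterogeneity: a per-participant
lognormal diffusion factor (log-sd 0.25) shared across conditions, plus a
per-participant-per-condition factor (log-sd 0.15) — without the second,
condition differences would be nearly noise-free and any effect would be
trivially significant.

**Network templates.** Each participant gets a base Watts–Strogatz
small-world template (10 nodes, degree 4, rewire probability 0.05);
the `randomized` kind, and per-cell partial randomization, apply
degree-preserving double-edge swaps to it. Latent ROI signals are
AR(1)-smoothed Gaussian processes (τ = 0.1 s) mixed to covariance
`Σ = I + c·A`. The default coupling `c = 0.24` sits just under the
Gershgorin bound `c < 1/degree = 0.25` that guarantees positive
definiteness for *every* degree-4 randomization (at c = 0.3 about 5 % of
randomized templates are infeasible). The τ = 0.1 s smoothing keeps raw
330-sample series nearly uncorrelated when coupling is 0 while leaving
ample in-band power.

**Optical channels.** Every channel inherits its ROI's latent signal plus:
a global systemic signal shared by all channels (sd 0.6 — the
physiological baseline that makes real fNIRS correlations predominantly
positive; without it half the estimated correlations are negative and the
published sparsity machinery cannot operate), white channel noise
(sd 0.6), and Mayer/respiratory/cardiac oscillations (0.1/0.3/1.0 Hz,
amplitudes 0.3/0.4/0.6, channel-specific phases emulating local vascular
variability). ΔHbO is the scaled sum (0.5 μM), ΔHbR = −0.4·ΔHbO, pushed
through the forward Beer–Lambert model; drift (random slope, sd
0.01 OD/min) and motion spikes (0.5/min, 12 channel-SD, 2–4 samples, both
wavelengths) are added in optical density, and intensities are
`10^(−ΔOD)`.

**Recording duration** defaults to 600 s per condition. This is the one
deliberately generous parameter: in the 0.01–0.1 Hz band the correlation
estimator has only ≈ 2·0.09·T effective degrees of freedom, and at 300 s
the resulting estimation noise erases most of the thresholded-graph
topology contrast the recovery experiments are designed to detect. The
calibration target is the ordering structure, not any published magnitude.

**Effect structure.** Per group×condition cell: a diffusion multiplier on
sway and a randomization amount (0 = base template, 1 = fully randomized)
on topology. Defaults mirror the published pattern (eyes-closed worse,
MCI-closed worst: diffusion 1.0/1.3/1.0/1.17, randomization
0.1/0.7/0.0/0.25 for MCI-open/MCI-closed/CN-open/CN-closed).
Demographics are drawn per group from the published summary statistics.
Determinism: every unit (participant, condition, trial, stage) draws from
its own seed sequence derived from the master seed, so datasets are
bitwise reproducible and streams are independent.

**What is not emulated** — photon transport and head geometry, spatially
correlated optode noise, serially dependent trials, non-Gaussian sway,
systemic confounds correlated with the task. Passing recovery tests shows
the analysis stack detects the modelled effect structure at realistic
noise levels; it does not certify performance on real recordings.

## Validation experiments (scaled study conditions)

Run at n = 17 per group, 100 nulls per threshold: (1) power — injected
1.5× diffusion in the MCI eyes-closed cell must yield a significant AREA
interaction in ≥ 80 % of 20 replicate cohorts; (2) type-I — null cohorts
reject the interaction at 0.05 ± 0.03 over 200 replicates; (3) topology
recovery — cohorts whose open/closed arms use small-world vs fully
randomized templates order the cohort-mean σ AUC correctly in ≥ 90 % of
20 replicates. Problem sizes were chosen so the whole suite remains
comfortably runnable on one CPU.

## Known limitations

* The generator's velocity magnitudes exceed published values (see above).
* The mixed-ANOVA partition is exact for equal group sizes; with unequal
  groups it follows the unweighted (cell-means) convention.
* σ on 10-node graphs has large per-draw spread (member clustering ranges
  ~0.15–0.5 within one null ensemble); self-normalization holds for
  ensemble means, and all σ-based conclusions are at the cohort-mean
  level.
* The connectivity QC exclusion (density cap 0.40) is a policy this
  package documents, not a published procedure; the published minimum
  sparsity rule is implemented verbatim and used within the retained set.

* Published sway areas are ~4× larger than a 95 % covariance ellipse of
  the published RMS magnitudes implies, so the original AREA method is
  probably not the covariance ellipse this package documents; absolute
  AREA magnitudes are therefore not comparable, only orderings.
* Connectivity QC exclusions are informative: they concentrate in cells
  with strongly randomized templates, so retained-case cell means of σ are
  biased upward precisely where the true σ is lowest. Topology conclusions
  should be drawn from the replicate-level ordering experiments, not from
  a single cohort's retained-case cell means.
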