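# Methods

This note documents the models, conventions and design choices behind
`restmetrics`: what the synthetic cohorts emulate, how each stage is
computed, which knobs matter, and what the validation suite does and does
not establish about real data.

## Synthetic BOLD cohorts

Each subject is a 4D series on an isotropic grid (default 24³ voxels at
3 mm, 186 volumes at TR = 2.17 s, the first 10 discarded downstream). The
"brain" is an ellipsoid filling ~90% of each axis; concentric inner shells
caricature white matter and CSF well enough to drive tissue-mean nuisance
regression. In-brain voxels receive:

- a positive baseline (default 1000, arbitrary units — PerAF divides by it,
  so it must stay positive through preprocessing);
- AR(1) thermal noise (SD 8, lag-1 autocorrelation 0.3), spatially smoothed
  at FWHM 2 voxels and rescaled back to its stationary SD, so that the
  group-level statistic maps are smooth fields — the regime random-field
  theory assumes;
- a linear scanner drift (0.05 units/volume, ~0.9% of baseline over a run)
  and a shared global fluctuation (SD 2);
- inside each effect ROI (a sphere, restricted to "cortex" = brain minus
  the WM/CSF cores), a band-limited oscillation: five sinusoids with
  frequencies drawn uniformly in the ROI's band (default 0.02–0.06 Hz,
  inside the analysis band) and per-subject random phases, rescaled to the
  root-mean-square power of a single sinusoid of the group's amplitude
  (defaults: control 5, patient 3 — patients have reduced amplitude, the
  direction reported for this disorder). With one component the signal is
  exactly `a*sin(2*pi*f*t + phi)`, which the tests exploit: its PerAF is
  2a/(pi*mu) in closed form.

Effects are planted only in cortex deliberately: a sphere overlapping the
WM/CSF cores leaks its oscillation into the tissue-mean regressors and the
nuisance regression then removes the very signal the pipeline is supposed
to detect. The same artifact appears at full strength on toy grids where
one ROI is ~8% of the brain (real cohorts: <1%), which also means the
global-mean regressor removes a small fraction of planted signal here —
a faithful miniature of the global-signal-regression debate.

Motion traces are cumulative Gaussian random walks over the six rigid
parameters (step SD 0.02 mm; rotation steps 100× smaller, in radians).
They never corrupt the images — realignment is out of scope and synthetic
data are generated aligned — but they exercise the Friston-24 expansion,
framewise displacement, and the 3 mm / 3° screening rule (which flags,
never deletes).

Per-subject seeds are spawned deterministically from the cohort seed;
identical configurations reproduce bit-identical volumes and file
checksums.

What the generator does **not** emulate: hemodynamic response shape,
cardiac/respiratory aliasing, susceptibility dropout, motion-correlated
intensity artifacts, anatomical variability, multi-site effects. Passing
tests therefore demonstrate the *statistical machinery* — unbiasedness,
error control, recovery, leak-freedom — not robustness to the full
phenomenology of real fMRI.

## Preprocessing

Order: discard → linear detrend → nuisance regression → (band-pass only on
the branch feeding ReHo). Both detrending and nuisance regression re-add
each voxel's temporal mean: PerAF's μ must remain the raw-scale mean, and
mean-zero residuals would make it undefined. The nuisance design is
[intercept | Friston-24 | wm_mean | csf_mean | global_mean], demeaned,
fitted jointly by OLS per voxel; constant-zero columns are dropped and
rank deficiency is an error naming the collinear columns. The Friston-24
order is: 6 parameters, their one-volume backward lags (first row
zero-padded), squares, lagged squares.

The spectral metrics (ALFF, fALFF, PerAF) are computed on the *unfiltered*
cleaned series: fALFF's denominator needs the full-band spectrum, ALFF
selects its band in the spectrum anyway, and PerAF follows the same branch
for comparability. ReHo is computed on the 0.01–0.08 Hz band-passed series.
The band-pass is an ideal frequency-domain filter (bin retained iff
lo ≤ f_k ≤ hi, closed interval; DC kept so the mean survives).

A practical caveat the test suite surfaced: with short series (~50–60
volumes) the 27 smooth nuisance regressors span most of the low-frequency
DFT bins and largely absorb band-limited signal; at the emulated 186
volumes (~27 in-band bins) the loss is modest. Validation cohorts
therefore use full-length series.

Framewise displacement is the rigid-transform RMS form: with
M = T_i T_{i-1}^{-1} − I decomposed into linear part A and translation b,
FD = sqrt(R²/5 · tr(AᵀA) + bᵀb) over an R = 80 mm sphere; rotations are
composed as R_x R_y R_z in radians. The scalar "mean FD" (mean over frames
2..T) is the group-level covariate.

## Regional metrics

Spectral amplitude convention: demean, DFT, single-sided amplitude
2|X_k|/N for every non-DC bin (any fixed convention cancels under
z-scoring; this one is stated so maps are bit-reproducible). ALFF is the
mean in-band amplitude, fALFF the in-band sum over the full non-DC sum
(0/0 guarded to 0). PerAF is the mean absolute relative deviation × 100;
voxels with near-zero mean are set to 0 and counted, not fatal.

ReHo ranks each voxel's series over time (midranks on ties, no tie
correction in the denominator — the classical formulation; ties are
measure-zero on continuous data) and computes Kendall's W over the cubic
neighborhood (27 default; 19 and 7 supported). Boundary and mask-edge
voxels use their available in-mask neighbors, with the per-voxel K
recorded; out-of-mask voxels are never read (verified by NaN poisoning).

Standardization before group analysis: z (global in-mask mean/SD,
population convention) for ALFF and fALFF; division by the global in-mask
mean for ReHo and — by this package's choice, since the convention for
PerAF is not settled — for PerAF too (a config switch selects z instead).
Maps are standardized first and then smoothed at 6 mm FWHM with a
mask-aware kernel (out-of-mask voxels excluded from the normalization, so
constants are preserved at the mask edge); a config switch moves smoothing
before metric computation instead.

## Group inference

Per voxel, OLS of the map value on [intercept | group indicator | demeaned
covariates]; the t statistic tests the patient-minus-control contrast with
df = n − rank(design). Smoothness is estimated from the standardized,
per-voxel-unit-variance residuals: along each axis,
FWHM = sqrt(4 ln 2 / var(Δ)) voxel units, where var(Δ) pools first
differences over subjects and in-mask pairs (exact 1.1774 voxels for white
noise; asymptotically the true FWHM for smooth Gaussian fields). Resels =
mask voxels / (FWHM_x FWHM_y FWHM_z).

Cluster correction: the voxel threshold is the two-tailed t quantile,
converted to its z-equivalent by quantile matching; positive and negative
excursions are clustered separately (26-connectivity default) so clusters
are sign-homogeneous. For a cluster of k voxels the corrected p combines
the expected cluster count from the 3D Euler-characteristic density,
E[m] = R (4 ln 2)^{3/2} (2π)^{-2} (u²−1) e^{−u²/2}, with the exponential
extent tail P(N ≥ k) = exp(−β k^{2/3}), β = (Γ(5/2)/E[n])^{2/3}, as
p = 1 − exp(−E[m] P(N ≥ k)). Lower-dimensional boundary terms are omitted
(adequate for interior masks at these scales); the permutation oracle —
max-cluster-extent null over label permutations, covariates kept with
subjects — is the empirical cross-check, and on smooth nulls the analytic
and empirical corrected p agree within a factor of two over the
informative range. A cluster is retained iff corrected p < cluster_p
*and* extent > min_extent (defaults 0.01 and 100 voxels; reduced-scale
validation uses extent > 20 on a 16³ grid).

## Classification

Features are cluster means of the standardized smoothed maps over the
regions surviving group inference. The central property is leak-freedom:
in the default `per_fold_rois` mode the entire screening (GLM + cluster
correction) is re-run on the 39 training subjects of every outer
leave-one-out fold, feature scaling uses training statistics only, and a
stratified 5-fold inner grid search picks (C, γ) for an RBF SVM on the
classical power-of-4 LIBSVM grid (C: 2⁻⁵…2¹⁵, γ: 2⁻¹⁵…2³; ties go to the
smallest C, then γ). Folds whose screening finds no cluster fall back to
one whole-mask-mean feature per metric (logged). The "Total" model
concatenates all four metrics' per-fold features. AUC is the rank
statistic over pooled outer-fold decision values (ties half), identical to
the trapezoidal area under the ROC staircase.

Two properties of leave-one-out worth knowing when reading permutation
baselines. First, on a perfectly balanced null cohort the training
majority is always the class opposite the held-out subject, so degenerate
(majority-vote) fits are systematically *wrong* and permuted-label
accuracy sits below 50% — a pessimistic bias documented for LOO
generally; class-balanced penalties merely flip it (minority-vote,
above-chance). Leakage, by contrast, inflates accuracy *above* chance, so
the no-leakage check bounds the permuted mean strictly from above at the
pooled-binomial band while allowing the cohort-size binomial band below.
Second, a mild group imbalance (validation uses 21/19, the same proportion
as the emulated 45/40 study) pins the degenerate regime near 52.5% rather
than 0%, which is why the validation cohorts are not perfectly balanced.

## Validation scale and numerical choices

The acceptance checks run at desk scale, as the package's own choice of
validation conditions: 16³ grids, 186 volumes, 20+20 (recovery) and 21/19
(classification) subjects, extent rule 20 voxels, 200 null simulations for
error-rate checks, 500 label permutations for the oracle, a 3×3 (C, γ)
grid for the nested SVM. Planted-effect recovery requires the in-ROI
standardized group difference to reach 1.5 before detection is asserted;
the generator defaults produce ~3 at these sizes. Determinism is enforced
end to end: reports are JSON with sorted keys, NIfTI writing is
deterministic, and re-running from a provenance record must reproduce
byte-identical reports.

Degenerate inputs are contracts, not crashes, where a scientist needs the
map anyway (zero-mean PerAF voxels, empty cluster tables); they are hard
errors where silence would corrupt inference (rank-deficient designs,
empty masks, bands outside (0, Nyquist], cluster-forming z ≤ 1).

## Known limitations

Registration-dependent steps (slice timing, realignment, MNI
normalization) are out of scope — synthetic data are generated aligned, so
anatomical (atlas) labeling of clusters is also absent. The GRF expected
cluster count uses only the 3D EC term. The LOO permutation baseline's
below-chance bias means permuted-label accuracies should be read against
the documented band, not naively against 50%. Nothing here validates
robustness to physiological noise or real head motion; the generator's
scope is the statistical pipeline itself.
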