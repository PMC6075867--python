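# Methods

`azquant` implements optical quantal analysis of glutamatergic synapses at the
*Drosophila* larval neuromuscular junction (NMJ): single-vesicle fusion events
are visualized as postsynaptic Ca²⁺-indicator flashes, mapped onto individual
active zones (AZs), and converted into per-AZ release probabilities, together
with the structural correlates of release strength (Ca²⁺-channel/scaffold
intensity, glutamate-receptor-field morphology) and their development over
days. Because the raw imaging data of such studies are rarely deposited, the
package pairs the analysis chain with a synthetic-data generator whose
defaults encode the published summary statistics, so every pipeline stage can
be validated against known ground truth.

## Release model

Release at AZ *i* is Bernoulli per stimulus with probability `p_i` (at most
one vesicle per AZ per action potential — quantal imaging cannot resolve
multivesicular release, which is out of scope) plus homogeneous-Poisson
spontaneous fusion at rate `s` per non-silent AZ. The estimator is the
empirical one used in quantal imaging: `p̂_i = events_i / stimuli`, with
spontaneous rate `ŝ_i = spontaneous events_i / duration`.

The population of `p_i` over all PSD-defined AZs is a three-part mixture:

- silent AZs (14.6%): no evoked or spontaneous release;
- spontaneous-only AZs (9.7%): `p_i = 0`, Poisson fusion only;
- active AZs (75.7%): `p_i` from a two-component gamma mixture,
  `(1−f_m)·Gamma(k=1.8, mean 0.0442) + f_m·Gamma(k=60, mean 0.355)` with
  `f_m = 0.168`, capped at 0.73.

The second ("mature") mode represents the small cohort of old, fully
matured AZs that dominate release; the developmental module generates exactly
this structure mechanistically (release strength grows with AZ age, and AZ
birth is ongoing, so a minority of AZs is old and strong at any time).

**Calibration criterion.** The committed constants
(`scripts/calibrate_pr_mixture.py`) are fixed by four measurement-level
targets: mean Pr 0.073 over all AZs; ~9.9% of AZs above the mean + 2 SD of
the *estimated* `p̂` at the reference stimulation protocol (0.3 Hz × 5 min,
~100 stimuli); high/low class-mean contrast near 5.7-fold; skewness near
2.2. Two points deserve emphasis:

1. The mean+2SD exceedance is calibrated on binomial *estimates*, not on the
   latent `p_i`, because the reference numbers are themselves estimates made
   through that protocol; estimation noise inflates the population SD (and
   hence the threshold), so the latent-level exceedance is higher (~11%).
2. A *single* capped gamma for the active mode cannot satisfy the targets
   jointly: with its mean pinned at 0.073, its mean+2SD exceedance never
   exceeds ~6.6% for any shape (the calibration script reproduces this
   bound). The published group means (0.049 low / 0.277 high with 9.9% high)
   also imply an overall mean near 0.060 rather than the printed 0.073; the
   calibration privileges the printed overall mean and the printed class
   fractions, accepting group means near 0.06/0.38. This tension is inherent
   to the published summaries and is documented rather than resolved.

## Movie generation

Movies are single focal planes at 0.138 µm/pixel and ~7.7 Hz (0.13 s frame
interval). Each fusion event renders an isotropic Gaussian flash
(σ = 0.2 µm, diffraction-limited single-AZ signal) with single-frame rise,
peak amplitude 40 AU, and exponential decay (τ = 0.26 s, two frame
intervals). The baseline (100 AU) carries a static membrane-like texture
(smoothed Gaussian field, SD 12 AU, correlation length 0.7 µm) emulating the
structured resting fluorescence of a membrane-targeted indicator — this is
what makes translational registration well-posed, exactly as at a real NMJ.
Photobleaching is exponential (τ = 2000 s, ~14% over a 5-min recording);
per-pixel Gaussian noise has SD 4 AU (post-filter flash SNR ≈ 19); field
drift is a Gaussian random walk (default step 0, set per experiment).

AZ layouts are dart-thrown with a hard minimum separation (default 0.6 µm,
~1 AZ/µm² at NMJ-like density); a configurable fraction of AZs can be
planted closer than 0.28 µm to a partner to emulate optically unresolvable
AZ pairs. Structural channels (Cac/BRP/GluRIIA/GluRIIB analogues) render one
Gaussian punctum per AZ (σ = 0.18 µm) with amplitudes constructed as
`mean + sd·(r·z(p) + √(1−r²)·ε)`, which gives Pearson correlation exactly
`r` with `p` (default 0.61, the published Cac–Pr coupling); amplitudes are
floored at the detection floor since an undetectable PSD would not define an
AZ.

## Analysis chain

Processing follows the standard quantal-imaging order:

1. **Fine Gaussian filter**, σ = 1 px (the source workflow's "fine" setting
   is unquantified; 1 px is the conventional choice and is configurable).
2. **Rigid registration** by phase cross-correlation against a reference
   frame with subpixel refinement (upsample 10). A candidate shift is only
   applied if it measurably improves frame-to-reference correlation;
   otherwise the frame is flagged ambiguous and left in place — this guards
   against spurious correlation peaks on featureless or flash-dominated
   frames. Within `analyze_movie` shifts are estimated on 2×-binned frames
   (0.1 px precision, four-fold cheaper; the registration contract is
   0.25 px). Rotation is not modeled (rigid translation assumed).
3. **Quiet-composite baseline subtraction**: the per-pixel mean of 5 frames
   without synaptic release is subtracted from every frame. "Auto" selection
   takes the lowest-sum frames at or above the median-frame floor; the
   frames used are recorded for reproducibility. Output may be negative.
4. **Spot detection** on the structural channel: local maxima above
   background median + 4 robust SDs, greedy Euclidean suppression
   (brightest kept) below the minimum separation (default 0.45 µm), 3×3
   intensity-weighted subpixel centroids.
5. **Event detection**: per-frame thresholding at 4× the per-pixel noise SD
   (temporal MAD, estimated and applied on frame-median-subtracted data so
   the residual bleaching trend left by composite subtraction is not
   mistaken for noise), 8-connected components with area ≥ 8 px and peak ≥
   (4+3)× noise SD (flashes peak ≥ 11 SD after filtering, so the peak
   criterion costs no sensitivity while keeping false positives below 1 per
   1000 frames even at a 3 SD threshold). Components at the same site on
   consecutive frames are one decaying flash and merge into the onset event;
   a one-frame gap starts a new event.
6. **Assignment** of each event to the nearest AZ centroid within 0.5 µm
   (the nearest-centroid reformulation of fixed 5-px ROI capture: identical
   for well-separated AZs, well-defined under overlap). Exact ties break to
   the lower AZ id; out-of-range events stay unassigned with a reason.
7. **Evoked/spontaneous split** by a post-stimulus window (default 0.3 s,
   2–3 frames; it must not exceed the inter-stimulus interval — for 5 Hz
   trains use 0.15 s). At most one evoked event per (AZ, stimulus); extras
   are relabelled spontaneous.
8. **Classification** with the mean + 2 SD rule over *all* PSD-defined AZs
   (silent included, population SD; the sample-SD variant is exposed).
   Classes — high, low, spontaneous-only, silent — partition the table.

## Morphometry and development

PSD profiles are radially averaged (rotation-invariant; a line mode oriented
for channel-B flank symmetry mirrors manually drawn line profiles) with
cubic-spline image sampling, then min–max normalized, making ring calls
invariant to affine intensity scaling. The ring criterion is a central dip
greater than 10% of the mean flank maximum (the denominator is a
documented choice; relative-to-global-max is selectable). FWHM diameters use
linear interpolation at the half maximum over an edge-plateau background
(outer 10% of samples).

The developmental generator grows the AZ population geometrically (default
1.9×/day) with continuous growth-law birth times; each AZ matures along
saturating trajectories (Pr toward a mixture-drawn target; receptor-field
diameters toward the mature 0.59/1.01 µm geometry; channel-B central dip
rising only after a 2-day structural floor and crossing the 10% ring
criterion at age `2 + Gamma(16)/activity` days, mean 3.2 at activity 1).
The concentrated delay (SD ≈ 0.3 d) reflects reported clustering of
segregation onset, with a small fast tail but never below 2 days. An
activity factor scales both maturation rate and AZ addition, reproducing the
direction of activity-mutant effects; magnitudes are free parameters, not
fits. A rab3-like flag silences a configured fraction of AZs presynaptically
(zero channel intensity, zero release, no ring) while concentrating
intensity in the remainder.

Cross-session identity is recovered geometrically: the inter-session
translation is the mode of all A→B displacement vectors (nearest-neighbour
pairing alone fails once drift exceeds AZ spacing), refined by the median of
the consensus cluster, followed by mutual-nearest-neighbour matching within
1 µm. Chained correspondences give persistent tracks; AZs present in the
first session are left-censored and excluded from maturation means; the
days-to-ring measurement is interval-censored at the session spacing and
takes the first ring-positive session's timestamp. Gap bridging is off by
default and logged when enabled. Note that with a finite observation window
the observed mean days-to-ring carries a small (≈ −0.1 d) truncation bias —
slow late-born AZs never ring inside the window — which affects any
equally-windowed empirical estimate the same way.

## Problem sizes

The classification recovery uses 2,000 AZs × 100 stimuli (≈ 2,300 frames of
a ~420² px field) per seed — 10 seeds in the acceptance script, 2 in the test
suite; rate recoveries use 500–1,000 AZs over 120–300 s; the developmental
recovery tracks ≈ 150 initial AZs over 6 daily sessions (≥ 300 uncensored
matured tracks). These sizes give Monte-Carlo errors comfortably inside the
stated tolerances.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis assumes:
punctate layouts, Bernoulli/Poisson release, diffraction-limited flashes
with realistic SNR, bleaching, drift, intensity–Pr coupling, core/ring PSD
geometry, and growth/maturation dynamics. It does not emulate indicator
saturation or dye dynamics (flash amplitude is constant across AZs), bouton
geometry or out-of-focus light, non-rigid tissue deformation, spectral
bleed-through, or biophysical Ca²⁺ buffering. Passing recoveries therefore
validate the estimator chain under the stated model, not the microscope
physics; on real data the practical limits are detection SNR and the
rigid-translation assumption of the movement correction.

## Numerical and degenerate-input choices

Noise-free stacks (zero estimated noise SD) fall back to an absolute event
threshold at 10% of the stack maximum, with a warning. All-equal Pr or
intensity populations yield zero high/bright AZs (strict inequality at the
threshold). Unimodal profiles get dip 0; profiles never crossing the half
maximum get an undefined (flagged) diameter. Gamma draws above the Pr cap
are resampled, and configurations whose cap would discard > 5% of the gamma
mass are rejected as miscalibrated. Fixed seeds make every generator output
bit-identical; analysis stages are deterministic throughout.
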