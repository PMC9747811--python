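# Methods notes

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Stimulus model

A protocol is a gap-free, non-overlapping event list on a half-open time
axis (`[onset, onset+duration)`, seconds from protocol start): 300 s of
static mean gray (spontaneous activity), then per contrast a 60 s gray
baseline followed by 20 alternating 1 s white / 1 s black flash pairs.
Contrast is Michelson on the 0–100 scale; flash luminances are symmetric
around the mean gray, so `contrast_pair(g, ct)` returns
`(g(1+ct/100), g(1−ct/100))` and inverts `michelson_contrast` exactly.
Luminance is a linear scalar; the mesopic/photopic regime tag
(0.092 / 9.20 cd/m²) is metadata only — contrast arithmetic is
regime-independent. Block presentation order is ascending CT by default and
configurable; the per-block 60 s gray baseline doubles as the inter-block
gray interval. (Presentation order and inter-block gray duration are
conventions of this package; nothing downstream depends on them.)

## Spike-train conventions

- Phase 0 = white onset; `[0,1)` s is the white half, `[1,2)` the black.
- PSTH: 10 ms bins, rate(b) = pooled count / (n_trials × bin width), so
  `sum(rates)·bin·n_trials` returns the pooled count exactly (to float
  round-off, < 1e−9).
- Cumulative cycle distribution: spikes pooled across trials (per-trial
  CDFs are not retained), evaluated on a fixed 200-point grid of 10 ms
  right bin edges. Pooling matches the trial-averaged curves such
  recordings are summarized by; the 10 ms grid matches the PSTH bin.
- The 0.1 spikes/s rate floor is evaluated on the 5 min spontaneous gray
  segment, inclusive ("at least").

## Template library and matching

The eight canonical CDFs are built from parametric kernels: uniform mass on
the preferred half (sustained), an exponential burst with τ = 80 ms at the
preferred onset (transient), mixtures 50/50, 70/30, 30/70 of the two onset
bursts (ON–OFF), and a delayed sustained variant (mass on [0.2, 1) s).
Matching is a single greedy pass: sup-norm distance to each template,
minimum wins, ties to library order, distance strictly greater than
θ = 0.25 ⇒ NA. Sup-norm is the natural scale-free metric on CDFs (an L2
option exists). Because the CDF ignores spike counts, calls are exactly
invariant to spike duplication.

Consequences worth knowing: an idealized *instantaneous* burst is
sup-distance ≥ 0.5 from every template (its step outruns the τ = 80 ms
kernels), so it is NA — only kinetically plausible responses match; and a
unit firing uniformly over the whole cycle sits ≈ 0.31 from its nearest
template, also NA. Template curves, count and θ are this package's
construction, configurable and serialized with every run.

## Clustering

PCA is mean-centered; the component count is the smallest reaching 90%
explained variance (degenerate all-identical input returns one zero
component). k-means is seeded, best of 10 restarts, clusters renumbered by
descending size (ties by first appearance) so outputs are byte-stable for a
fixed seed. k is scanned over 2–20 and chosen by maximal mean silhouette
width; when even the best mean silhouette is below 0.25 the selection is
flagged unconfident (on isotropic low-dimensional data k-means always
produces moderate silhouettes, so the floor is meaningful only in the
feature space actually used). Units are pooled across genotypes and ZTs
within a polarity class and regime before clustering; genotype effects are
then assessed as per-cluster composition tests (per-retina proportions as
replicates, t-test, Holm–Šídák within the class). Note that proportions sum
to one within a retina, so a real enrichment of one cluster necessarily
depresses the others — the composition test family should be read jointly,
not cluster by cluster.

## Daily statistics

Peak rate is the maximum 10 ms PSTH bin within the preferred half-cycle (no
latency exclusion window is applied). ON–OFF units are excluded from peak
analysis (their preference is ambient-dependent) but retained in
polarity-maintenance accounting, where NA-in-either-regime units form their
own group excluded from the maintained/switched denominator. The
control-normalization denominator is the maximum control cluster-mean peak
across contrasts *within each ZT* (a per-day variant — maximum across the
whole day — is available as a config switch). Fisher tests on maintenance
pool cell counts across retinae.

## Cosinor

The fixed-period (24 h) cosine is fit by the standard linearization, an
ordinary least-squares problem, so noiseless inputs are recovered to
machine precision at any acrophase, including ones aliased across the
4-point ZT grid. Amplitude = √(β²+γ²) ≥ 0 by construction; acrophase =
atan2(γ,β)/ω mod 24. Model selection: cosine if the extra-sum-of-squares F
test against the flat line gives p < 0.05; else linear if the slope t-test
does; else flat. A perfect cosine fit (zero residual) is treated as
infinitely strong evidence for the cosine. The D'Agostino–Pearson K2 check
is skipped below 8 residuals or on degenerate residuals. Replicates enter
the fit individually (no ZT24 duplication; display conventions are not
data).

## ERG

The a-wave trough is the *deepest sub-baseline sample* within 0–100 ms
post-flash ("first negative deflection" is operationalized by the window):
on noisy averaged traces a first-local-minimum rule latches onto microvolt
noise dips before the true trough, while the window minimum is identical on
clean waveforms and robust under noise. The b-wave is the maximum after the
trough within 300 ms, minus the trough voltage; traces with no a-wave
(common photopically) fall back to baseline-referenced b-waves and are
flagged. Both amplitudes are invariant to constant voltage offsets. Search
windows follow standard murine flash-ERG timing and are configurable.
Oscillatory potentials are not removed.

## Synthetic-data generator

**Spikes.** Each unit is an exact superposition of a homogeneous Poisson
baseline over the whole protocol and per-trial evoked Poisson components
(counts drawn per cycle, event times by inverse CDF — no time
discretization). Evoked strength scales as a Naka–Rushton contrast term
CT/(CT+30) and a (genotype, ZT) gain factor. Defaults, chosen once as
realistic mesopic RGC numbers and then left alone: baseline 0.5 spikes/s
(above the 0.1 floor), sustained gain 25 spikes/s, transient gain
120 spikes/s with τ = 80 ms, ON–OFF burst gain 100 spikes/s, latency 0 so
generator kinetics are phase-locked to the template library. At CT100 these
give roughly 100–400 evoked spikes per 20-trial block — enough that the
baseline's uniform "dilution" of the cycle CDF (~0.1 sup-norm) plus
empirical-CDF fluctuation stays inside θ. Poisson spiking (no
refractoriness) suffices for every property tested; a 1.5 ms absolute
refractory option exists for ISI realism. The default effect table encodes
the injectable ground truths used in recovery tests: knockout evoked gain
×1.5 at ZT18, and elevated OFF→ON–OFF switch probability in the photopic
knockout at ZT0 (0.5 vs 0.2 in controls).

**Expression.** value = baseline + A·cos(2π(t−φ)/24) + N(0,σ) at
ZT 0/6/12/18; the knockout acrophase is the control's plus a configurable
shift (−4 h in the recovery suite). Default σ = 0.2·A, 6 replicates per ZT.

**ERG.** The a- and b-deflections are disjoint raised-cosine kernels with
peaks snapped to the sampling grid (16.3 kHz) and the b kernel's height set
to b−a, so extraction returns the generating amplitudes *exactly* at zero
noise (this requires b ≥ a, which holds for these waveforms). Trace noise
is band-limited (white noise smoothed to ~1 ms correlation, renormalized to
the requested SD), consistent with a 0.2–5000 Hz acquisition band;
broadband per-sample noise would bias extremum-based amplitude readings
upward by σ√(2 ln n).

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: receptive-field structure and spatial
stimuli, adaptation and trial-order effects, bursting/refractory ISI
structure (by default), electrode geometry and sorting errors, correlated
noise across units, qPCR efficiency differences, oscillatory potentials. In
particular the cohort has exactly two kinetic kernels per polarity class,
so its silhouette-selected k is small (k = 2) and should not be compared to
the cluster counts reported for real retinae.

## Problem sizes and calibration choices

Recovery and calibration experiments run at the package's standard sizes:
300 units per kinetic class for classifier recovery with 200 thinning
seeds; 240 units (4 kernels × 60) for clustering recovery; 500 seeds for
cosinor recovery and phase-shift recovery; 800/500/1000 null replicates for
the responsiveness / ANOVA / genotype-KS type-I rates; 40 injected-effect
configurations and 200 null configurations for gain detection. The default
synthetic cohort uses 110 units per retina (a scaled-down version of the
~530-unit average population) and 2 retinae per group so a full pipeline
run takes seconds.

The genotype-KS null calibration uses 500 cells per arm, the order of
pooled per-stratum cell counts in large-scale recordings. At a few dozen
cells per arm the exact two-sample KS test is intrinsically conservative
(discrete null; measured size 3–4% at nominal 5%), which is a limitation to
keep in mind when reading per-stratum p-values at small n — the package
reports those p-values as scipy computes them.

## Known limitations

- Template matching assumes response kinetics broadly similar to the
  canonical kernels; exotic cell types (direction-selective, suppressed-by-
  contrast) would land in NA.
- The polarity-maintenance Fisher test pools cells across retinae and so
  inherits any between-retina heterogeneity.
- Peak rates are quantized at 1/(n_trials·bin) spikes/s, which contributes
  ties to the per-stratum KS tests (making them conservative).
- The cosinor assumes a single 24 h harmonic; multi-harmonic waveforms
  alias on a 4-point ZT grid.
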