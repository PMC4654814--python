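# Methods

This note documents the models, parameter choices and numerical
decisions behind `rctcnv`, and what the synthetic-data experiments do
and do not demonstrate.

## Generative model for dosage-assay signals

Raw signals (MLPA peak heights, molecule counts) are simulated as

    y(s,p) = BASE · A_s · E_p · (c(s,g)/2) · b(s,p) · d(s) · exp(ε)

* `A_s = exp(N(0, amp_sd²))` — per-sample amplification/input factor
  (default `amp_sd` 0.3). Cancelled exactly by intra-sample
  normalization; its size is therefore uncritical and chosen large
  enough that un-normalized signals are visibly incomparable across
  samples.
* `E_p = exp(N(0, probe_eff_sd²))` — per-probe efficiency, constant
  across samples (default 0.2). Cancelled by inter-sample
  normalization against reference samples.
* `c(s,g)` — true copies; reference and ligation-control probes behave
  as two-copy loci.
* `b(s,p)` — 0.5 when sample *s* is heterozygous for a ligation-site
  variant under MLPA probe *p*, 1 otherwise. A fixed halving reproduces
  the observed artifact ratios (~0.55) without modeling ligation
  chemistry. The orthogonal count assay has no `b` term: its probes
  bind different regions of the gene, which is precisely what makes the
  artifact detectable by platform comparison.
* `d(s)` — denaturation factor: in denaturation-failure samples
  (default rate 1%) all genomic probes drop to 0.5 while the
  denaturation-control probes, silent otherwise, emit full signal; this
  gives per-sample QC a realistic failure mode to catch. Ligation
  failure (rate 0 by default) silences the ligation control.
* `ε ~ N(0, σ²)` with `σ = sigma_mlpa = sigma_count = 0.05` —
  multiplicative lognormal noise. Signals are positive and instrument
  noise scales with signal, so a lognormal is the natural choice; 5%
  reproduces the observed scale of replicate standard deviations
  (< ±0.05 on ratios near 1) and reference-probe interquartile ranges
  (~0.04–0.09).

Cohort defaults encode the regime the screen was designed for: 320
samples, 16 genes, per-gene single-copy-loss probability 0.003 (rare
losses, expected ~15 per cohort), no gains, ligation-site heterozygote
frequency 0.006 at the APOA4-like probe. Expression is
`x = μ_g + beta_expr·log2(c/2) + N(0, expr_sd²)` with `μ_g ~ N(8, 1)`
(typical log2 microarray intensity), `beta_expr = 0` by default (no
dosage effect — the observed regime) and the dosage term floored at −5
(≈3% of diploid expression) so homozygous losses stay finite. Lipids:
HDL ~ N(45, 12), LDL ~ N(125, 25) truncated positive, 10% missing LDL,
triglycerides lognormal around 130 mg/dL, total cholesterol derived
with noise; 65% HIV-positive of whom ~70% receive therapy. These
marginals put realistic mass in all NCEP strata at n ≈ 320; the sheet
does not attempt to reproduce any real cohort's joint distribution,
correlations between lipids and covariates, or batch structure.

Every generator draws from an independent, seed-derived stream
(`SeedSequence(seed, spawn_key)`), so simulated MLPA and count tables
are genuinely independent replicates of the same truth, and repeated
MLPA runs (different `stream`) are true technical replicates.

## Normalization and QC

Intra-sample normalization divides each probe by the geometric mean of
the sample's reference probes — the right location estimate under
multiplicative noise, and exactly scale-invariant: rescaling a sample's
whole peak vector leaves its ratios unchanged to 1e-9 (asserted).
Samples with any non-positive reference signal are unnormalizable.

Per-sample QC (cut-offs are package choices, stated in `Thresholds` and
logged, since only "poor reference probe quality" is specified
upstream): reference-probe CV > 0.30; denaturation-control signal
> 10% of mean reference signal; ligation-control signal < 10% of it.

Reference samples are the *k* samples minimizing the mean relative
deviation from the cohort-mean profile over target + reference probes
(controls excluded — their near-zero means make relative deviation
meaningless). `k` defaults to max(5, 10% of the surviving cohort) for
MLPA and 34 for the count assay; ties break by sample id, making
selection order-independent. The workflow is two-pass: provisional
normalization → QC exclusions → reference selection among survivors →
ratios, so a failed sample can neither be a calibrator nor receive a
ratio. Ratios divide by the reference-sample mean per probe, so the
reference set's mean ratio is exactly 1; re-normalizing a ratio matrix
against the same references is a no-op (idempotence, asserted).

## Calling

Threshold calling uses the conventional dosage-quotient bounds, loss
< 0.7 and gain > 1.3, with an explicit borderline class within
`boundary_tol` (1e-9) of a cut-off. The borderline class *counts as
flagged*: a ratio exactly on 0.7 indicates a possible loss that needs
orthogonal follow-up, and collapsing it into "normal" would silently
drop exactly the calls that are hardest to interpret. No
multiple-testing correction is applied — these are fixed instrument
cut-offs, not per-probe hypothesis tests.

Anchored cluster calling (for loci with known-copy controls)
calibrates a single multiplicative scale as the geometric mean of
`ratio/(copies/2)` over the anchors (anchors whose implied scales
disagree by > 25% are rejected as contradictory), assigns each sample
to the nearest center `(c/2)·scale` on the log scale (copy 0, which has
no log center, is called below the linear midpoint `0.25·scale`), then
re-estimates the scale from all assigned samples and iterates
assignment to a fixed point (≤ 25 deterministic passes). Refining the
shared scale rather than free per-cluster means exploits the structural
constraint centers ∝ copies, corrects anchor miscalibration — the
dominant error source — and is well defined even for singleton
clusters. Copies are capped at 12, beyond the range multicopy QC panels
target.

At σ = 0.05 the log-scale noise on a raw ratio is σ√(1 + 1/16) ≈ 0.052
while adjacent high-copy centers differ by ln(7/6)/2 ≈ 0.077 in
half-gap, so the 6↔7 boundary carries an irreducible ~7% per-tail
misassignment: panel accuracy ≈ 95–96% is the *intrinsic limit* of any
caller under this noise model, not an implementation shortfall.
Passing the 95% recovery test therefore shows the caller operates at
that limit; averaging duplicate runs would push accuracy above 99%.

## Cross-platform confirmation

Verdicts partition the flagged MLPA calls: loss on both platforms →
`confirmed_loss`; gain on both → `confirmed_gain`; unambiguous MLPA
loss with normal orthogonal ratio → `artifact_suspected`; borderline
MLPA loss with normal orthogonal ratio → `unconfirmed_borderline`; any
other pattern → `discordant_unexplained`; no orthogonal measurement →
`untested`. The artifact verdict is deliberately asymmetric —
binding-site artifacts are platform-specific by mechanism — and carries
a caveat that a small CNV covering the MLPA probe but not the counting
probe cannot be excluded without sequencing; sequencing itself is out
of scope and collapsed into this verdict + caveat. The headline
statistic is 100 × (confirmed losses + gains) / cohort size, one
decimal place; the cohort denominator is caller-supplied, since
different stages of a real screen type different sample subsets (e.g.
366 selected / 319 MLPA-typed / 267 confirmation-typed), and the
package does not attempt to reconcile those counts.

## Phenotypes and association

NCEP ATP III bounds are inclusive (≤/≥), following the definitions
that carry the published group counts (the alternative strict reading
appears in some method statements but is inconsistent with those
counts): atheroprotective = HDL ≥ 60 and LDL ≤ 100 mg/dL; atherogenic =
HDL ≤ 40 and LDL ≥ 160; screen eligibility from any single criterion
(HDL ≤ 40 or ≥ 60; LDL ≤ 100 or ≥ 130). Missing LDL →
group `unclassified` (HDL alone can still establish eligibility).

CNV–lipid comparison reports median (IQR) HDL/LDL for carriers vs
non-carriers per gene and runs a two-sided Mann–Whitney test only with
≥ 3 carriers; below that the row is marked underpowered and no p-value
is emitted — rare-variant screens should refuse to over-interpret
single carriers.

CNV–expression association regresses log2 expression on log2(ratio)
(floored at −5) per expression column, mapping `GENE_k` transcript
variants to their gene's ratio. On the dosage scale the fitted slope
directly estimates the generative coefficient `beta_expr` (regression
on the raw ratio is available via `dosage_scale=False` but its slope is
a rescaled, mixture-dependent quantity). Genes with numerically zero
ratio variance are reported as non-assessable — the expected situation
when CNV is absent. Unadjusted p-values are the primary surface, with a
Benjamini–Hochberg column across assessable genes. Type-I error at
`beta_expr = 0` and slope unbiasedness at `beta_expr = 1` are verified
over 200 replicate cohorts (binomial 99% band; 2-SE band), using true
copy ratios as the regressor so the properties of the *estimator* are
isolated from measurement-noise attenuation, which on noisy ratios
biases slopes toward zero by ~5% at σ = 0.05.

## Problem sizes and determinism

Tests and recovery experiments use the defaults they validate
(n = 320 cohorts; 120-sample multicopy panels; 200–500 replicate
mini-simulations for error-rate checks, with replicate streams derived
from fixed base seeds). All randomness flows through
`SimulationConfig.seed`; identical seeds give byte-identical outputs,
and report writers emit deterministic bytes (fixed column order and
float formats, sorted JSON keys).

## Known limitations

* One probe per gene: intragenic CNV smaller than the probe footprint,
  and repeat-length variation (e.g. LPA kringle repeats), are invisible
  by design.
* The generator does not emulate fragment-size electrophoresis, PCR
  kinetics, sequence-dependent probe binding, GC effects, batch drift,
  or vendor file formats (.fsa/RCC/IDAT); tables enter as plain CSV.
* Passing recovery tests shows the pipeline inverts its own generative
  model at realistic noise; real assay noise need not be lognormal or
  probe-independent, and real cohorts have lipid–covariate correlations
  the sample sheet lacks.
* The artifact verdict is evidence of a platform-specific binding
  problem, not proof: only sequencing distinguishes it from a small CNV
  under one probe.
* Therapy and ancestry labels are pass-through covariates; no
  therapy-effect or ancestry modeling is attempted.
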