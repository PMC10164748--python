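# Methods

## Assay model and normalization

The unit of observation is one well: lung epithelial cells, optionally one
or two bacterial species at defined MOIs, optionally a pro-inflammatory
stimulus, one read-out. Raw signals are expressed per plate as a percentage
of the mean of the matched control wells — the stimulus-alone wells for
inflammatory read-outs (NF-κB luminescence, IL-8), the uninfected untreated
wells for viability. The control mean (not median) is used, so control
replicates average to exactly 100% on each plate, and normalization is
invariant to rescaling a plate's raw signal. Controls are matched *per
plate*; whether real experiments pooled controls per day instead is not
inferable from the assay design, so per-plate is the default and the only
implemented policy.

Doses live on 1:4 serial-dilution ladders. A dose is stored as
`base × 4⁻ˢᵗᵉᵖ` and never as the result of repeated floating division, so
dose ratios are exact in binary floating point (0.78125/12.5 = 0.0625
exactly). Display values round to two decimals (half away from zero),
falling back to one significant digit when two decimals would print 0.00;
this reproduces the conventional printed grid 50, 12.5, 3.13, 0.78, 0.2,
0.05, 0.01, 0.003 while keeping at most three significant digits. The
MOI→CFU conversion is `moi × host_cells` with 2.5 × 10⁵ host cells per
well by default (MOI 50 → 1.25 × 10⁷ CFU).

## Statistics

Each replicate group (n ≥ 3) is routed by a Shapiro–Wilk test at α = 0.05:
normal-looking groups take the parametric test (one-sample t against 100%,
or Welch unequal-variance t between groups), others the rank-based analogue
(Wilcoxon signed-rank with zeros dropped and the exact null for n ≤ 25;
Mann–Whitney U with the exact small-sample null). All tests are two-sided.
When several conditions share one control — the species×MOI conditions of a
screen, the doses of one ladder, the 16 cells of one checkerboard — their
p-values form one Benjamini–Hochberg family and decisions use the adjusted
q. CFU counts are compared on the log10(count + 1) scale.

Two consequences of this recipe are surfaced rather than patched:

- with n = 3 the signed-rank two-sided p cannot fall below 0.25, so a
  non-normal triplicate can never reach q < 0.05;
- zero-variance groups (possible only with noise-free synthetic data) have
  no defined Shapiro–Wilk statistic; by convention a constant sample equal
  to the null gives p = 1 and a constant sample off the null gives p = 0,
  which makes noise-free planted-truth recovery exact.

## Screening rules

A species×dose condition is *anti-inflammatory* when its mean normalized
read-out is strictly below 50% with q strictly below 0.05; *cytotoxic* when
mean viability is strictly below 80% with q < 0.05 (a sub-80% mean without
significance is explicitly not cytotoxic); *self-activating* when the
species alone significantly raises the read-out above the uninfected
control (significant reductions are not activation). A species is retained
for synergy testing when it is anti-inflammatory at ≥ 1 tested dose,
cytotoxic at none, and not self-activating. Boundary values fail all strict
inequalities.

The minimal effective MOI (mMOI) of a species, per read-out, is the lowest
ladder dose that passes the anti-inflammatory call *with every higher
tested dose also passing*. The contiguity requirement reflects that a
monotone dose–response is expected; an isolated pass under a failing higher
dose is reported as a non-monotonicity warning and not used. On noise-free
Hill-curve ladders this equals the analytic lowest-dose-below-threshold
oracle (property-tested over random parameter draws).

## Checkerboard synergy

Each two-species consortium is a 4×4 grid of 1:4 dilutions anchored at the
two mMOIs (16 MOI ratios). Per cell, FICI = a/mMOI_A + b/mMOI_B on exact
ladder values; comparisons use an absolute tolerance of 1e−9 and rounding
to two decimals is display-only. The synergy boundary is inclusive
(FICI ≤ 0.5) because exact grid arithmetic produces cells at exactly 0.5
that belong to the synergistic set. A cell is synergistic when it also
shows < 50% activation at q < 0.05 (BH family = the 16 cells of that
checkerboard); FICI ≥ 4 is antagonism; cells with fewer than 3 replicates
are NOT_EVALUABLE. FICI-passing cells that miss the effect criteria are
flagged `fici_pass_effect_fail`, distinguishing magnitude failures from
significance failures. On the standard grid only the 9 cells whose
dilution-fraction pair sums to ≤ 0.5 can ever be synergistic, a pure
consequence of the fractions {1, 1/4, 1/16, 1/64}.

Isobolograms plot the 16 dose pairs with the cut-off drawn from
(0.5·mMOI_A, 0) to (0, 0.5·mMOI_B); on linear axes this straight chord is
exactly the FICI = 0.5 locus, so the geometric below-the-line rule and the
arithmetic rule provably agree (property-tested). A log-scale variant draws
the curved image of the same locus; linear is the default because the
cut-off is then the textbook straight isobole. Rendering is deterministic
(fixed figure geometry and metadata): identical inputs give byte-identical
PNGs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the biology underneath it. Single-species inhibition is a Hill curve
`activation = 100·(1 − emax·mᵸ/(mᵸ + EC50ᵸ))` with separate EC50s for the
NF-κB and IL-8 read-outs (IL-8 defaults to 4× the NF-κB dose, reflecting
that cytokine suppression typically needs more bacteria). Cytotoxicity is a
second Hill term on viability; the luminescence read-out is multiplied by
the viability fraction, reproducing the real-world confound where dying
reporter cells mimic anti-inflammatory activity (such species are excluded
by the LDH criterion, as intended). Combinations follow Loewe
dose-equivalence with interaction strength α: the combination sits at the
activation level A where `a/D_A(A) + b/D_B(A) = α`, with D the inverse Hill
dose; α = 1 is additivity, α < 1 synergy (α = 0.5 halves the total dose
needed for any iso-effect), α > 1 antagonism. The level is found by
bracketed root-finding to residual < 1e−8; a species contributes nothing at
levels below its own floor, and single present species reduce exactly to
their own curve. Loewe was chosen over Bliss independence because FICI is
itself a Loewe-type index: planted truth and classifier target then
coincide conceptually, so recovery failures indicate classifier error, not
model mismatch.

Replicate noise is additive Gaussian on the percent scale, truncated at 0
(plate read-outs are averages over many cells), with sd 5% and n = 4 as the
default regime — a realistic mid-range plate-assay noise level, swept in
the recovery tests. Raw signals are the percent values scaled by a fixed
per-assay base signal. Generation is deterministic given the seed
(byte-identical CSV on rerun).

The default 15-species panel mirrors a realistic screen: nine
anti-inflammatory species with minimal effective doses spread across
12.5–0.2, three cytotoxic species, three inert species.

What passing tests show — and don't: recovery results certify the pipeline
against data satisfying its own assumptions (Hill-shaped monotone
responses, Loewe interactions, Gaussian percent-scale noise, exact ladder
doses). Real data add plate effects, non-Gaussian noise, pipetting error in
the dilution series, and interactions that need not be Loewe-consistent;
performance there is not established by these tests.

## Validation problem sizes and conditions

- Parameter recovery: 200 simulated consortia (alternating planted
  α ∈ [0.15, 0.4] and α ∈ [1, 2], EC50s log-uniform on [0.2, 12.5], Hill
  slope in [1, 3], sd 5%, n = 4), requiring ≥ 95% correct classification in
  each direction. Checkerboards here are anchored at the species' *true*
  iso-50% doses; with ladder-quantized mMOIs (up to 4× the iso-50 dose) an
  additive pair can legitimately produce FICI ≤ 0.5 cells with > 50%
  inhibition, so discretization — not the classifier — then sets the
  specificity floor.
- Type-I calibration: 1000 null simulations (normal noise around 100%,
  n = 6) must keep the routed test's rejection rate within the binomial
  99% band around 0.05.
- Planted-phenotype screen: the noise-free default panel must reproduce its
  planted labels exactly (3 cytotoxic excluded, 9 retained).
- The crossover interaction regime 0.4 < α < 1 straddles the FICI ≤ 0.5
  boundary by construction and is deliberately not asserted on.

## Known limitations

- Per-plate normalization is the only control policy; no plate-geometry or
  edge-effect modelling, and no raw instrument-file parsing (tidy CSV in).
- FICI is defined for species pairs only; no ≥ 3-species generalization and
  no response-surface synergy scores (Bliss/ZIP/HSA) — the generator uses
  Loewe internally but the analysis scores only FICI.
- The two-group normality routing assumes independent groups; paired
  designs are not supported.
- mMOI contiguity means a species whose top tested dose fails can have no
  mMOI even if intermediate doses pass; this is by design and warned about.
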