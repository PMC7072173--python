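# Methods

## Problem and model

Roughly half of human small nucleolar RNAs (snoRNAs) are encoded inside
introns of host genes (protein-coding or lncRNA) and are co-transcribed with
them. Somatic copy-number alteration (CNA) at such a locus would naively be
expected to hit snoRNA and host together, but tumor genomes need not respect
that expectation. `snocna` quantifies, per tumor cohort, how often the two
members of each snoRNA/host *couple* are altered together or separately, and
whether copy-number dosage propagates to expression.

The unit of observation is the **(couple, sample) cell**. Inputs are
GISTIC-style discrete copy-number codes per gene and sample
(−2 deep deletion, −1 shallow deletion, 0 diploid, +1 gain, +2 high-level
amplification). Only the deep calls ±2 count as events; ±1 are treated as
copy-number noise. Each cell is classified as

* `none` — neither member carries an event,
* `snorna_only` / `host_only` — exactly one member altered,
* `co_occurring` — both altered. Sign concordance (amp/amp or del/del) is
  recorded but **not** required for co-occurrence; discordant co-occurring
  cells are rare and biologically odd, so they are surfaced rather than
  silently merged or split.

A cell with a missing code for either member is excluded from both the
numerator and the denominator of every frequency — treating missing cells as
unaltered would bias frequencies downward.

Derived statistics per cohort:

* **cumulative CNA frequency** = altered cells / (couples × samples −
  missing cells). By default each altered cell counts once ("cell"
  counting), which keeps the ratio ≤ 1 under the couples × patients
  denominator; a "gene" counting mode (co-occurring cells count twice) is
  exposed via `event_counting` for users who want gene-level event totals.
* **per-sample event rates** for each altered class;
* **amp/del breakdown**: gene-level sign counts per context. The main table
  follows the snoRNA side (contexts `snorna_only` and `co_occurring` carry
  the snoRNA's sign); a companion table carries the host side, so no sign
  information is lost.
* **couple-level co-occurrence classes**: a couple is `co_occurring` in a
  cohort if ≥ 1 of its cells is, `altered_not_co_occurring` if altered but
  never jointly, `absent` otherwise. Percentages are emitted against both
  the all-couples and the mutant-couples denominators, since either can be
  of interest.
* **cross-cohort categories**: a couple is `never` altered, altered in
  `all` cohorts where it is evaluable, or altered in `some`. Couples absent
  from every cohort's matrices are `not_evaluable` and excluded from the
  percentage denominator.
* **top-k recurrent couples**: ranked by the fraction of non-missing samples
  with ≥ 1 altered cell; ties break deterministically by descending
  fraction, then ascending `SNORNA/HOST` label, then ascending snoRNA id —
  determinism is required for byte-identical reruns.

## Expression alteration

Z-scores are diploid-referenced: for each gene, the reference population is
the samples with CNA code 0 for that gene, and
`z = (x − μ_ref) / σ_ref` with the unbiased (n−1) standard deviation. The
n−1 choice matches standard sample-based Z-scoring; it is configurable, as
is the minimum reference size (`min_ref`, default 3). A gene whose reference
is smaller than `min_ref` or has zero spread yields undefined scores, which
propagate as `undefined` calls and are excluded from rates. Samples with a
missing CNA code are excluded from the reference even when expression is
present, because the reference is defined by diploid status, not by data
availability.

Calls are `up` when z > 2 and `down` when z < −2, strictly — z = 2.0 is
`normal`. Because z is an affine transform of x per gene, calls are
invariant under any positive affine rescaling of a gene's expression row
(verified by a property test).

A couple counts as up-regulated in a sample when **either** member is called
up (each driving member is recorded); the alternative readings (host-only or
snoRNA-only) can be reconstructed from the per-member flags that are kept in
the output. snoRNA abundance from small-RNA-enriched libraries can
under-represent mid/large snoRNAs; the package logs a caution when snoRNA
expression rows are present but does not attempt to model that bias.

## Exact association test

The 2×2 association between "snoRNA altered" and "host altered" across
samples is tested with a Fisher exact test written from first principles:
conditioning on both margins, the two-sided p-value sums the hypergeometric
probabilities of all tables whose probability is ≤ that of the observed
table (probability method, the default of the major statistics ecosystems).
The ≤ comparison uses a 10⁻⁷ relative tolerance so exact ties arising from
symmetric margins are included despite floating-point rounding. Factorials
are evaluated as log-gamma sums and normalized in log space, so totals up to
~10⁶ are handled. A zero margin means one variable is constant; p = 1 by
convention, logged. The implementation is verified against exhaustive
rational-arithmetic enumeration for every table with n ≤ 12 (to 10⁻¹⁰) and
cross-checked against an independent library implementation on random
tables.

Because the test is exact and conditional, it is **conservative**: under
independence with alteration rates ~0.1 and n = 400 the realized rejection
rate at α = 0.05 is ≈ 0.035, not 0.05. The calibration test therefore
asserts validity (rate ≤ α plus Monte-Carlo error) and non-degeneracy
(rate > 0.02) rather than equality with the nominal level, which no exact
test of a discrete table can attain.

Raw p-values are Benjamini–Hochberg adjusted across the couples of a cohort
(≈ 295 simultaneous tests); both raw and adjusted values are emitted so
either convention can be applied downstream.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis measures; it
is the package's test bed, not a genome simulator.

Per couple and cohort, alteration is a two-stage Bernoulli process: a sample
is altered with probability `p_alt`; given alteration, both members are hit
with probability `p_co`, otherwise one member chosen by
`p_sno_given_single`. Signs are amplification with probability `p_amp`
(else deep deletion); co-occurring events share the sign with probability
`p_sign_concord`. Otherwise-diploid gene cells receive spurious ±1 codes at
rate `p_shallow` — pure nuisance that downstream code must ignore — and go
missing at rate `p_missing` (default 0).

Cross-cohort structure comes from couple classes: a fraction `frac_never`
(default 0.39) of couples is never altered anywhere, `frac_all` (default
0.10) is alterable in every cohort, and the remainder is active only in a
random proper subset of cohorts. At finite sample sizes an "all-class"
couple may realize no event in a small, low-burden cohort, so recovered
category percentages scatter around, not exactly at, the class fractions.

Expression is log-normal: per-gene baseline
`exp(N(expr_log_loc, expr_log_scale))`, multiplied by `f_amp` (default 4)
under amplification and `f_del` (default 0.25) under deep deletion, with
multiplicative noise `exp(N(0, noise_sd))`. This guarantees non-negative,
right-skewed abundances with a tunable dosage→expression coupling;
`f_amp = 1` with `f_del → 1` is the no-coupling null.

Defaults describe a ten-cohort pan-cancer design (sample sizes 354–1070,
5359 total) with per-cohort overrides: the OV-like series has the highest
alteration burden and the KIRC/GBM-like series the lowest; the KIRC-like
regime is strongly co-occurring (`p_co = 0.75`, giving a ≈ 3:1
co-occurring:single-member cell ratio) and the BRCA-like regime weakly
(`p_co = 0.30`). Named presets (`default`, `kirc_like`, `ov_like`,
`brca_like`) freeze these regimes for tests and examples.

What the generator does **not** model: genomic positions and segment-level
correlation between neighboring couples (real CNA events span megabases, so
neighboring couples are correlated; here couples are independent), tumor
purity and subclonality (real codes are noisier calls on mixtures), and
small-RNA library bias in snoRNA quantification. Passing recovery tests
therefore show the pipeline measures what the generative process encodes,
not that real cBioPortal extracts will show any particular value.

## Determinism and numerics

All randomness flows from a single `numpy` `default_rng(rng_seed)`; the same
seed yields bit-identical matrices, and the generator re-counts the emitted
matrices against its truth record before returning. Analysis outputs are
plain TSVs written with a fixed `%.10g` float format, so a fixed seed and
config reproduce a byte-identical output tree; the run manifest records the
resolved configuration, a config hash and input checksums (paths as
basenames, so the manifest is location-independent). Structural invariants
— class counts + missing = couples × samples, frequencies in [0, 1] and
permutation-invariant, reference Z mean 0 / sd 1 per gene to 10⁻⁹, category
percentages closing to 100 — are asserted in the test suite, and the count
conservation additionally at run time.

Problem sizes used by the test suite and the acceptance script (random
cohorts of 20 couples × 30 samples for oracle equivalence; presets at
n_samples = 1000 for parameter recovery; 200 replicates of 295 tests at
n = 400 for type-I behavior) were chosen as the smallest sizes at which the
binomial 3·SE bands are meaningfully narrow.

## Known limitations

* Couple-level independence in the generator understates the spatial
  correlation of real CNA segments; cross-couple statistics (e.g. how many
  couples share one amplicon) are out of reach.
* The expression model has no library-size or batch structure, so the
  diploid-reference Z-score never has to correct for them, as it would on
  real RSEM matrices.
* The Fisher test is applied per couple; no attempt is made to model
  dependence between tests of couples sharing a chromosome arm.
* `not_evaluable` couples are excluded from category percentages; with
  heavily fragmented inputs the reported percentages describe the evaluable
  subset only.
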