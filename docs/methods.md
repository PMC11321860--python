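# Methods

## The model of the data

A stomach-content metabarcoding experiment produces, per genetic marker, an
integer matrix of read counts over features (MOTUs for a clustered
mitochondrial marker, ASVs for a denoised ribosomal one) × samples. Samples
are stomachs plus no-template controls (extraction blanks, PCR negatives).
The observed counts mix four processes: true prey DNA, the predator's own
DNA, laboratory contamination, and reads misassigned between multiplexed
samples (tag-switching / index hopping). Taxonomic assignments carry a
confidence score — a best-hit identity fraction for COI, a per-rank
classifier bootstrap for 18S — and may be wrong or shallow.

`jellydiet` does not model these processes statistically; it applies the
rule-based curation used in practice, then computes descriptive diet metrics
and permutation tests. The synthetic generator, by contrast, *is* a
generative model, built so the rules' behaviour can be verified against
known truth.

## Curation cascade

Order: reassignments → blank correction → taxonomy filters → per-cell
zeroing → predator removal → regional filter → depth filter. The endpoints
are fixed by the logic of the data (blank correction must see the raw table;
the depth rule must see fully curated depths); the middle order puts cheap
whole-feature filters before cell-level edits. The order is recorded in the
report so deviations are auditable.

Decisions a reader should know:

- **Blank rule denominator.** A feature is removed when
  (reads in extraction blanks) / (feature's total reads across *all*
  samples, controls included) strictly exceeds the threshold (default 0.10).
  PCR negatives can be pooled into the numerator via
  `blanks_include_pcr_negatives`; the default uses extraction blanks only.
- **Strict inequalities throughout**: identity < 0.85 removed (0.85 kept),
  bootstrap < 70 removed (70 kept), cells < 5 reads zeroed (5 kept), samples
  < 1000 reads dropped (1000 kept), blank share > 0.10 removed (0.10 kept).
- **Predator removal modes.** COI removes the focal predator species from
  its own stomachs only (per-sample); 18S removes the configured predator
  orders from every sample, because order-level reads in *other* samples may
  be tag-switched predator DNA. Both modes are config-overridable.
- **Cells are zeroed, never proportionally corrected** — the cascade
  removes, it does not decontaminate.
- **Idempotence.** Re-curating curated output is a no-op provided the
  control samples fell below the depth threshold in the first pass (true
  under realistic blank loads, where blanks carry a few hundred reads). If a
  control somehow survived, a second blank-rule pass would see reduced
  feature totals and could remove more; the audit report makes this visible.
- Features already all-zero on input are left alone by the cell-zeroing
  rule; only features *emptied by* a rule are dropped and attributed to it.

## Diet metrics

RRA is reported in percent (0–100). `overall_rra` defaults to the pooled
(read-sum) estimator, which weights stomachs by depth; the `mean` estimator
(average of per-sample RRAs) weights stomachs equally and is available
because the two differ whenever depths differ. FOO counts post-curation
presence (≥ 1 read after the 5-read cell rule), so a 1–4-read detection
never counts, and %FOO uses the per-marker retained stomach count as
denominator. Rank aggregation rolls features unassigned at the target rank
up to their deepest assigned rank, labelled e.g. `Tentaculata (class)`, so
total reads are conserved exactly; group trait flags are the OR of member
flags, confidence scores the member maximum.

The importance index multiplies the GZP-fraction RRA (percent, renormalized
over gelatinous features only, benthic gelatinous invertebrates included by
default) by the absolute FOO. The conventional integer bands (<100 low,
101–499 medium, >500 high) leave gaps at non-integer values, so the bands
are closed as low ≤ 100 < medium < 500 ≤ high, which partitions [0, ∞);
both edges are parameters of `importance()`.

## Community statistics

All tests run on fourth-root-transformed per-sample RRAs under Bray–Curtis
dissimilarity. PERMANOVA uses the one-way distance-based decomposition
(SS_total = Σ_{j<k} d²/N; SS_within = Σ_g Σ_{j<k∈g} d²/n_g;
pseudo-F = (SS_among/(a−1))/(SS_within/(N−a))) with unrestricted label
permutations and the (1 + count)/(1 + n_perm) p estimator, which includes
the observed labelling and cannot return 0. Default 999 permutations; every
permutation stream is seeded. Pairwise tests rerun PERMANOVA on each pair's
submatrix with Bonferroni adjustment (m = number of pairs). PERMDISP embeds
the matrix by principal coordinates keeping negative-eigenvalue axes
(squared centroid distances = real² − imaginary², floored at 0), then
permutes the distance-to-centroid values across groups under a one-way F.

NMDS is implemented in the package so the stress computation is auditable:
Kruskal stress-1 = sqrt(Σ(d − d̂)²/Σd²) with disparities d̂ from isotonic
regression of configuration distances on dissimilarity order, minimized by
Guttman-transform majorization. Because stress-1 is scale-invariant the
bare iteration can shrink the configuration toward the origin; after each
update the configuration is rescaled to the input dissimilarity norm, which
leaves stress unchanged and keeps coordinates plottable. The first restart
starts from the principal-coordinate solution, the remaining (default 20)
from seeded random configurations; the stress trace is non-increasing by
construction (the run stops, keeping the previous configuration, if an
update fails to improve) and non-convergence is reported, never silent.
18S analyses are run on family-aggregated tables; COI at feature level.

## Synthetic generator

Per stomach: diet ~ Dirichlet(per-species concentration); depth ~
Poisson(LogNormal(depth_log_mean, depth_log_sd)); predator-read fraction ~
Beta(a, b) realized as a Binomial draw; the remaining reads are allocated
Multinomial(diet × per-taxon marker detectability, renormalized).
Contaminant features draw Poisson(contaminant_blank_load) reads in every
control and Poisson(contaminant_sample_load) in every stomach. Finally a
Binomial(tag_switch_rate) share of every cell's reads moves to uniformly
chosen other samples, preserving feature identity and total read count
exactly. Confidence scores are Normal draws (clipped to range) per feature.
All intermediate quantities are resolved by integer draws, never rounding,
and the whole dataset is a deterministic function of the config seed.

Defaults mirror the survey the package is shaped around: seven predator
species with stomach counts 27/29/30/12/16/3/9 split across west/east/south
Greenland regions, five extraction blanks, two PCR negatives, a 20-taxon
pool (crustaceans, echinoderms, polychaetes, forage fish, and gelatinous
taxa with marker-biased detectability — lobate ctenophores and salps
18S-only, a cephalopod COI-only), depths ~e^10 ≈ 22k reads. No quantitative
contamination or tag-switching rates are available for such surveys, so the
defaults (150 reads per contaminant per blank, 2 per stomach, tag-switch
rate 0.002) were chosen once as plausible for pooled NovaSeq amplicon
libraries and are surfaced in `SimConfig`, not hard-coded.

What the generator does *not* emulate: sequence-level artefacts (chimeras,
PCR error, primer-slippage), MOTU over-splitting (one feature per taxon),
depth–composition correlation, and taxonomically structured assignment
error. Passing tests therefore demonstrate the pipeline's correctness on
the stated generative model, not robustness to upstream bioinformatic
artefacts.

## Problem sizes and numerics

The test suite runs the cascade oracle on a 6-feature hand fixture, 100–200
small randomized datasets for the conservation/idempotence/brute-force
properties, a 30-stomach × 50k-read noise-free run for RRA recovery
(Pearson r ≥ 0.95), 500 null simulations (12 samples, 999 permutations) for
the PERMANOVA type-I error band, and exhaustive enumeration at n = 6 for the
permutation p oracle. The acceptance script uses the full 126-stomach
default survey plus a 200-replicate null. RRA normalizations are exact to
1e-9; pseudo-F matches the closed-form ANOVA F to 1e-10 on Euclidean toys;
NMDS convergence tolerance is 1e-7 on stress with 300 iterations per
restart. Degenerate inputs are contracts, not silent behaviour: all-zero
samples are rejected by Bray–Curtis by name, empty gelatinous fractions
return empty results rather than dividing by zero, and groups of size < 2
are errors for all permutation tests.

## Known limitations

- No statistical decontamination (frequency-based contaminant inference) or
  secondary-predation modelling; only the rule-based cascade.
- One-way PERMANOVA only; no nested/multi-factor designs or strata-
  restricted permutations.
- The congruence report joins on harmonized rank labels; it cannot detect
  two markers naming the same organism at incompatible ranks beyond the
  roll-up convention.
- Biomass or energetic conversion of read counts is out of scope; RRA is a
  read-proportion, not a diet-mass estimate.
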