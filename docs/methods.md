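# Methods

This note documents the models, defaults and design choices behind
`episcreen`, and what the synthetic-data tests do and do not establish about
real assay data.

## Pipeline model

The package implements a two-stage pooled screen for CD8+ T cell epitopes of
a five-protein viral proteome (N, P, M, GP, L in genome order) on the three
BALB/c MHC class I alleles (H2-Kd, H2-Dd, H2-Ld).

1. **Enumeration.** Every 8–11-mer window of every protein, 1-based
   inclusive coordinates. GP is treated as a single protein; no cleavage
   products are modelled.
2. **Scoring and tiering.** Peptides carry an affinity (predicted IC50, nM),
   a percent rank, and optional stability and immunogenicity scores. Binder
   tiers follow percent-rank cutoffs strong < 0.5 ≤ weak < 2.0 ≤ marginal
   < 10.0 ≤ non; a value exactly on a boundary takes the weaker tier (a
   fixed convention — predictors disagree on boundary handling, and a
   deterministic rule keeps panels reproducible).
3. **Composite ranking.** When several predictor scores are available the
   composite is the mean of the available per-predictor ranks (percent rank
   ascending; stability and immunogenicity descending). Rank averaging is
   scale-free, robust to heterogeneous score units, and degrades gracefully
   when a predictor is missing for some peptides. Ties break on (affinity,
   genome order, start, sequence) so selection is a total order.
4. **Gradient panel selection.** Per-protein quotas 15/15/10/5/5 (N/P/M/GP/L,
   total 50) encode the protein-abundance gradient of sequential
   negative-strand RNA virus transcription. A duplicate sequence occurring
   in two proteins is kept once, attributed to the more upstream protein
   (one peptide is one stimulus). A protein offering fewer scored peptides
   than its quota cascades the shortfall to the next protein in genome
   order, preserving the panel budget. Identifiers are protein letter +
   global index in genome-then-rank order.
5. **Matrix design.** Row-major placement by rank into a 7×7 grid; rows are
   pools 1–7 (horizontal), columns pools 8–14 (vertical). With 50 candidates
   in 49 cells, the lowest-ranked candidate shares cell (7,7) and is flagged
   ambiguous; the single-peptide stage resolves the ambiguity, so the
   14-pool / two-pools-per-peptide structure is preserved.
6. **Positivity calling.** Unpaired two-sample *t* test (Student's
   equal-variance by default, the common graphing-software convention; Welch
   available) of treated vs untreated wells, combined with a spot-count
   floor: positive ⇔ *p* < α ∧ treated mean ≥ floor ∧ treated mean >
   control mean. The 60-spot line is applied both as the positivity floor on
   test wells and as the acceptability bound on the positive control in
   plate QC (with the negative-control mean bounded by a 50-spot background
   ceiling); all three thresholds are configurable. No multiplicity
   correction is applied by default (per-pool raw tests, as in the original
   readout); Benjamini–Hochberg is available. Indeterminate calls (missing
   wells, groups of fewer than two mice) are never positive.
7. **Deconvolution and confirmation.** A candidate is nominated iff both its
   pools are positive (the cross-product rule; the alternative — advancing
   all members of any positive vertical pool — is inconsistent with the
   observed 9→20, 6→8 and 4→4 pool-to-candidate arithmetic). Nominated
   candidates are re-tested individually under the same call; only then are
   they called epitopes.
8. **ICS/flow analyses.** The module consumes pre-gated summaries (%IFN-γ+
   of CD8+), never raw cytometry events. Route comparisons fit
   `freq ~ C(stimulus) * C(route)` by OLS with a type-II ANOVA omnibus
   table, then compute Tukey-HSD-adjusted pairwise route contrasts within
   each stimulus (degenerate factors drop out of the formula). Epitope
   composition subtracts the negative-control mean, clamps at zero (the
   subtraction is a package choice to prevent negative shares; it is
   configurable by passing pre-corrected data). Polyfunctionality gates are
   plain Boolean-combination percentages over {IFN-γ, TNF-α, CD107a}.
   Reported percentages are rounded to 2 decimals; computation is full
   precision.
9. **Characterization.** Protein and length distributions, anchor-motif
   conformity (descriptive only — motif violations never filter
   confirmation, since low-affinity binders can be immunogenic), nested
   same-allele length variants, exact cross-strain sequence sharing, and
   multimer eligibility with the manufacturer cutoff of 1,000 nM predicted
   IC50 (a value exactly at the cutoff counts as eligible; "above" is the
   exclusion).

## Surrogate scorer

External binding/stability predictors are out of scope; their tabular
exports are inputs. For self-contained runs the surrogate scorer assigns a
deterministic percent rank from the allele's anchor motif — H2-Kd: Tyr at
position 2 and Leu/Ile C-terminus; H2-Dd: Gly-2, Pro-3, Lys-5 and a
hydrophobic C-terminus; H2-Ld: Pro-2 and a hydrophobic C-terminus — with a
per-match step (24 / number of rules) that strictly dominates the hash-based
residual (< 0.45) separating equal-motif peptides, plus a mild 0.6/residue
penalty away from the canonical 9-mer length. Affinity, stability and
immunogenicity are monotone transforms of the same rank. The surrogate is a
motif model, not a trained predictor: it reproduces ordering properties
(more anchor matches ⇒ better rank), not calibrated affinities.

## Synthetic data generator

**What it emulates.** Study conditions of the original campaign: 4 untreated
and 6 treated mice per plate, one well per mouse × stimulus, negative
control ≈ 10 spots, positive control ≈ 500 spots, planted immunogenic
stimuli ≈ 300 spots in treated mice only (untreated mice are virus-naive and
never carry effects). Spot counts are negative-binomial with a mean/Fano
parameterisation: `dispersion` is the variance-to-mean ratio φ (default 5,
i.e. CV ≈ 13% at the effect mean and ≈ 70% at background), chosen as a
realistic overdispersion level for replicate ELISpot wells; φ→1 recovers
Poisson. Per-epitope immunogenicity heterogeneity is a deterministic
log-uniform multiplier (spread 0.5, range ≈ 0.61–1.65×) applied identically
to ELISpot effects and ICS baselines — this shared factor is what makes the
two assays correlate across epitopes, as observed. A pool responds at the
level of its strongest planted member. ICS frequencies are multiplicative:
baseline 0.4% × route (i.v. 2.7, i.t. 1.0) × tissue (tumor 4.0, spleen 1.0)
× unit-mean log-normal noise (CV 0.2), clipped to [0, 100]; the default
campaign grants three epitopes (H2-Kd P16/P25, H2-Dd M35) route parity by
raising their i.t. response to the i.v. level.

**What it does not emulate.** Plate/batch effects, well-position artefacts,
saturated ("too numerous to count") wells beyond a configurable cap or
exclusion, inter-mouse correlation across stimuli, T cell competition
between co-pooled peptides, bystander IFN-γ sources, or any mechanistic
immunology. Passing recovery tests therefore demonstrates that the
*decision logic* (calling, decoding, confirmation) is correct under the
stated noise model — not that the thresholds are optimal for any particular
real assay.

All generation flows from one integer seed through numpy's PCG64 generator;
per-allele and per-stage child seeds are derived with `default_rng([seed,
index])`, so outputs are bit-reproducible across platforms.

## Numerical and statistical choices

- *t* tests via `scipy.stats.ttest_ind`; identical-group inputs yield an
  undefined statistic and a non-positive call.
- Tukey contrasts via `statsmodels` `pairwise_tukeyhsd`, read from its
  full-precision attributes (the printed summary rounds to 4 decimals); the
  test suite cross-checks against `scipy.stats.tukey_hsd` to 1e-8.
- Pearson correlation via `scipy.stats.pearsonr`; zero-variance inputs are
  flagged undefined rather than raised, since a flat vector is a legitimate
  (if uninformative) assay outcome.
- With the default floor of 60 spots and background of 10, the effective
  null positive rate of pool calling is far below α (the floor, not the
  test, dominates): measured < 0.1% per plate over 1,000 simulated null
  plates.
- Planted effects of ≥ ~180 spots against this background are recovered with
  sensitivity 1.0 over 100 seeds; heavier-tailed parameterisations (e.g. NB
  shape k = 5, CV 45% at the effect mean) would not support that guarantee,
  which is why `dispersion` is defined as the Fano factor.

## Problem sizes

The bundled synthetic proteome uses realistic lengths for N (422 aa), P
(265), M (229) and GP (498) and a shortened polymerase stand-in (600 aa vs
~2,100 in nature) — the L protein contributes only 5 of 150 panel slots, so
its length affects only enumeration volume, not screen behaviour. Recovery
and null-rate properties are established over 100 and 1,000 simulated
plates respectively.

## Known limitations

- The exact grid layout of the original screen (which candidate shared a
  cell, if any) is not published; the row-major convention here reproduces
  all published pool/candidate arithmetic but is not guaranteed to match the
  bench layout peptide-for-peptide.
- Whether the original 60-spot line acted as a QC bound on controls or a
  biological floor on test wells is ambiguous; both are implemented and both
  default on.
- Only 7 of the 11 validated epitope sequences are published; the other four
  are represented by ids only, and any stand-in sequences used in tests are
  labelled synthetic.
- The two-way ANOVA factor structure for route comparisons is the package's
  own model formula (stimulus × route); equivalence with the original
  graphing-software analysis is not asserted.
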