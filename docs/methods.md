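# Methods

## Statistical model

### Two-sample cis-MR

Each protein's plasma abundance is treated as an exposure instrumented by
its cis-pQTLs: variants within ±1 Mb of the encoding gene's boundaries
(start/end, not TSS — configurable) associated with the protein at
p < 5×10⁻⁸, thinned by greedy LD clumping to r² < 0.1 (distance-based
fallback when no LD matrix is available). The cis restriction is itself a
pleiotropy defense: a variant inside the gene's own regulatory neighborhood
most plausibly affects the outcome through that gene's product.

With exposure effects βx and outcome effects βy on shared, harmonized
variants, the causal effect θ (log-odds of outcome per unit exposure) is
estimated by the Wald ratio βy/βx for single-variant instruments and by
fixed-effects IVW for k ≥ 2:

θ̂ = Σ βxᵢβyᵢ/σyᵢ² ÷ Σ βxᵢ²/σyᵢ² , se = (Σ βxᵢ²/σyᵢ²)^(−1/2),

identical to weighted least squares of βy on βx through the origin with
weights 1/σy². The Wald-ratio SE is the first-order delta approximation
σy/|βx|, which ignores exposure-side error; this is the conventional choice
for genome-wide-significant instruments, and a second-order variant is
exposed separately. Diagnostics: Cochran's Q over per-variant ratios
(k ≥ 2, χ²_{k−1}), and the MR-Egger intercept (k ≥ 3), fit as a weighted
affine regression after orienting all βx ≥ 0; the intercept estimates the
average directional (horizontal) pleiotropic effect.

Multiplicity is controlled by Benjamini–Hochberg step-up against the full
family of tested proteins: when only the significant tail of a larger
screen is in hand, the family size m is passed explicitly (the bundled
case study uses m = 1557 over its 16 tabulated rows). Standard
monotonization is used; for tied raw p-values all tied entries share one
adjusted value, which can differ in the third significant figure from
outputs of software with other tie conventions.

### Colocalization

A significant MR signal can be produced by two distinct causal variants in
LD (one for the protein, one for the outcome). The per-region Bayesian
colocalization assumes at most one causal variant per trait and scores each
variant with the Wakefield approximate Bayes factor
log ABF = ½[log(1−r) + r z²], r = w/(V+w), where V is the squared SE and w
the prior effect variance (prior SD 0.2 for quantitative traits, 0.15 for
case-control — the conventional defaults; the analysis priors are
p1 = p2 = 10⁻⁴ for single-trait causality and p12 = 10⁻⁵ for shared
causality). Summing ABFs over configurations gives posteriors for H0 (no
association), H1/H2 (one trait), H3 (distinct variants), H4 (shared
variant). Accumulation uses log-sum-exp throughout; the H3 term
S1·S2 − S12 is computed as a log-space difference clamped at zero, since
with one variant (or perfectly concordant signals) it cancels exactly.
Classification is strict: suggestive requires PP.H4 > 0.5, strong > 0.8.
Colocalization runs on marginal (unadjusted) statistics over the gene's
full cis window; conditionally adjusted statistics can be supplied
pre-computed but are never derived internally.

### Pleiotropy triage and annotation

Four steps: (1) secondary proteins/transcripts associated with the
instruments at p < 5×10⁻⁸ (excluding the primary protein); (2) proximity
of the gene to known outcome risk loci within 1 Mb; (3) MR of each
secondary trait on the outcome using the secondary trait's own lead cis
instrument (pQTL preferred, eQTL fallback), Bonferroni threshold 0.05/n
over the n instrumented secondary traits; (4) pathway concordance:
significant secondary traits sharing a pathway with the primary gene
indicate vertical pleiotropy (benign — downstream of the exposure),
disjoint annotated pathways indicate horizontal pleiotropy, missing
annotation leaves the verdict unknown. Gene-level precedence is
conservative: horizontal > unknown > vertical; this ordering is a design
choice where the procedure's sources are silent on mixed evidence. Pathway
and druggability tables are user-supplied flat files; no live database
queries, keeping runs hermetic.

Reporting helpers: modality inference (OR > 1 → inhibitor, OR < 1 →
agonist; protein raises or lowers risk respectively), directionality
concordance against risk factors whose harmful/protective polarity is a
*declared* input column (polarity is contestable — e.g. diastolic blood
pressure and HDL-C — so it is never inferred from data), and tractability
regrouping: bucket 1 → licensed; 2–3 → clinical; 4–5 → preclinical (small
molecules) or predicted (antibodies); 6–8 → predicted (small molecules);
9 or unannotated → non-druggable.

### GWAS meta-analysis

Two harmonized studies are pooled per variant by fixed-effects IVW;
variants with minor-allele frequency strictly below 0.5% are removed
beforehand (records lacking a frequency are kept and logged). Distinct
leads are selected greedily in ascending p (ties broken by position),
absorbing candidates at r² ≥ 0.6 with a selected lead, or within 500 kb
when no LD matrix is supplied — the distance rule is explicitly an
approximation of the R² rule. A lead is novel when every known lead on its
chromosome is farther than 500 kb.

## Harmonization rules

Studies are joined on variant id (positional matching is an opt-in
dialect). Study b is re-expressed on study a's effect allele: identical
alleles pass through; swapped alleles negate β and replace eaf by 1−eaf;
strand complements are resolved likewise. Palindromic (A/T, C/G) variants
cannot be strand-resolved from alleles alone, so they are kept only when
the allele frequency is informative — any palindromic variant with eaf
within 0.08 of 0.5 in either study (i.e. inside (0.42, 0.58)), or with a
missing eaf, is dropped; otherwise the minor-allele side orients the
strand. The window is configurable; 0.08 is a conservative default in the
absence of an authoritative convention.

## Synthetic data

Regional summary statistics use the standard multivariate-normal model for
GWAS z-scores under LD, z | λ ~ N(Rλ, R), with AR(1) LD R_jk = ρ^|j−k| and
non-centrality `effect_z` at the causal variant; betas are z/√n with SE
1/√n (a unit-variance trait scale). Scenario defaults mirror the study
conditions the estimators are validated under: 50 variants, ρ = 0.9,
effect_z = 10 for shared-variant (H4) regions and 8 for distinct-variant
(H3) regions, with H3 causal pairs drawn at |r| < 0.2 unless pinned.

MR datasets draw true exposure effects N(0.2, 0.05²) across independent
instruments, observed with SE 1/√n_exp, and outcome effects
θ·βx_true + α + noise with SE 1/√n_out (n_exp = 100,000, n_out = 50,000).
The exposure sample size is chosen so lead-instrument z-scores are in the
tens — the regime real cis-pQTL instruments occupy — making the
no-measurement-error assumption behind the IVW SE hold to within a few
percent of variance; with a much noisier exposure side the extra θ²σx²
dispersion is real and CI coverage genuinely drops, which is a property of
weak instruments, not an estimator defect.

What the generator does *not* emulate: individual-level genotypes, realistic
human LD panels (block structure, long-range LD), liability-scale effects
for binary traits, allele-frequency-dependent power, or sample overlap
between exposure and outcome studies. Passing tests therefore demonstrate
correctness and calibration of the estimators under their stated
assumptions, not robustness to those real-data complications.

## Numerical choices

* All normal/χ² tails via scipy; 95% intervals use z = 1.96 exactly.
* Coloc in log space; H3 non-negativity clamp; posteriors renormalized so
  they sum to 1 within 1e-9 even at z ≈ 40.
* BH step-up via reverse cumulative minimum; input order preserved.
* Clumping ties on p broken by ascending position (deterministic).
* Summary-statistics writer emits shortest-repr floats and the reader
  parses at round-trip precision, so write∘read is bit-exact for finite
  values.
* Singular LD matrices are rejected with advice to jitter rather than
  silently regularized.
* The MR-Egger fit is delegated to a standard weighted-least-squares
  routine; Wald/IVW/Q are closed-form.

## Problem sizes

Validation runs use deliberately moderate sizes chosen to make Monte-Carlo
error small relative to the assertion bands: 200 random instances for the
enumeration cross-check (≤6 variants, where exhaustive enumeration is
exact), 100 seeds per coloc scenario, 500 seeds for IVW/Egger parameter
recovery, 2,000 for Q and meta-analysis calibration, and 20,000 for the
type-I-error check at the 5×10⁻⁴ threshold used by the FDR-level MR
screen.

## Known limitations

* Single-causal-variant assumption in colocalization (no SuSiE-style
  multi-signal decomposition); secondary pQTL signals are handled only via
  externally supplied conditional statistics.
* LD clumping approximates conditional analysis; genes whose instruments
  came from approximate joint models elsewhere will not be reproduced
  exactly.
* No proxy-variant lookup: instruments absent from the outcome study are
  dropped.
* No Steiger filtering, weighted-median/mode estimators, or multivariable
  MR; the triage steps are the pleiotropy defense.
* The distance fallback in clumping treats physical distance as a proxy
  for LD and will over-merge in recombination hotspots and under-merge in
  long haplotypes.
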