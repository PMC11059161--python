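# Methods

`pqtlmr` implements a discovery pipeline for screening circulating proteins
against disease risk using *cis* protein quantitative trait loci (cis-pQTL)
as genetic instruments. This note records the statistical model behind each
component, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter.

## Instrument selection

A cis-pQTL is a variant associated with a protein's circulating
concentration whose position lies within a window (default 1 Mb) of the
protein's cognate gene body — measured from the gene's start and end
coordinates, not the TSS, so the cis window is
`[gene.start − 1 Mb, gene.end + 1 Mb]`. Candidates must pass four gates:

| gate | default | rationale |
| --- | --- | --- |
| association p-value | ≤ 5e-8 (primary) or ≤ 5e-5 (relaxed) | genome-wide significance; the relaxed mode reflects the strong prior that variants near the cognate gene affect the protein, and is recorded on each instrument as `source_threshold` |
| minor allele frequency | ≥ 0.01 | rare variants have unstable effect estimates and poor LD-reference coverage |
| single-variant F statistic `(beta/se)^2` | > 10 | the conventional weak-instrument bound |
| LD clumping | pairwise r² < 0.01 | near-independent instruments |

Clumping is greedy by ascending p-value; ties are broken by larger F, then
lexicographic rsid, so output is deterministic and invariant to input order.
The exposure (protein) GWAS allele frequency is authoritative when the two
studies disagree.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele: a swapped
allele pair flips the beta sign and replaces EAF with 1−EAF; a strand flip
is resolved by complementing alleles first. Palindromic variants (A/T, C/G)
cannot be strand-resolved from labels, so they are kept only when both EAFs
fall on the same side of 0.5 after alignment **and** MAF < 0.42 (the
`palindrome_eaf_limit`); otherwise the pair is dropped with a reason.
When an instrument is absent from an outcome GWAS, a proxy is sought in the
LD reference: the variant maximizing r² subject to r² ≥ 0.8 (the community
convention), with the sign of r applied so the proxy's beta is interpreted
on the instrument's effect allele. Both cut-offs are configurable;
harmonization is idempotent.

## MR estimation

The model object is `MendelianRandomization(beta_exp, se_exp, beta_out,
se_out)`; `fit(method=...)` returns an `MRResults` with the causal effect
`theta` per SD of exposure (log-odds for case-control outcomes), its SE,
the odds ratio with 95% CI (z = 1.959964), and a p-value.

* **Wald ratio** (single instrument, the primary discovery estimator):
  `theta = beta_out/beta_exp`, `se = se_out/|beta_exp|`. The first-order
  delta SE is used deliberately — it treats the exposure estimate as fixed,
  which is appropriate when the protein GWAS is much better powered than
  the outcome GWAS (F ≫ 10); the second-order correction is negligible in
  that regime.
* **IVW**: fixed-effect inverse-variance-weighted mean of per-instrument
  ratios. Fixed effect is the default because instrument counts here are
  modest and per-locus; random-effects variants are out of scope.
* **Weighted median**: ratios ordered ascending, weights ∝ 1/σ², estimate
  interpolated at the cumulative-weight midpoint 0.5; SE by seeded
  parametric bootstrap (default 2,000 resamples of θ_j ~ N(θ_j, σ_j)).
* **MR-Egger**: WLS of outcome on exposure betas with intercept, weights
  1/se_out², pairs oriented so beta_exp > 0 (the estimate is invariant to
  this convention). Slope and intercept p-values use a t distribution with
  n−2 df; with exactly two instruments the line is an exact fit and no
  inference is reported.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor: with
`V = se²`, `W = prior_sd²`, `r = W/(V+W)`, `z = beta/se`,

```
log ABF = 0.5·log(1−r) + r·z²/2
```

`prior_sd` defaults to 0.15 for quantitative traits and 0.2 for log-odds.
The five-hypothesis enumeration (H0 none, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared variant) uses per-SNP priors
p1 = p2 = 1e-4 and p12 = 1e-5 — the canonical defaults of the approach.
All hypothesis sums are evaluated in log space with log-sum-exp; the H3 term
`S1·S2 − S12` is computed via `log1p(−exp(·))`, never by subtracting raw
exponentials.

**Conditional-iterative route.** Each trait is first decomposed into
conditionally independent signals by stepwise forward selection on z-scores
against the LD reference: conditional z given selected set S is
`(z − R[:,S]·R[S,S]⁻¹·z_S)` rescaled by the conditional variance
`diag(I − R[:,S]·R[S,S]⁻¹·R[S,:])`. Selection continues while the minimum
conditional p ≤ 1e-6, up to 5 signals (both configurable; the stop rule
admits secondary signals without overfitting noise). A singular `R[S,S]`
falls back to a ridge-regularized inverse (λ = 1e-4) with a logged warning;
variants with conditional variance below 1e-10 get conditional z = 0
(pure LD shadows). Every signal pair across the two traits is then
colocalized; the decision statistic `pp4_max` is the greatest PP4 across the
conventional result and all conditional pairs, so it can only improve on
the conventional PP4. Colocalization in regions with irregular haplotype
structure (e.g. the chromosome-6 MHC region) remains fragile under any of
these settings; no algorithmic remedy is attempted.

## Multi-trait colocalization

For T traits the hypothesis space is "each trait null or causal at exactly
one SNP". Configuration priors extend the pairwise constants: the first
trait causal at a SNP contributes p1, each further trait sharing that SNP
contributes p12/p1, so a fully shared configuration has prior
`p1·(p12/p1)^(T−1)` and T = 2 reduces exactly to pairwise colocalization.
Because the prior couples traits landing on the same SNP, the normalizing
sum does not factorize trait-by-trait; it is evaluated exactly by Möbius
inversion over set partitions of the causal trait set (cost ≈ Bell(T)·m,
capped at T = 6), with signed log-sum-exp accumulation. A direct (m+1)^T
enumeration is kept as an independent reference implementation for tiny
inputs. Clustering is divisive and greedy, in the spirit of HyprColoc
(this is an independent implementation of the idea, not a port): start from
all traits and, while the shared posterior is below the threshold (default
0.7, matching the PP4 convention), remove the trait whose exclusion most
improves the remainder.

## Decision rules

* Colocalization is computed **only** for pairs with lead Wald p < 0.05
  (the gating is auditable: a coloc result exists iff the MR was nominally
  significant).
* `noteworthy`: Wald p < 0.05/N_proteins (N_proteins = unique proteins
  analysed for that outcome) **and** pp4_max > 0.7.
* `suggestive`: Wald p < 0.05 and pp4_max > 0.7.
* Replication re-estimates the discovery instrument against an external
  GWAS; "replicated" means same sign and p < 0.05 — a deliberate
  operationalization, since sign+nominal-significance is the weakest
  defensible criterion; an absent instrument with no proxy is
  "not evaluable", distinct from non-replication.
* Reverse MR instruments the outcome (p < 5e-8, clumped at r² < 0.01)
  against the protein. IVW and weighted median are always computed; the
  Egger intercept screens for directional pleiotropy and the Egger slope
  joins the consistency check when the intercept p < 0.05. The verdict is
  "supported" only when all computed methods agree in sign and the IVW p
  passes Bonferroni. Fewer than 3 usable instruments yields an
  "insufficient instruments" status.
* The PHEWAS screen applies the same Wald + gated-coloc machinery per trait
  with threshold 0.05/N_traits.

## Power calculation

For a binary outcome with case fraction `K`, instrument variance explained
`rsq` and odds ratio `OR`, the attenuated slope is
`b = K·(OR/(1+K·(OR−1)) − 1)` and the 1-df non-centrality is
`NCP = N·rsq·b²/(K(1−K) − b²)`; power is the upper tail of the non-central
chi-square beyond the central 1−α quantile. α defaults to 0.05. The minimum
detectable OR is found on a 0.01 grid rather than by root finding because
such thresholds are conventionally reported at that resolution.

## Synthetic data

Summary statistics are simulated directly from the sampling distribution of
marginal z-scores, `z ~ MVN(R·z_causal, R)`, with no individual-level
genotypes — sufficient for every consumer in this package and orders of
magnitude faster. Betas follow from `beta = z·se` with
`se = 1/sqrt(2·n·maf·(1−maf))` (quantitative) or the same with
`n_eff = 4/(1/n_case + 1/n_control)` (case-control log-odds). Defaults —
m = 200 variants, AR-1 LD with ρ = 0.9, MAF ~ U(0.05, 0.5), protein GWAS
n = 10,000, cancer GWAS 10,000/10,000 — were chosen once as typical
cis-region texture and typical proteomics/cancer-consortium sample sizes.
Scenario presets plant causal configurations matching the coloc hypotheses;
the H3 preset places the two causals at the AR-1 offset nearest the
requested r² (default 0.5). The default planted study effect (0.5 SD per
allele on the protein, 0.41 log-odds on the cancer) implies a Wald ratio of
0.82, OR 2.27 per SD — a magnitude representative of the strong protein
associations such screens report.

What the generator does **not** emulate: genotype-level sampling, winner's
curse in instrument discovery, sample overlap between exposure and outcome
GWAS, allele-frequency mismatch between studies, strand errors, or
irregular haplotype structure. Passing calibration tests therefore
demonstrates internal statistical correctness of the estimators and
decision rules under the assumed model, not robustness to those real-data
pathologies.

## Numerical choices and degenerate inputs

* All posterior arithmetic in log space; signed log-sum-exp for the
  alternating multi-trait partition sums, with tiny negative cancellations
  treated as zero.
* 95% intervals use z = 1.959964 throughout.
* p-values are clipped into (0, 1] (smallest positive double) so records
  remain valid after extreme z.
* A single-SNP region has PP3 = 0 identically (the log-difference term is
  −∞ by construction).
* Zero exposure beta raises a degenerate-instrument error rather than
  returning an infinite ratio.
* Region files with invalid rows (se ≤ 0, EAF outside (0,1), identical
  alleles) drop those rows with a logged count rather than failing.
* Numeric round trips preserve ≥ 10 significant digits (written at 12).

## Problem sizes used in validation

The shipped acceptance checks run: 200 seeded replicates per coloc scenario
preset; 100 seeds for conditional-signal recovery and for the
secondary-signal comparison; 10,000 null replicates for the Wald test size;
and 100 planted + 100 null synthetic studies of 20 proteins × 200 variants
for the end-to-end family-wise checks. These sizes give Monte-Carlo error
small enough to resolve the calibration bands being asserted while keeping
a full run in the low minutes on one CPU.

## Known limitations

* The Wald SE ignores exposure-side sampling error (first-order delta);
  with weak instruments this understates uncertainty — the F > 10 gate is
  the guard.
* Conditional signal selection uses the marginal-z approximation to joint
  conditioning; it assumes the LD reference matches the GWAS population.
* The multi-trait prior parameterization is a coloc-consistent mapping, not
  a reimplementation of any specific published tool's prior; posteriors for
  T > 2 should be compared across parameterizations before strong claims.
* No meta-analysis machinery: replication consumes a single pre-combined
  GWAS file.
* Effective-sample-size outcomes (meta-analysed GWAS reporting n_eff) are
  not specially handled in the power module; the case fraction is computed
  from the printed counts.
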