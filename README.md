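# pqtlmr

Cis-pQTL Mendelian randomisation and colocalization screening of circulating
proteins against disease GWAS.

## What this is for

Circulating proteins are attractive candidates for understanding disease
aetiology and for therapeutic prevention, because many are regulated by
genetic variants in or near their cognate gene (*cis* protein quantitative
trait loci, cis-pQTL). Using cis-pQTL as instruments, two-sample Mendelian
randomisation (MR) can screen thousands of proteins against disease GWAS
summary statistics while limiting confounding and reverse causation, and
colocalization can then exclude the main remaining artefact — confounding by
linkage disequilibrium (LD). `pqtlmr` implements that full screen for
analysts working with GWAS summary statistics:

* **Instrument QC** — cis-window selection, p-value / MAF / F-statistic
  gates, greedy LD clumping at r² < 0.01.
* **Harmonization** — allele alignment across studies, strand flips,
  palindrome policy, LD-proxy lookup.
* **MR estimation** — Wald ratio (θ = β_out/β_exp with SE(β_out)/|β_exp|)
  for single instruments; IVW, weighted median and MR-Egger for
  multi-instrument (e.g. reverse-direction) analyses. Effects are odds
  ratios per SD of protein concentration for case-control outcomes.
* **Colocalization** — Wakefield approximate-Bayes-factor posteriors
  PP0–PP4, both conventional and conditional-iterative (stepwise
  conditioning on an LD reference, then colocalizing every signal pair),
  with the decision statistic PP4_max = max over the two routes.
* **Multi-trait colocalization** — exact shared-causal-variant posterior
  for up to six traits with greedy divisive clustering.
* **Decision pipeline** — per-outcome Bonferroni tiering
  (noteworthy = p < 0.05/N_proteins and PP4_max > 0.7;
  suggestive = p < 0.05 and PP4_max > 0.7), replication against external
  GWAS, reverse MR with a sign-consistency verdict, and a PHEWAS screen.
* **Power** — binary-outcome MR power via the non-central chi-square
  approximation, and the minimum detectable OR at ≥ 80% power.
* **Simulation** — LD-structured regional summary statistics
  (z ~ MVN(R·z_causal, R)) under shared / distinct / null causal-variant
  scenarios, up to full on-disk synthetic studies, so every stage is
  testable without access to restricted consortium GWAS.

The statistical details, defaults and limitations are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a 200-variant cis region (AR-1 LD, ρ = 0.9) where the protein and
a case-control outcome share one causal variant, then run the core
estimators:

```python
from pqtlmr import preset_scenario, simulate_pair, Colocalization, wald_ratio

scenario = preset_scenario("H4", m=200, rho=0.9, seed=7)
protein, cancer, ld = simulate_pair(scenario)

lead = min(protein.records, key=lambda r: r.pvalue)   # lead cis-pQTL
mr = wald_ratio(lead, cancer.by_rsid(lead.variant.rsid))
print(mr.summary())

coloc = Colocalization(protein, cancer, ld=ld).fit("both")
print(coloc.summary())
```

```
Mendelian randomization results
==============================================
method                wald
exposure              r_t0
outcome               r_t1
n_snp                 1
theta (per SD)        0.904215
se(theta)             0.0641767
OR per SD             2.4700
95% CI (OR)           (2.1781, 2.8011)
p-value               4.41e-45
...
Colocalization (conditional_iterative)
----------------------------------------
  PP0 0.0000 ... PP4 1.0000
PP4_max over methods: 1.0000
```

The Wald OR of 2.47 (95% CI 2.18–2.80) is the estimated odds ratio per SD
increment in genetically predicted protein concentration — here recovering
the planted effect (true θ = 0.82, OR 2.27, inside the CI) — and
PP4_max = 1.00 says the two traits almost certainly share a single causal
variant, so the MR signal is not an LD artefact. A full synthetic study
(many proteins, one cancer GWAS, gene map, LD panels) is produced by
`pqtlmr.simulate_study` and screened by `pqtlmr.run_discovery`, or from the
shell:

```sh
pqtlmr simulate --preset study --n-proteins 20 --seed 1 --out study/
pqtlmr power --n-case 7638 --n-control 7364 --rsq 0.013
```

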