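"""Synthetic LD-structured regional GWAS summary statistics.

Marginal z-scores are simulated directly from their joint sampling model --
``z ~ MVN(R @ z_causal, R)`` for an LD correlation matrix ``R`` and a causal
z-vector with nonzero entries at the causal variants -- with no
individual-level genotypes.  Betas follow from ``beta = z * se`` where
``se = 1/sqrt(2*n*maf*(1-maf))`` for quantitative traits and
``se = 1/sqrt(2*n_eff*maf*(1-maf))`` with
``n_eff = 4/(1/n_case + 1/n_control)`` for case-control traits, the standard
large-sample approximations for an additively coded biallelic variant.

Scenario presets label the pairwise-colocalization hypotheses: H0 (neither
trait causal), H1/H2 (one trait causal), H3 (distinct causal variants at a
chosen r^2), H4 (one shared causal variant).  Default texture is a 200-variant
region with AR-1 LD at rho = 0.9 and allele frequencies U(0.05, 0.5).

:func:`simulate_study` writes a full on-disk study -- protein GWAS TSVs, one
cancer GWAS, a gene map, LD files and a truth table -- directly consumable by
:func:`pqtlmr.pipeline.run_discovery`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError
from .summary_io import (
    AssocRecord,
    LdMatrix,
    RegionStats,
    VariantKey,
    write_ld_matrix,
    write_region_stats,
)

DEFAULT_M = 200
DEFAULT_RHO = 0.9
DEFAULT_MAF = (0.05, 0.5)


@dataclass
class SimScenario:
    """Generative description of one synthetic region.

    ``causal_config`` holds one list of ``(variant_index, per_allele_beta)``
    per trait.  Trait 0 is quantitative (per-SD units, ``n_trait1`` samples);
    trait 1, when present, is case-control (log-odds units).
    """

    m: int = DEFAULT_M
    ld_model: tuple = ("ar1", DEFAULT_RHO)
    maf_dist: tuple[float, float] = DEFAULT_MAF
    causal_config: list[list[tuple[int, float]]] = field(default_factory=lambda: [[]])
    hypothesis_label: str | None = None
    n_trait1: int = 10_000
    n_case: int = 10_000
    n_control: int = 10_000
    seed: int = 0
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 5_000
    tag: str = "r"

    def __post_init__(self) -> None:
        for per_trait in self.causal_config:
            for idx, _ in per_trait:
                if not (0 <= idx < self.m):
                    raise InvalidParameterError(f"causal index {idx} outside region")
        kind, *params = self.ld_model
        if kind == "ar1":
            if not (-1.0 < params[0] < 1.0):
                raise InvalidParameterError("AR-1 rho must lie in (-1,1)")
        elif kind == "block":
            if not (-1.0 < params[1] < 1.0):
                raise InvalidParameterError("block rho must lie in (-1,1)")
        else:
            raise InvalidParameterError(f"unknown LD model {kind!r}")


def make_ld(scenario: SimScenario) -> LdMatrix:
    """Build the scenario's LD matrix (AR-1 or block-diagonal)."""
    kind, *params = scenario.ld_model
    m = scenario.m
    if kind == "ar1":
        rho = params[0]
        idx = np.arange(m)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        sizes, rho = params
        if sum(sizes) != m:
            raise InvalidParameterError("block sizes must sum to m")
        r = np.zeros((m, m))
        off = 0
        for s in sizes:
            r[off : off + s, off : off + s] = rho
            off += s
        np.fill_diagonal(r, 1.0)
    # Guard positive definiteness (exact AR-1 is PD already).
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        r = r + 1e-8 * np.eye(m)
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            raise InvalidParameterError("LD matrix not positive definite") from None
    variants = _variant_list(scenario)
    return LdMatrix(variants=variants, r=r, build_label="synthetic")


_ALLELES = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _variant_list(scenario: SimScenario) -> list[VariantKey]:
    return [
        VariantKey(
            chrom=scenario.chrom,
            pos=scenario.start + i * scenario.spacing,
            rsid=f"rs{scenario.tag}_{i}",
            effect_allele=_ALLELES[i % len(_ALLELES)][0],
            other_allele=_ALLELES[i % len(_ALLELES)][1],
        )
        for i in range(scenario.m)
    ]


def _eafs(scenario: SimScenario) -> np.ndarray:
    lo, hi = scenario.maf_dist
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    return rng.uniform(lo, hi, size=scenario.m)


def _chol(scenario: SimScenario) -> np.ndarray:
    kind, *params = scenario.ld_model
    m = scenario.m
    if kind == "ar1":
        rho = params[0]
        idx = np.arange(m)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        r = make_ld(scenario).r
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(r + 1e-8 * np.eye(m))


def simulate_region(
    scenario: SimScenario,
    trait_index: int = 0,
    _chol_cache: np.ndarray | None = None,
) -> RegionStats:
    """Simulate one trait's marginal summary statistics for the region.

    Deterministic given ``(scenario.seed, trait_index)``; the variant list and
    allele frequencies are shared across traits of the same scenario.
    """
    m = scenario.m
    variants = _variant_list(scenario)
    eaf = _eafs(scenario)
    quantitative = trait_index == 0
    if quantitative:
        n = float(scenario.n_trait1)
        n_eff = n
        trait_type = "quantitative"
        n_case = n_control = None
    else:
        n_case, n_control = float(scenario.n_case), float(scenario.n_control)
        n = n_case + n_control
        n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
        trait_type = "case_control"
    se = 1.0 / np.sqrt(2.0 * n_eff * eaf * (1.0 - eaf))

    z_causal = np.zeros(m)
    if trait_index < len(scenario.causal_config):
        for idx, beta in scenario.causal_config[trait_index]:
            z_causal[idx] = beta / se[idx]
    L = _chol_cache if _chol_cache is not None else _chol(scenario)
    mean = L @ (L.T @ z_causal)  # R @ z_causal
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 11, trait_index]))
    z = mean + L @ rng.standard_normal(m)
    beta = z * se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

    trait_id = f"trait{trait_index}" if not scenario.tag else f"{scenario.tag}_t{trait_index}"
    records = [
        AssocRecord(
            variant=variants[i],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pvals[i]),
            n=n,
            trait_id=trait_id,
            trait_type=trait_type,
            n_case=n_case,
            n_control=n_control,
        )
        for i in range(m)
    ]
    return RegionStats(records=records, build_label="synthetic")


def simulate_pair(scenario: SimScenario) -> tuple[RegionStats, RegionStats, LdMatrix]:
    """Simulate an aligned (quantitative, case-control) trait pair plus LD."""
    ld = make_ld(scenario)
    L = np.linalg.cholesky(ld.r)
    r1 = simulate_region(scenario, 0, _chol_cache=L)
    r2 = simulate_region(scenario, 1, _chol_cache=L)
    return r1, r2, ld


def _offset_for_r2(rho: float, r2: float) -> int:
    """Index offset with AR-1 correlation closest to the requested r^2."""
    import math

    if r2 <= 0:
        return 1
    d = math.log(r2) / (2.0 * math.log(abs(rho)))
    return max(1, round(d))


def preset_scenario(
    label: str,
    m: int = DEFAULT_M,
    rho: float = DEFAULT_RHO,
    seed: int = 0,
    beta1: float = 0.25,
    beta2: float = 0.2,
    h3_r2: float = 0.5,
    **kwargs,
) -> SimScenario:
    """Scenario presets keyed by the pairwise-colocalization hypothesis.

    ``beta1`` is the causal per-allele effect on the quantitative trait (SD
    units), ``beta2`` the per-allele log-odds effect on the case-control
    trait; ``h3_r2`` sets the LD between the two distinct causals under H3.
    """
    c = m // 2
    if label == "H0":
        config = [[], []]
    elif label == "H1":
        config = [[(c, beta1)], []]
    elif label == "H2":
        config = [[], [(c, beta2)]]
    elif label == "H3":
        off = _offset_for_r2(rho, h3_r2)
        config = [[(c, beta1)], [(min(c + off, m - 1), beta2)]]
    elif label == "H4":
        config = [[(c, beta1)], [(c, beta2)]]
    else:
        raise InvalidParameterError(f"unknown preset {label!r}")
    return SimScenario(
        m=m,
        ld_model=("ar1", rho),
        causal_config=config,
        hypothesis_label=label,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Full study layout
# ---------------------------------------------------------------------------


def simulate_study(
    out_dir: str | Path,
    n_proteins: int = 20,
    n_planted: int = 1,
    effect_grid: list[tuple[float, float]] | None = None,
    seed: int = 0,
    m: int = DEFAULT_M,
    rho: float = DEFAULT_RHO,
    n_protein_gwas: int = 10_000,
    n_case: int = 10_000,
    n_control: int = 10_000,
) -> Path:
    """Write a complete synthetic discovery study to ``out_dir``.

    Every protein receives a strong cis-pQTL at its region centre (per-allele
    effect from ``effect_grid``, default 0.5 SD); the first ``n_planted``
    proteins additionally share that causal variant with the cancer trait
    (default per-allele log-odds 0.41, i.e. a Wald ratio of 0.82, OR 2.27 per
    SD).  The remaining proteins have a null cancer region.  Layout::

        out_dir/
          genes.tsv             gene_id  chrom  start  end  protein_id
          proteins/<id>.tsv     protein GWAS per region
          outcome.tsv           cancer GWAS over all regions
          ld/<id>.{ld.txt,vars.tsv,meta.json}
          truth.tsv             planted effects

    Deterministic given ``seed``: rerunning writes identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "proteins").mkdir(parents=True, exist_ok=True)
    (out_dir / "ld").mkdir(parents=True, exist_ok=True)
    if effect_grid is None:
        effect_grid = [(0.5, 0.41)]

    genes = []
    truth = []
    outcome_frames = []
    for p in range(n_proteins):
        protein_id = f"P{p:03d}"
        beta_exp, beta_out = effect_grid[p % len(effect_grid)]
        planted = p < n_planted
        scenario = SimScenario(
            m=m,
            ld_model=("ar1", rho),
            causal_config=[
                [(m // 2, beta_exp)],
                [(m // 2, beta_out)] if planted else [],
            ],
            n_trait1=n_protein_gwas,
            n_case=n_case,
            n_control=n_control,
            seed=seed * 100_003 + p,
            chrom=str(p + 1),
            tag=protein_id,
        )
        prot, cancer, ld = simulate_pair(scenario)
        write_region_stats(prot, out_dir / "proteins" / f"{protein_id}.tsv")
        write_ld_matrix(
            ld,
            out_dir / "ld" / f"{protein_id}.ld.txt",
            out_dir / "ld" / f"{protein_id}.vars.tsv",
            out_dir / "ld" / f"{protein_id}.meta.json",
        )
        outcome_frames.append(cancer.to_dataframe())
        causal = prot.records[m // 2]
        genes.append(
            {
                "gene_id": f"G{p:03d}",
                "chrom": scenario.chrom,
                "start": causal.variant.pos - 10_000,
                "end": causal.variant.pos + 10_000,
                "protein_id": protein_id,
            }
        )
        if planted:
            truth.append(
                {
                    "protein_id": protein_id,
                    "causal_rsid": causal.variant.rsid,
                    "beta_exposure": beta_exp,
                    "beta_outcome": beta_out,
                    "theta": beta_out / beta_exp,
                }
            )

    pd.DataFrame(genes).to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    outcome = pd.concat(outcome_frames, ignore_index=True)
    outcome["trait_type"] = "case_control"
    outcome.to_csv(out_dir / "outcome.tsv", sep="\t", index=False, float_format="%.12g")
    truth_df = pd.DataFrame(
        truth,
        columns=["protein_id", "causal_rsid", "beta_exposure", "beta_outcome", "theta"],
    )
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "study.json", "w") as fh:
        json.dump(
            {
                "n_proteins": n_proteins,
                "n_planted": n_planted,
                "seed": seed,
                "m": m,
                "rho": rho,
            },
            fh,
            indent=2,
        )
    return out_dir
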