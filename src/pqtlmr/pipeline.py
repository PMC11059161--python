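"""Discovery orchestration: tiering, replication, reverse MR, PHEWAS.

Decision rules
--------------
* Per protein x outcome, the lead cis-pQTL (minimum exposure p after
  clumping) supplies the primary Wald ratio; every instrument's Wald ratio is
  reported, lead flagged.
* Colocalization is attempted only when the lead Wald p < 0.05; ``pp4_max``
  is the greater PP4 of conventional and conditional-iterative routes.
* Tiers: ``noteworthy`` = Bonferroni-significant MR (p < 0.05/N_proteins,
  N_proteins the unique proteins analysed for that outcome) AND
  pp4_max > 0.7; ``suggestive`` = nominal MR (p < 0.05) AND pp4_max > 0.7;
  otherwise ``null``.
* Replication: the discovery instrument re-estimated against an external
  GWAS; replicated iff same sign of theta and replication p < 0.05.
* Reverse MR: genome-wide-significant, clumped outcome instruments against
  the protein; IVW + weighted median always, Egger added when its intercept
  indicates pleiotropy (p < 0.05); supported iff all computed methods agree
  in sign and IVW p passes Bonferroni.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .coloc import ColocPriors, ColocResult, iterative_coloc
from .exceptions import (
    ContractViolationError,
    InsufficientInstrumentsError,
    PqtlMrError,
)
from .instruments import GeneAnnotation, Instrument, greedy_clump, select_cis_pqtl
from .mr import MendelianRandomization, MRResults, wald_ratio
from .summary_io import (
    AssocRecord,
    DropSignal,
    LdMatrix,
    RegionStats,
    find_proxy,
    harmonize_pair,
    read_ld_matrix,
    read_region_stats,
)

logger = logging.getLogger(__name__)

PP4_THRESHOLD = 0.7


@dataclass
class Thresholds:
    p_primary: float = 5e-8
    p_relaxed: float = 5e-5
    maf_min: float = 0.01
    f_min: float = 10.0
    r2_clump: float = 0.01
    pp4: float = PP4_THRESHOLD
    window: int = 1_000_000
    proxy_min_r2: float = 0.8
    palindrome_eaf_limit: float = 0.42


@dataclass
class StudyConfig:
    """Paths and thresholds for one discovery run."""

    proteins_dir: str
    outcome_path: str
    genes_path: str
    ld_dir: str
    outcome_id: str = "cancer"
    thresholds: Thresholds = field(default_factory=Thresholds)
    relaxed: bool = False
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)

    @classmethod
    def for_study_dir(cls, study_dir: str | Path, **kwargs) -> "StudyConfig":
        """Config pointing at a :func:`pqtlmr.simulate.simulate_study` layout."""
        study_dir = Path(study_dir)
        return cls(
            proteins_dir=str(study_dir / "proteins"),
            outcome_path=str(study_dir / "outcome.tsv"),
            genes_path=str(study_dir / "genes.tsv"),
            ld_dir=str(study_dir / "ld"),
            **kwargs,
        )


@dataclass
class TierCall:
    """Evidence tier for one protein-outcome pair."""

    protein_id: str
    outcome_id: str
    mr: MRResults
    coloc: ColocResult | None
    tier: str
    bonferroni_threshold: float
    instrument_rsid: str = ""
    exposure_record: AssocRecord | None = None
    all_instruments: list[MRResults] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "protein_id": self.protein_id,
            "outcome_id": self.outcome_id,
            "instrument_rsid": self.instrument_rsid,
            "theta": self.mr.theta,
            "se_theta": self.mr.se_theta,
            "or": self.mr.or_value,
            "ci_low": self.mr.ci_low,
            "ci_high": self.mr.ci_high,
            "pvalue": self.mr.pvalue,
            "tier": self.tier,
            "bonferroni_threshold": self.bonferroni_threshold,
        }
        if self.coloc is not None:
            row.update(
                {f"pp{i}": p for i, p in enumerate(self.coloc.posteriors)}
            )
            row["pp4_max"] = self.coloc.pp4_max
        else:
            row.update({f"pp{i}": None for i in range(5)})
            row["pp4_max"] = None
        return row


@dataclass
class ReplicationCall:
    protein_id: str
    outcome_id: str
    discovery: MRResults
    replication: MRResults | None
    replicated: bool | None  # None = not evaluable

    @property
    def status(self) -> str:
        if self.replicated is None:
            return "not_evaluable"
        return "replicated" if self.replicated else "not_replicated"


@dataclass
class ReverseMrReport:
    """IVW / weighted-median (/ Egger) triplet plus the paper-style verdict."""

    ivw: MRResults | None
    weighted_median: MRResults | None
    egger: MRResults | None
    egger_intercept_p: float | None
    verdict: str  # "supported" | "unsupported" | "insufficient_instruments"
    n_snp: int = 0


def bonferroni_tier(
    mr: MRResults,
    coloc: ColocResult | None,
    n_proteins: int,
    protein_id: str = "",
    outcome_id: str = "",
    pp4_threshold: float = PP4_THRESHOLD,
) -> TierCall:
    """Assign the evidence tier for one protein-outcome MR + coloc result.

    Colocalization must be absent when the MR p-value is not nominally
    significant (those pairs are never colocalized); supplying one raises
    :class:`ContractViolationError`.
    """
    if n_proteins < 1:
        raise ContractViolationError("n_proteins must be >= 1")
    threshold = 0.05 / n_proteins
    if mr.pvalue >= 0.05:
        if coloc is not None:
            raise ContractViolationError(
                "coloc result supplied for a pair with MR p >= 0.05"
            )
        tier = "null"
    elif coloc is not None and coloc.pp4_max > pp4_threshold:
        tier = "noteworthy" if mr.pvalue < threshold else "suggestive"
    else:
        tier = "null"
    return TierCall(
        protein_id=protein_id or mr.exposure_id,
        outcome_id=outcome_id or mr.outcome_id,
        mr=mr,
        coloc=coloc,
        tier=tier,
        bonferroni_threshold=threshold,
        instrument_rsid=mr.snp_rsids[0] if mr.snp_rsids else "",
    )


# ---------------------------------------------------------------------------
# Harmonization helpers
# ---------------------------------------------------------------------------


def _match_outcome(
    instrument: Instrument,
    outcome_region: RegionStats,
    ld: LdMatrix,
    thresholds: Thresholds,
) -> tuple[AssocRecord, AssocRecord] | None:
    """Harmonized (exposure, outcome) pair for one instrument, proxy fallback."""
    exp = instrument.record
    out = outcome_region.by_rsid(exp.variant.rsid)
    if out is None:
        try:
            proxy = find_proxy(exp.variant, outcome_region, ld, thresholds.proxy_min_r2)
        except PqtlMrError:
            return None
        if proxy is None:
            return None
        out, sign = proxy
        if sign < 0:
            out = replace(out, beta=-out.beta, eaf=1.0 - out.eaf)
        # The proxy's beta is now interpreted on the target's effect allele.
        return exp, replace(out, variant=exp.variant)
    result = harmonize_pair(exp, out, thresholds.palindrome_eaf_limit)
    if isinstance(result, DropSignal):
        logger.info("%s: dropped (%s)", exp.variant.rsid, result.reason)
        return None
    return result


def _gated_coloc(
    lead_mr: MRResults,
    protein_region: RegionStats,
    outcome_region: RegionStats,
    ld: LdMatrix,
    priors: ColocPriors,
) -> ColocResult | None:
    """Conventional + conditional-iterative coloc, gated on MR p < 0.05."""
    if lead_mr.pvalue >= 0.05:
        return None
    shared = [s for s in protein_region.rsids if outcome_region.by_rsid(s) is not None]
    if not shared:
        return None
    return iterative_coloc(
        protein_region.subset(shared),
        outcome_region.subset(shared),
        ld,
        priors,
    )


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


@dataclass
class _ProteinAnalysis:
    protein_id: str
    lead_mr: MRResults
    lead_exposure: AssocRecord
    all_mr: list[MRResults]
    coloc: ColocResult | None


def _analyse_protein(
    protein_id: str,
    protein_region: RegionStats,
    gene: GeneAnnotation,
    outcome_region: RegionStats,
    ld: LdMatrix,
    thresholds: Thresholds,
    relaxed: bool,
    priors: ColocPriors,
) -> _ProteinAnalysis | None:
    p_threshold = thresholds.p_relaxed if relaxed else thresholds.p_primary
    instruments = select_cis_pqtl(
        protein_region,
        gene,
        ld,
        p_threshold=p_threshold,
        window=thresholds.window,
        maf_min=thresholds.maf_min,
        f_min=thresholds.f_min,
        r2_clump=thresholds.r2_clump,
    )
    if not instruments:
        return None
    all_mr: list[MRResults] = []
    lead_mr: MRResults | None = None
    lead_exposure: AssocRecord | None = None
    for inst in instruments:  # sorted by ascending exposure p
        pair = _match_outcome(inst, outcome_region, ld, thresholds)
        if pair is None:
            continue
        try:
            res = wald_ratio(*pair)
        except PqtlMrError:
            continue
        all_mr.append(res)
        if lead_mr is None:
            lead_mr = res
            lead_exposure = pair[0]
    if lead_mr is None or lead_exposure is None:
        return None
    coloc_res = _gated_coloc(lead_mr, protein_region, outcome_region, ld, priors)
    return _ProteinAnalysis(
        protein_id=protein_id,
        lead_mr=lead_mr,
        lead_exposure=lead_exposure,
        all_mr=all_mr,
        coloc=coloc_res,
    )


def _region_outcome_stats(
    outcome_all: RegionStats, chrom: str, start: int, end: int
) -> RegionStats:
    records = [
        r
        for r in outcome_all.records
        if r.variant.chrom == chrom and start <= r.variant.pos <= end
    ]
    return RegionStats(records=records, build_label=outcome_all.build_label)


def read_gene_map(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            protein_id=str(row.protein_id),
        )
        for row in df.itertuples(index=False)
    ]


def run_discovery(
    config: StudyConfig, priors: ColocPriors | None = None
) -> list[TierCall]:
    """Run the full discovery screen described by ``config``.

    For each protein: select cis-pQTL instruments, harmonize against the
    outcome (rsid match, proxy fallback), compute per-instrument Wald ratios
    (lead = minimum exposure p), run gated colocalization, and assign a tier
    with the Bonferroni denominator equal to the number of proteins actually
    analysed.  Component failures are logged per-pair and the screen
    continues.  Deterministic given config: identical rerun gives identical
    output files.
    """
    priors = priors or ColocPriors()
    thresholds = config.thresholds
    genes = {g.protein_id: g for g in read_gene_map(config.genes_path)}
    outcome_all = read_region_stats(config.outcome_path, config.outcome_id)

    analyses: list[_ProteinAnalysis] = []
    protein_files = sorted(Path(config.proteins_dir).glob("*.tsv"))
    for pfile in protein_files:
        protein_id = pfile.stem
        gene = genes.get(protein_id)
        if gene is None:
            logger.warning("%s: no gene annotation; skipped", protein_id)
            continue
        try:
            region = read_region_stats(pfile, protein_id)
            ld = read_ld_matrix(
                Path(config.ld_dir) / f"{protein_id}.ld.txt",
                Path(config.ld_dir) / f"{protein_id}.vars.tsv",
                Path(config.ld_dir) / f"{protein_id}.meta.json",
            )
            outcome_region = _region_outcome_stats(
                outcome_all,
                gene.chrom,
                gene.start - thresholds.window,
                gene.end + thresholds.window,
            )
            analysis = _analyse_protein(
                protein_id,
                region,
                gene,
                outcome_region,
                ld,
                thresholds,
                config.relaxed,
                priors,
            )
        except PqtlMrError as exc:
            logger.warning("%s: %s; skipped", protein_id, exc)
            continue
        if analysis is not None:
            analyses.append(analysis)

    n_proteins = len(analyses)
    calls = [
        bonferroni_tier(
            a.lead_mr,
            a.coloc,
            n_proteins,
            protein_id=a.protein_id,
            outcome_id=config.outcome_id,
            pp4_threshold=thresholds.pp4,
        )
        for a in analyses
    ]
    for call, a in zip(calls, analyses):
        call.all_instruments = a.all_mr
        call.exposure_record = a.lead_exposure

    if config.out_dir is not None:
        write_results(calls, config.out_dir)
    return calls


def write_results(calls: list[TierCall], out_dir: str | Path) -> None:
    """Write the per-pair table as TSV and JSON (stable order, stable bytes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [c.to_row() for c in sorted(calls, key=lambda c: (c.outcome_id, c.protein_id))]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "results.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out_dir / "results.json", "w") as fh:
        json.dump(rows, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------


def replicate(
    discovery: TierCall,
    replication_outcome: RegionStats,
    ld: LdMatrix | None = None,
    thresholds: Thresholds | None = None,
) -> ReplicationCall:
    """Re-estimate a noteworthy discovery against an external outcome GWAS.

    Replicated iff the replication Wald ratio has the same sign as the
    discovery estimate and p < 0.05.  An instrument absent from the
    replication GWAS with no adequate proxy yields a ``not_evaluable`` call
    (distinct from non-replication).
    """
    if discovery.tier != "noteworthy":
        raise ContractViolationError("replication applies to noteworthy calls only")
    thresholds = thresholds or Thresholds()
    exposure = discovery.exposure_record
    if exposure is None:
        raise ContractViolationError("discovery call lacks its exposure record")
    out = replication_outcome.by_rsid(exposure.variant.rsid)
    pair: tuple[AssocRecord, AssocRecord] | None = None
    if out is not None:
        result = harmonize_pair(exposure, out, thresholds.palindrome_eaf_limit)
        if not isinstance(result, DropSignal):
            pair = result
    elif ld is not None:
        proxy = find_proxy(exposure.variant, replication_outcome, ld, thresholds.proxy_min_r2)
        if proxy is not None:
            out, sign = proxy
            if sign < 0:
                out = replace(out, beta=-out.beta, eaf=1.0 - out.eaf)
            pair = exposure, replace(out, variant=exposure.variant)
    if pair is None:
        return ReplicationCall(
            protein_id=discovery.protein_id,
            outcome_id=discovery.outcome_id,
            discovery=discovery.mr,
            replication=None,
            replicated=None,
        )
    rep = wald_ratio(*pair)
    ok = (rep.theta * discovery.mr.theta > 0) and (rep.pvalue < 0.05)
    return ReplicationCall(
        protein_id=discovery.protein_id,
        outcome_id=discovery.outcome_id,
        discovery=discovery.mr,
        replication=rep,
        replicated=bool(ok),
    )


# ---------------------------------------------------------------------------
# Reverse MR
# ---------------------------------------------------------------------------


def reverse_mr(
    outcome_region_set: RegionStats,
    protein_region: RegionStats,
    ld: LdMatrix,
    n_proteins: int,
    p_instrument: float = 5e-8,
    r2_clump: float = 0.01,
    seed: int = 0,
) -> ReverseMrReport:
    """Assess whether the outcome (cancer liability) affects protein levels.

    Instruments are genome-wide-significant (p < 5e-8), clumped (r^2 < 0.01)
    outcome variants harmonized against the protein GWAS.  IVW and weighted
    median are always computed; the Egger intercept screens for directional
    pleiotropy and, when its p < 0.05, the Egger slope joins the consistency
    check.  Verdict ``supported`` iff all computed methods agree in sign and
    the IVW p-value passes Bonferroni (0.05/n_proteins).
    """
    candidates = [r for r in outcome_region_set.records if r.pvalue < p_instrument]
    try:
        clumped = greedy_clump(candidates, ld, r2_clump)
    except PqtlMrError:
        clumped = [r for r in candidates if r.variant.rsid in ld]
        clumped = greedy_clump(clumped, ld, r2_clump)
    pairs = []
    for rec in clumped:
        prot = protein_region.by_rsid(rec.variant.rsid)
        if prot is None:
            continue
        result = harmonize_pair(rec, prot)
        if isinstance(result, DropSignal):
            continue
        pairs.append(result)
    if len(pairs) < 3:
        return ReverseMrReport(
            ivw=None,
            weighted_median=None,
            egger=None,
            egger_intercept_p=None,
            verdict="insufficient_instruments",
            n_snp=len(pairs),
        )
    model = MendelianRandomization.from_pairs(pairs)
    ivw_res = model.fit("ivw")
    wm_res = model.fit("weighted_median", seed=seed)
    egger_res = model.fit("egger")
    methods = [ivw_res, wm_res]
    pleiotropic = (
        egger_res.egger_intercept_p is not None
        and egger_res.egger_intercept_p == egger_res.egger_intercept_p  # not NaN
        and egger_res.egger_intercept_p < 0.05
    )
    report_egger = egger_res if pleiotropic else None
    if pleiotropic:
        methods.append(egger_res)
    signs = {1 if m.theta > 0 else (-1 if m.theta < 0 else 0) for m in methods}
    consistent = len(signs) == 1 and 0 not in signs
    supported = consistent and ivw_res.pvalue < 0.05 / n_proteins
    return ReverseMrReport(
        ivw=ivw_res,
        weighted_median=wm_res,
        egger=report_egger,
        egger_intercept_p=egger_res.egger_intercept_p,
        verdict="supported" if supported else "unsupported",
        n_snp=len(pairs),
    )


# ---------------------------------------------------------------------------
# PHEWAS
# ---------------------------------------------------------------------------


def run_phewas(
    protein_region: RegionStats,
    instruments: list[Instrument],
    trait_library: str | Path,
    ld: LdMatrix,
    n_traits: int | None = None,
    thresholds: Thresholds | None = None,
    priors: ColocPriors | None = None,
) -> list[TierCall]:
    """Screen one protein's instruments against a library of outcome GWAS.

    ``trait_library`` is a directory of per-trait regional TSVs.  Each trait
    gets a lead-instrument Wald ratio and gated colocalization; the
    multiple-testing threshold 0.05/n_traits (n_traits defaulting to the
    library size) is applied for the noteworthy tier.  Unreadable trait files
    are skipped with a log entry.
    """
    thresholds = thresholds or Thresholds()
    priors = priors or ColocPriors()
    files = sorted(Path(trait_library).glob("*.tsv"))
    if n_traits is None:
        n_traits = max(len(files), 1)
    calls: list[TierCall] = []
    for tfile in files:
        trait_id = tfile.stem
        try:
            trait_region = read_region_stats(tfile, trait_id)
        except PqtlMrError as exc:
            logger.warning("%s: %s; skipped", tfile, exc)
            continue
        lead_mr = None
        for inst in instruments:
            pair = _match_outcome(inst, trait_region, ld, thresholds)
            if pair is None:
                continue
            try:
                lead_mr = wald_ratio(*pair)
            except PqtlMrError:
                continue
            break
        if lead_mr is None:
            continue
        coloc_res = _gated_coloc(lead_mr, protein_region, trait_region, ld, priors)
        calls.append(
            bonferroni_tier(
                lead_mr,
                coloc_res,
                n_traits,
                protein_id=protein_region.trait_id,
                outcome_id=trait_id,
                pp4_threshold=thresholds.pp4,
            )
        )
    return calls
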