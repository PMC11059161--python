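"""Selection and QC of cis-pQTL instruments for one protein.

A cis-pQTL is a variant associated with circulating protein concentration
that lies within a window (default 1 Mb) of the protein's cognate gene body.
Candidates must pass a p-value gate (5e-8 primary, 5e-5 relaxed), a
minor-allele-frequency floor (0.01), and a single-variant F-statistic gate
(F > 10); survivors are LD-clumped greedily at r^2 < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError, MissingLdError
from .summary_io import AssocRecord, LdMatrix, RegionStats

P_PRIMARY = 5e-8
P_RELAXED = 5e-5


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-body coordinates defining a protein's cis window (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class Instrument:
    """A QC-passing cis-pQTL with its strength and clumping rank."""

    record: AssocRecord
    f_stat: float
    clump_index: int
    source_threshold: str  # "primary" (5e-8) or "relaxed" (5e-5)

    def __post_init__(self) -> None:
        if not self.f_stat > 0:
            raise ValueError("instrument F statistic must be positive")


def f_statistic(record: AssocRecord) -> float:
    """Single-variant instrument strength, ``(beta/se)**2``."""
    return (record.beta / record.se) ** 2


def _clump_priority(record: AssocRecord) -> tuple:
    # Ascending p; ties broken by larger F, then lexicographic rsid.
    return (record.pvalue, -f_statistic(record), record.variant.rsid)


def greedy_clump(
    candidates: list[AssocRecord],
    ld: LdMatrix,
    r2_clump: float = 0.01,
) -> list[AssocRecord]:
    """Greedy LD clumping by ascending p-value.

    A candidate is retained iff its r^2 with every already-retained candidate
    is strictly below ``r2_clump``.  The result is invariant to input order;
    p-value ties are broken by larger F statistic, then rsid.  Candidates
    absent from the LD panel raise :class:`MissingLdError`.
    """
    for rec in candidates:
        if rec.variant.rsid not in ld:
            raise MissingLdError(f"candidate {rec.variant.rsid} absent from LD panel")
    retained: list[AssocRecord] = []
    for rec in sorted(candidates, key=_clump_priority):
        ok = all(
            ld.r2_between(rec.variant.rsid, kept.variant.rsid) < r2_clump
            for kept in retained
        )
        if ok:
            retained.append(rec)
    return retained


def select_cis_pqtl(
    protein_region: RegionStats,
    gene: GeneAnnotation,
    ld: LdMatrix,
    p_threshold: float = P_PRIMARY,
    window: int = 1_000_000,
    maf_min: float = 0.01,
    f_min: float = 10.0,
    r2_clump: float = 0.01,
) -> list[Instrument]:
    """Select clumped, QC-passing cis-pQTL instruments for one protein.

    Candidates are variants with position in
    ``[gene.start - window, gene.end + window]``, ``p <= p_threshold``,
    MAF >= ``maf_min`` and F > ``f_min``; :func:`greedy_clump` is then applied
    and the survivors returned sorted by ascending p-value.
    """
    if protein_region.records and str(gene.chrom) != str(protein_region.chrom):
        raise ConfigurationError(
            f"gene {gene.gene_id} on chrom {gene.chrom} but region on "
            f"chrom {protein_region.chrom}"
        )
    lo = gene.start - window
    hi = gene.end + window
    candidates = [
        rec
        for rec in protein_region.records
        if lo <= rec.variant.pos <= hi
        and rec.pvalue <= p_threshold
        and rec.maf >= maf_min
        and f_statistic(rec) > f_min
    ]
    clumped = greedy_clump(candidates, ld, r2_clump)
    clumped.sort(key=_clump_priority)
    label = "primary" if p_threshold <= P_PRIMARY else "relaxed"
    return [
        Instrument(
            record=rec,
            f_stat=f_statistic(rec),
            clump_index=i,
            source_threshold=label,
        )
        for i, rec in enumerate(clumped)
    ]
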