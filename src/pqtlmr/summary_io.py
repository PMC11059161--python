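"""GWAS summary-statistics data model, file I/O and cross-study harmonization.

The in-memory unit is :class:`AssocRecord` -- one variant's marginal
association with one trait -- grouped into a :class:`RegionStats` (all records
for one trait in one genomic region, in a stable order).  Pairwise LD between
the variants of a region is carried by :class:`LdMatrix`, which stores signed
correlations ``r`` (clumping consumes ``r**2``; proxy alignment needs the
sign).

Files are tab-delimited with GWAS-SSF-style column names
(``chromosome``, ``base_pair_location``, ``rsid``, ``effect_allele``,
``other_allele``, ``effect_allele_frequency``, ``beta``, ``standard_error``,
``p_value``, ``n``, ``n_case``, ``n_control``); the short synonyms
``chrom``/``pos``/``eaf``/``se``/``pvalue`` are accepted on input.  LD panels
are a whitespace-delimited square matrix plus a variant-list sidecar and a
JSON metadata sidecar.  Positions are 1-based; one genome build per run,
carried as an opaque label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    MissingLdError,
    SummaryFormatError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Column synonyms accepted on input, mapped to canonical internal names.
_COLUMN_SYNONYMS = {
    "chromosome": "chrom",
    "chrom": "chrom",
    "base_pair_location": "pos",
    "pos": "pos",
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_allele_frequency": "eaf",
    "eaf": "eaf",
    "beta": "beta",
    "standard_error": "se",
    "se": "se",
    "p_value": "pvalue",
    "pvalue": "pvalue",
    "n": "n",
    "n_case": "n_case",
    "n_control": "n_control",
    "trait_type": "trait_type",
}

_MANDATORY = [
    "chrom",
    "pos",
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
]

#: Output column order (GWAS-SSF names).
_SSF_COLUMNS = [
    "chromosome",
    "base_pair_location",
    "rsid",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
    "n_case",
    "n_control",
    "trait_type",
]


def complement_allele(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variants read identically on both strands."""
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic variant with a declared effect allele."""

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom))
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass(frozen=True)
class AssocRecord:
    """One variant's marginal association with one trait.

    ``beta`` is in per-SD units for quantitative traits and on the log-odds
    scale for case-control traits.
    """

    variant: VariantKey
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    trait_id: str
    trait_type: str = "quantitative"
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant.rsid}: eaf must lie in (0,1)")
        if not self.se > 0:
            raise ValueError(f"{self.variant.rsid}: se must be positive")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant.rsid}: pvalue must lie in (0,1]")
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.n_case is None or self.n_control is None:
                raise ValueError("case_control records need n_case and n_control")
            if abs((self.n_case + self.n_control) - self.n) > 0.5:
                raise ValueError(
                    f"{self.variant.rsid}: n_case + n_control must equal n"
                )

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class RegionStats:
    """All :class:`AssocRecord` of one trait in one genomic region."""

    records: list[AssocRecord]
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    build_label: str = ""

    def __post_init__(self) -> None:
        rsids = [r.variant.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate variant rsids in region")
        traits = {r.trait_id for r in self.records}
        if len(traits) > 1:
            raise ValueError(f"records span multiple traits: {sorted(traits)}")
        if self.records and self.chrom is None:
            self.chrom = self.records[0].variant.chrom
        if self.records and self.start is None:
            self.start = min(r.variant.pos for r in self.records)
        if self.records and self.end is None:
            self.end = max(r.variant.pos for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def trait_id(self) -> str:
        if not self.records:
            return ""
        return self.records[0].trait_id

    @property
    def rsids(self) -> list[str]:
        return [r.variant.rsid for r in self.records]

    def by_rsid(self, rsid: str) -> AssocRecord | None:
        for r in self.records:
            if r.variant.rsid == rsid:
                return r
        return None

    def subset(self, rsids: Sequence[str]) -> "RegionStats":
        """Records for ``rsids`` in the given order (missing ones skipped)."""
        index = {r.variant.rsid: r for r in self.records}
        return RegionStats(
            records=[index[s] for s in rsids if s in index],
            chrom=self.chrom,
            build_label=self.build_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "chromosome": r.variant.chrom,
                    "base_pair_location": r.variant.pos,
                    "rsid": r.variant.rsid,
                    "effect_allele": r.variant.effect_allele,
                    "other_allele": r.variant.other_allele,
                    "effect_allele_frequency": r.eaf,
                    "beta": r.beta,
                    "standard_error": r.se,
                    "p_value": r.pvalue,
                    "n": r.n,
                    "n_case": r.n_case,
                    "n_control": r.n_control,
                    "trait_type": r.trait_type,
                }
            )
        return pd.DataFrame(rows, columns=_SSF_COLUMNS)


@dataclass
class LdMatrix:
    """Signed pairwise LD correlations aligned to an ordered variant list."""

    variants: list[VariantKey]
    r: np.ndarray
    build_label: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variants)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m},{m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v.rsid: i for i, v in enumerate(self.variants)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index_of(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise MissingLdError(f"variant {rsid} absent from LD panel") from None

    def r_between(self, rsid_a: str, rsid_b: str) -> float:
        return float(self.r[self.index_of(rsid_a), self.index_of(rsid_b)])

    def r2_between(self, rsid_a: str, rsid_b: str) -> float:
        return self.r_between(rsid_a, rsid_b) ** 2

    def submatrix(self, rsids: Sequence[str]) -> "LdMatrix":
        idx = [self.index_of(s) for s in rsids]
        return LdMatrix(
            variants=[self.variants[i] for i in idx],
            r=self.r[np.ix_(idx, idx)],
            build_label=self.build_label,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_SYNONYMS:
            renames[col] = _COLUMN_SYNONYMS[key]
    return df.rename(columns=renames)


def read_region_stats(path: str | Path, trait_id: str) -> RegionStats:
    """Read a tab-delimited summary-statistics file into a validated region.

    Rows violating :class:`AssocRecord` invariants (se<=0, eaf outside (0,1),
    identical alleles, ...) are dropped with a logged count.  A missing
    mandatory column raises :class:`SummaryFormatError` naming the column; an
    empty file raises :class:`EmptyInputError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty summary-statistics file") from None
    df = _canonical_columns(df)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SummaryFormatError(f"{path}: missing mandatory column {col!r}")
    if not any(c in df.columns for c in ("n", "n_case")):
        raise SummaryFormatError(f"{path}: missing sample-size column ('n' or 'n_case')")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    records: list[AssocRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            variant = VariantKey(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                rsid=str(d["rsid"]),
                effect_allele=str(d["effect_allele"]),
                other_allele=str(d["other_allele"]),
            )
            n_case = d.get("n_case")
            n_control = d.get("n_control")
            n_case = None if n_case is None or pd.isna(n_case) else float(n_case)
            n_control = (
                None if n_control is None or pd.isna(n_control) else float(n_control)
            )
            trait_type = d.get("trait_type")
            if trait_type is None or pd.isna(trait_type):
                trait_type = "case_control" if n_case is not None else "quantitative"
            n = d.get("n")
            if n is None or pd.isna(n):
                if n_case is None or n_control is None:
                    raise ValueError("no usable sample size")
                n = n_case + n_control
            records.append(
                AssocRecord(
                    variant=variant,
                    eaf=float(d["eaf"]),
                    beta=float(d["beta"]),
                    se=float(d["se"]),
                    pvalue=float(d["pvalue"]),
                    n=float(n),
                    trait_id=trait_id,
                    trait_type=str(trait_type),
                    n_case=n_case,
                    n_control=n_control,
                )
            )
        except (ValueError, KeyError, TypeError):
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d invalid row(s)", path, dropped)
    return RegionStats(records=records)


def write_region_stats(stats: RegionStats, path: str | Path) -> None:
    """Write a region back to a tab-delimited GWAS-SSF-style file.

    Numeric fields are written with 12 significant digits so a round trip
    preserves them well beyond 10 significant digits.
    """
    df = stats.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ld_matrix(
    matrix_path: str | Path,
    variants_path: str | Path,
    meta_path: str | Path | None = None,
) -> LdMatrix:
    """Read an LD panel: square matrix file + variant list (+ JSON metadata)."""
    r = np.loadtxt(matrix_path, dtype=float, ndmin=2)
    vdf = pd.read_csv(variants_path, sep="\t")
    vdf = _canonical_columns(vdf)
    variants = [
        VariantKey(
            chrom=str(row.chrom),
            pos=int(row.pos),
            rsid=str(row.rsid),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
        )
        for row in vdf.itertuples(index=False)
    ]
    build_label = ""
    if meta_path is not None and Path(meta_path).exists():
        with open(meta_path) as fh:
            build_label = json.load(fh).get("build_label", "")
    return LdMatrix(variants=variants, r=r, build_label=build_label)


def write_ld_matrix(
    ld: LdMatrix,
    matrix_path: str | Path,
    variants_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g")
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "rsid": v.rsid,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
        }
        for v in ld.variants
    ]
    pd.DataFrame(rows).to_csv(variants_path, sep="\t", index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump({"build_label": ld.build_label, "m": len(ld.variants)}, fh)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropSignal:
    """Sentinel returned when a pair cannot be safely harmonized."""

    reason: str


def _aligned_variant(outcome: AssocRecord, exposure_key: VariantKey) -> VariantKey:
    return replace(
        outcome.variant,
        effect_allele=exposure_key.effect_allele,
        other_allele=exposure_key.other_allele,
    )


def harmonize_pair(
    exposure: AssocRecord,
    outcome: AssocRecord,
    palindrome_eaf_limit: float = 0.42,
) -> tuple[AssocRecord, AssocRecord] | DropSignal:
    """Re-express ``outcome`` on the exposure's effect allele.

    If the outcome's effect allele equals the exposure's other allele, the
    outcome beta sign is flipped and its EAF replaced by ``1 - eaf``.  Strand
    mismatches are resolved by complementing the outcome alleles first.
    Palindromic variants (A/T or C/G), whose strand cannot be resolved from
    allele labels, are retained only when both EAFs fall on the same side of
    0.5 after alignment and the minor-allele frequency is below
    ``palindrome_eaf_limit``; otherwise a :class:`DropSignal` is returned.

    Harmonizing an already-harmonized pair is a no-op (idempotence).
    """
    ek, ok = exposure.variant, outcome.variant

    if ek.is_palindromic:
        if ok.alleles != ek.alleles:
            return DropSignal("incompatible-alleles")
        flipped = ok.effect_allele == ek.other_allele
        eaf_out = 1.0 - outcome.eaf if flipped else outcome.eaf
        beta_out = -outcome.beta if flipped else outcome.beta
        if (exposure.eaf - 0.5) * (eaf_out - 0.5) <= 0:
            return DropSignal("ambiguous-palindrome")
        if min(eaf_out, 1.0 - eaf_out) >= palindrome_eaf_limit:
            return DropSignal("ambiguous-palindrome")
        harmonized = replace(
            outcome,
            variant=_aligned_variant(outcome, ek),
            beta=beta_out,
            eaf=eaf_out,
        )
        return exposure, harmonized

    alleles_out = ok.alleles
    if alleles_out == ek.alleles:
        eff, oth = ok.effect_allele, ok.other_allele
    else:
        eff = _COMPLEMENT.get(ok.effect_allele)
        oth = _COMPLEMENT.get(ok.other_allele)
        if eff is None or oth is None or {eff, oth} != set(ek.alleles):
            logger.info(
                "%s: alleles irreconcilable (%s/%s vs %s/%s)",
                ek.rsid,
                ek.effect_allele,
                ek.other_allele,
                ok.effect_allele,
                ok.other_allele,
            )
            return DropSignal("incompatible-alleles")
    if eff == ek.effect_allele:
        harmonized = replace(outcome, variant=_aligned_variant(outcome, ek))
    else:
        harmonized = replace(
            outcome,
            variant=_aligned_variant(outcome, ek),
            beta=-outcome.beta,
            eaf=1.0 - outcome.eaf,
        )
    return exposure, harmonized


def harmonize_regions(
    exposure_region: RegionStats,
    outcome_region: RegionStats,
    palindrome_eaf_limit: float = 0.42,
) -> tuple[RegionStats, RegionStats]:
    """Intersect two regions on rsid and harmonize record-by-record.

    Drop signals are logged and the variant excluded from both sides; record
    order follows the exposure region.
    """
    out_index = {r.variant.rsid: r for r in outcome_region.records}
    exp_keep: list[AssocRecord] = []
    out_keep: list[AssocRecord] = []
    dropped = 0
    for exp in exposure_region.records:
        out = out_index.get(exp.variant.rsid)
        if out is None:
            continue
        result = harmonize_pair(exp, out, palindrome_eaf_limit)
        if isinstance(result, DropSignal):
            dropped += 1
            continue
        exp_keep.append(result[0])
        out_keep.append(result[1])
    if dropped:
        logger.info(
            "harmonize_regions(%s, %s): dropped %d pair(s)",
            exposure_region.trait_id,
            outcome_region.trait_id,
            dropped,
        )
    return (
        RegionStats(records=exp_keep, build_label=exposure_region.build_label),
        RegionStats(records=out_keep, build_label=outcome_region.build_label),
    )


def find_proxy(
    target: VariantKey,
    outcome_region: RegionStats,
    ld: LdMatrix,
    min_r2: float = 0.8,
) -> tuple[AssocRecord, int] | None:
    """Best-LD proxy for ``target`` among the outcome region's variants.

    Returns the outcome record maximizing ``r**2`` with the target subject to
    ``r**2 >= min_r2``, together with the alignment sign ``sign(r)`` (to be
    applied so the proxy's beta is interpreted on the target's effect allele),
    or ``None`` when no variant qualifies.  Raises :class:`MissingLdError`
    when the target is absent from the LD panel.
    """
    ti = ld.index_of(target.rsid)
    best: tuple[float, AssocRecord, int] | None = None
    for rec in outcome_region.records:
        if rec.variant.rsid not in ld:
            continue
        r = float(ld.r[ti, ld.index_of(rec.variant.rsid)])
        r2 = r * r
        if r2 < min_r2:
            continue
        if best is None or r2 > best[0]:
            sign = 1 if r >= 0 else -1
            best = (r2, rec, sign)
    if best is None:
        return None
    return best[1], best[2]
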