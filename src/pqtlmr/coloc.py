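"""Pairwise colocalization via Wakefield approximate Bayes factors.

Given regional summary statistics for two traits over a shared variant list,
the five-hypothesis enumeration assigns posterior probability to

* H0 -- no causal variant for either trait,
* H1/H2 -- a causal variant for trait 1 / trait 2 only,
* H3 -- two distinct causal variants (confounding by LD),
* H4 -- one shared causal variant.

Two routes are provided: conventional colocalization over the marginal
statistics, and conditional-iterative colocalization, which first decomposes
each trait into conditionally independent association signals (stepwise
conditioning on an LD reference) and then colocalizes every signal pair.
``pp4_max`` -- the greatest PP4 across the two routes -- is the decision
statistic used downstream (PP4_max > 0.7).

All hypothesis arithmetic is done in log space with log-sum-exp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .exceptions import EmptyOverlapError, InvalidParameterError
from .summary_io import AssocRecord, LdMatrix, RegionStats

logger = logging.getLogger(__name__)

#: Default per-SNP priors: causality for one trait (p1, p2) and shared (p12).
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Default effect-size prior scales for the Wakefield ABF.
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2


@dataclass(frozen=True)
class ColocPriors:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise InvalidParameterError("require 0 < p12 <= min(p1, p2)")


@dataclass
class ColocResult:
    """Posterior probabilities for one trait pair in one region."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    method: str  # "conventional" or "conditional_iterative"
    n_signals_1: int = 1
    n_signals_2: int = 1
    pp4_max: float = 0.0
    signal_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")
        if self.pp4_max == 0.0:
            self.pp4_max = self.pp4

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp0,
            "pp1": self.pp1,
            "pp2": self.pp2,
            "pp3": self.pp3,
            "pp4": self.pp4,
            "method": self.method,
            "n_signals_1": self.n_signals_1,
            "n_signals_2": self.n_signals_2,
            "pp4_max": self.pp4_max,
        }

    def summary(self) -> str:
        lines = [
            f"Colocalization ({self.method})",
            "-" * 40,
        ]
        for i, pp in enumerate(self.posteriors):
            lines.append(f"  PP{i} {pp:.4f}")
        lines.append(f"  PP4_max {self.pp4_max:.4f}")
        return "\n".join(lines)


def default_prior_sd(region: RegionStats) -> float:
    """Effect-size prior scale by trait type (0.15 quantitative, 0.2 log-odds)."""
    if region.records and region.records[0].trait_type == "case_control":
        return PRIOR_SD_CASE_CONTROL
    return PRIOR_SD_QUANTITATIVE


def log_abf(record: AssocRecord, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    With ``V = se**2``, ``W = prior_sd**2``, shrinkage ``r = W/(V+W)`` and
    ``z = beta/se``::

        log ABF = 0.5*log(1 - r) + r * z**2 / 2

    Positive values favour causality; ``z = 0`` gives the (negative)
    no-association penalty and ``se -> inf`` gives 0 (no information).
    """
    if prior_sd <= 0:
        raise InvalidParameterError("prior_sd must be positive")
    V = record.se**2
    W = prior_sd**2
    r = W / (V + W)
    z = record.beta / record.se
    return 0.5 * math.log1p(-r) + r * z * z / 2.0


def _log_abf_vector(region: RegionStats, prior_sd: float) -> np.ndarray:
    return np.array([log_abf(rec, prior_sd) for rec in region.records])


def _posteriors_from_labf(
    l1: np.ndarray, l2: np.ndarray, priors: ColocPriors
) -> np.ndarray:
    """Normalized PP0..PP4 from per-SNP log ABFs of the two traits."""
    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = math.log(priors.p1) + log_s1
    lh2 = math.log(priors.p2) + log_s2
    # H3: sum over ordered distinct pairs = S1*S2 - S12, kept in log space.
    diff = log_s12 - (log_s1 + log_s2)
    if diff >= 0:
        lh3 = -np.inf  # m = 1, or cancellation to zero
    else:
        lh3 = math.log(priors.p1) + math.log(priors.p2) + log_s1 + log_s2 + math.log1p(
            -math.exp(diff)
        )
    lh4 = math.log(priors.p12) + log_s12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    return np.exp(lh - logsumexp(lh))


def coloc_posteriors(
    region1: RegionStats,
    region2: RegionStats,
    priors: ColocPriors | None = None,
    prior_sd_1: float | None = None,
    prior_sd_2: float | None = None,
) -> ColocResult:
    """Conventional colocalization of two traits over their shared variants.

    The variant intersection (on rsid, in region-1 order) is taken and logged;
    an empty overlap raises :class:`EmptyOverlapError`.
    """
    priors = priors or ColocPriors()
    shared = [s for s in region1.rsids if s in set(region2.rsids)]
    if not shared:
        raise EmptyOverlapError("no shared variants between regions")
    if len(shared) < len(region1) or len(shared) < len(region2):
        logger.info(
            "coloc: intersected to %d shared variants (%d vs %d)",
            len(shared),
            len(region1),
            len(region2),
        )
    r1 = region1.subset(shared)
    r2 = region2.subset(shared)
    sd1 = prior_sd_1 if prior_sd_1 is not None else default_prior_sd(r1)
    sd2 = prior_sd_2 if prior_sd_2 is not None else default_prior_sd(r2)
    pp = _posteriors_from_labf(_log_abf_vector(r1, sd1), _log_abf_vector(r2, sd2), priors)
    return ColocResult(*pp, method="conventional")


# ---------------------------------------------------------------------------
# Conditional-iterative route
# ---------------------------------------------------------------------------


def conditional_signals(
    region: RegionStats,
    ld: LdMatrix,
    p_stop: float = 1e-6,
    max_signals: int = 5,
) -> list[RegionStats]:
    """Decompose a region into conditionally independent association signals.

    Stepwise forward selection on z-scores against the LD reference: the
    first signal is the minimum-p variant; conditional z-scores given the
    selected set ``S`` are::

        z_cond = (z - R[:,S] @ inv(R[S,S]) @ z[S]) / sqrt(diag(I - R[:,S] @ inv(R[S,S]) @ R[S,:]))

    and selection continues while the minimum conditional p is at most
    ``p_stop`` and fewer than ``max_signals`` are selected.  For each selected
    signal ``s`` the region's statistics conditioned on ``S \\ {s}`` are
    returned (betas rescaled from conditional z at unchanged SE); with a
    single signal this is the original region.  A singular ``R[S,S]`` falls
    back to a ridge-regularized inverse (lambda = 1e-4) with a logged warning.

    Returns an empty list when no variant reaches ``p_stop``.
    """
    if len(region) == 0:
        return []
    sub = ld.submatrix(region.rsids)
    R = sub.r
    z = np.array([rec.z for rec in region.records])

    def cond_z(selected: list[int]) -> np.ndarray:
        if not selected:
            return z.copy()
        S = np.array(selected)
        Rss = R[np.ix_(S, S)]
        RxS = R[:, S]
        try:
            inv = np.linalg.inv(Rss)
        except np.linalg.LinAlgError:
            inv = None
        if inv is None or np.linalg.cond(Rss) > 1e8:
            logger.warning("singular LD submatrix; applying ridge 1e-4")
            inv = np.linalg.inv(Rss + 1e-4 * np.eye(len(S)))
        resid = z - RxS @ inv @ z[S]
        var = 1.0 - np.einsum("ij,jk,ik->i", RxS, inv, RxS)
        var = np.clip(var, 0.0, None)
        out = np.zeros_like(z)
        ok = var > 1e-10
        out[ok] = resid[ok] / np.sqrt(var[ok])
        out[S] = 0.0
        return out

    selected: list[int] = []
    while len(selected) < max_signals:
        zc = cond_z(selected)
        mask = np.ones(len(z), dtype=bool)
        mask[selected] = False
        if not mask.any():
            break
        cand = int(np.flatnonzero(mask)[np.argmax(np.abs(zc[mask]))])
        p = 2.0 * stats.norm.sf(abs(zc[cand]))
        if p > p_stop:
            break
        selected.append(cand)

    out_regions: list[RegionStats] = []
    for s in selected:
        others = [j for j in selected if j != s]
        if not others:
            # Nothing to condition on: the signal's statistics are the originals.
            out_regions.append(
                RegionStats(records=list(region.records), build_label=region.build_label)
            )
            continue
        zc = cond_z(others)
        records = []
        for i, rec in enumerate(region.records):
            beta = zc[i] * rec.se
            pv = min(1.0, max(2.0 * stats.norm.sf(abs(zc[i])), np.nextafter(0, 1)))
            records.append(replace(rec, beta=beta, pvalue=pv))
        out_regions.append(RegionStats(records=records, build_label=region.build_label))
    return out_regions


def iterative_coloc(
    region1: RegionStats,
    region2: RegionStats,
    ld: LdMatrix,
    priors: ColocPriors | None = None,
    prior_sd_1: float | None = None,
    prior_sd_2: float | None = None,
    p_stop: float = 1e-6,
    max_signals: int = 5,
) -> ColocResult:
    """Conditional-iterative colocalization with ``pp4_max`` attached.

    Every pair of (conditioned signal of trait 1) x (conditioned signal of
    trait 2) is colocalized conventionally; the returned posteriors are those
    of the maximal-PP4 pair and ``pp4_max`` is the maximum PP4 over the
    conventional result and all conditional pairs.  A trait with no signal
    reaching ``p_stop`` contributes its unconditioned statistics as a single
    signal, so one signal per trait reduces exactly to conventional
    colocalization.
    """
    priors = priors or ColocPriors()
    conventional = coloc_posteriors(region1, region2, priors, prior_sd_1, prior_sd_2)
    sig1 = conditional_signals(region1, ld, p_stop, max_signals) or [region1]
    sig2 = conditional_signals(region2, ld, p_stop, max_signals) or [region2]

    best: ColocResult | None = None
    best_pair = (0, 0)
    for i, s1 in enumerate(sig1):
        for j, s2 in enumerate(sig2):
            res = coloc_posteriors(s1, s2, priors, prior_sd_1, prior_sd_2)
            if best is None or res.pp4 > best.pp4:
                best = res
                best_pair = (i, j)
    assert best is not None
    pp4_max = max(conventional.pp4, best.pp4)
    return ColocResult(
        best.pp0,
        best.pp1,
        best.pp2,
        best.pp3,
        best.pp4,
        method="conditional_iterative",
        n_signals_1=len(sig1),
        n_signals_2=len(sig2),
        pp4_max=pp4_max,
        signal_pair=best_pair,
    )


# ---------------------------------------------------------------------------
# Model-class surface
# ---------------------------------------------------------------------------


@dataclass
class ColocResults:
    """Results of :meth:`Colocalization.fit`: both routes plus ``pp4_max``."""

    conventional: ColocResult
    conditional: ColocResult | None
    pp4_max: float

    def summary(self) -> str:
        parts = [self.conventional.summary()]
        if self.conditional is not None:
            parts.append(self.conditional.summary())
        parts.append(f"PP4_max over methods: {self.pp4_max:.4f}")
        return "\n".join(parts)


class Colocalization:
    """Colocalization model for one trait pair in one region.

    ``fit(method=...)`` with ``"conventional"``, ``"conditional"`` or
    ``"both"`` (default); the conditional routes require an LD reference.
    """

    def __init__(
        self,
        region1: RegionStats,
        region2: RegionStats,
        ld: LdMatrix | None = None,
        priors: ColocPriors | None = None,
        prior_sd_1: float | None = None,
        prior_sd_2: float | None = None,
        p_stop: float = 1e-6,
        max_signals: int = 5,
    ) -> None:
        self.region1 = region1
        self.region2 = region2
        self.ld = ld
        self.priors = priors or ColocPriors()
        self.prior_sd_1 = prior_sd_1
        self.prior_sd_2 = prior_sd_2
        self.p_stop = p_stop
        self.max_signals = max_signals

    def fit(self, method: str = "both") -> ColocResults:
        conventional = coloc_posteriors(
            self.region1, self.region2, self.priors, self.prior_sd_1, self.prior_sd_2
        )
        conditional = None
        if method in ("conditional", "both"):
            if self.ld is None:
                raise InvalidParameterError(
                    "conditional colocalization requires an LD matrix"
                )
            conditional = iterative_coloc(
                self.region1,
                self.region2,
                self.ld,
                self.priors,
                self.prior_sd_1,
                self.prior_sd_2,
                self.p_stop,
                self.max_signals,
            )
        elif method != "conventional":
            raise ValueError(f"unknown coloc method {method!r}")
        pp4_max = conventional.pp4
        if conditional is not None:
            pp4_max = max(pp4_max, conditional.pp4_max)
        return ColocResults(
            conventional=conventional, conditional=conditional, pp4_max=pp4_max
        )
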