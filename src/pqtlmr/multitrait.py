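"""Multi-trait colocalization with greedy divisive clustering.

The posterior that a set of T traits shares one causal variant is computed by
exact enumeration of the configurations in which each trait is either null or
causal at exactly one SNP.  Configuration priors extend the pairwise
colocalization constants: every causal trait contributes a factor ``p1``,
except that traits sharing a SNP with an earlier sharer contribute
``p12/p1`` instead, so T traits sharing one SNP carry prior
``p1 * (p12/p1)**(T-1)`` -- for T = 2 this reduces exactly to the pairwise
five-hypothesis model.  Because the prior couples traits that land on the
same SNP, the configuration sum is evaluated exactly by Moebius inversion
over set partitions of the causal trait set (cost ~ Bell(T) * m, exact for
the T <= 6 this module accepts).

The clustering step is inspired by HyprColoc's divisive strategy: start from
all traits, and while the shared posterior is below threshold, remove the
trait whose exclusion most improves the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .coloc import ColocPriors, _log_abf_vector, default_prior_sd
from .exceptions import EmptyOverlapError, InsufficientTraitsError, InvalidParameterError
from .summary_io import RegionStats

MAX_TRAITS = 6


@dataclass
class SharedPosterior:
    """Posterior that all supplied traits share one causal SNP."""

    posterior_share: float
    candidate_snp: str
    per_snp_share_weights: np.ndarray
    rsids: list[str]


@dataclass
class Cluster:
    trait_ids: list[str]
    posterior_share: float
    candidate_snp: str
    per_snp_share_weights: np.ndarray


@dataclass
class MultiColocResult:
    clusters: list[Cluster] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Multi-trait colocalization", "-" * 40]
        for c in self.clusters:
            lines.append(
                f"  cluster {{{', '.join(c.trait_ids)}}}: "
                f"P(shared)={c.posterior_share:.4f} at {c.candidate_snp}"
            )
        if self.unclustered:
            lines.append(f"  unclustered: {', '.join(self.unclustered)}")
        return "\n".join(lines)


def _set_partitions(items: list[int]):
    """Yield all set partitions of ``items`` as lists of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        # first in its own block
        yield [[first]] + part
        # first joined to an existing block
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]


def _align_regions(regions: Sequence[RegionStats]) -> tuple[list[RegionStats], list[str]]:
    shared = list(regions[0].rsids)
    for reg in regions[1:]:
        have = set(reg.rsids)
        shared = [s for s in shared if s in have]
    if not shared:
        raise EmptyOverlapError("no variants shared by all traits")
    return [reg.subset(shared) for reg in regions], shared


def shared_posterior(
    regions: Sequence[RegionStats],
    priors: ColocPriors | None = None,
    prior_sds: Sequence[float] | None = None,
) -> SharedPosterior:
    """Exact posterior that all T traits share one causal SNP.

    ``prior_sds`` gives the per-trait Wakefield effect-size prior scale
    (defaulted from each trait's type when omitted).
    """
    T = len(regions)
    if T < 2:
        raise InsufficientTraitsError("multi-trait colocalization needs >= 2 traits")
    if T > MAX_TRAITS:
        raise InvalidParameterError(f"at most {MAX_TRAITS} traits supported")
    priors = priors or ColocPriors()
    aligned, rsids = _align_regions(regions)
    if prior_sds is None:
        prior_sds = [default_prior_sd(reg) for reg in aligned]
    labf = np.vstack(
        [_log_abf_vector(reg, sd) for reg, sd in zip(aligned, prior_sds)]
    )  # (T, m)

    log_p1 = math.log(priors.p1)
    log_rho = math.log(priors.p12) - log_p1  # log(p12/p1)

    def log_s(traits: tuple[int, ...]) -> float:
        # log sum over SNPs of the product of the traits' Bayes factors.
        return float(logsumexp(labf[list(traits)].sum(axis=0)))

    # Accumulate the total normalizing sum over all configurations.
    term_logs: list[float] = [0.0]  # empty causal set
    term_signs: list[float] = [1.0]
    for size in range(1, T + 1):
        for C in combinations(range(T), size):
            for partition in _set_partitions(list(C)):
                b = len(partition)
                log_prior = b * log_p1 + (size - b) * log_rho
                # Injective assignment of blocks to distinct SNPs via Moebius
                # inversion over partitions of the blocks (merging = same SNP).
                for merge in _set_partitions(list(range(b))):
                    sign = 1.0
                    log_term = log_prior
                    for group in merge:
                        k = len(group)
                        sign *= (-1.0) ** (k - 1)
                        log_term += math.lgamma(k)  # (k-1)!
                        traits = tuple(
                            t for gi in group for t in partition[gi]
                        )
                        log_term += log_s(traits)
                    term_logs.append(log_term)
                    term_signs.append(sign)
    log_total, total_sign = logsumexp(term_logs, b=term_signs, return_sign=True)
    if total_sign <= 0:
        raise InvalidParameterError("degenerate configuration sum")

    share_log = labf.sum(axis=0)
    log_numer = log_p1 + (T - 1) * log_rho + float(logsumexp(share_log))
    posterior = float(math.exp(log_numer - log_total))

    weights = np.exp(share_log - logsumexp(share_log))
    best = int(np.argmax(weights))
    return SharedPosterior(
        posterior_share=min(posterior, 1.0),
        candidate_snp=rsids[best],
        per_snp_share_weights=weights,
        rsids=rsids,
    )


def brute_force_shared_posterior(
    regions: Sequence[RegionStats],
    priors: ColocPriors | None = None,
    prior_sds: Sequence[float] | None = None,
) -> float:
    """Direct ``(m+1)**T`` enumeration of the same posterior (small inputs only).

    Independent reference implementation of the configuration sum, kept for
    cross-checking the factorized computation on tiny regions.
    """
    from itertools import product

    priors = priors or ColocPriors()
    aligned, _ = _align_regions(regions)
    if prior_sds is None:
        prior_sds = [default_prior_sd(reg) for reg in aligned]
    labf = np.vstack([_log_abf_vector(reg, sd) for reg, sd in zip(aligned, prior_sds)])
    T, m = labf.shape
    if (m + 1) ** T > 2_000_000:
        raise InvalidParameterError("brute force restricted to tiny regions")
    rho = priors.p12 / priors.p1
    total = 0.0
    numer = 0.0
    for config in product(range(m + 1), repeat=T):  # 0 = null, j = causal at j-1
        weight = 1.0
        counts: dict[int, int] = {}
        for t, a in enumerate(config):
            if a == 0:
                continue
            j = a - 1
            counts[j] = counts.get(j, 0) + 1
            # First sharer at a SNP contributes p1, later sharers p12/p1.
            prior = priors.p1 if counts[j] == 1 else rho
            weight *= prior * math.exp(labf[t, j])
        total += weight
        if all(a != 0 for a in config) and len(set(config)) == 1:
            numer += weight
    return numer / total


def divisive_cluster(
    regions: Sequence[RegionStats],
    threshold: float = 0.7,
    priors: ColocPriors | None = None,
    prior_sds: Sequence[float] | None = None,
) -> MultiColocResult:
    """Greedy divisive clustering of traits by shared-causal-variant posterior.

    Starting from all traits: if the shared posterior reaches ``threshold``,
    emit the set as a cluster; otherwise drop the trait whose removal
    maximizes the remaining set's shared posterior and recurse on both the
    remainder and the removed singleton (singletons are unclustered by
    definition).
    """
    priors = priors or ColocPriors()
    result = MultiColocResult()

    def recurse(idx: list[int]) -> None:
        if len(idx) == 1:
            result.unclustered.append(regions[idx[0]].trait_id)
            return
        subset = [regions[i] for i in idx]
        sds = [prior_sds[i] for i in idx] if prior_sds is not None else None
        sp = shared_posterior(subset, priors, sds)
        if sp.posterior_share >= threshold:
            result.clusters.append(
                Cluster(
                    trait_ids=[r.trait_id for r in subset],
                    posterior_share=sp.posterior_share,
                    candidate_snp=sp.candidate_snp,
                    per_snp_share_weights=sp.per_snp_share_weights,
                )
            )
            return
        best_drop, best_post = None, -1.0
        for drop in idx:
            rest = [i for i in idx if i != drop]
            if len(rest) == 1:
                post = 0.0
            else:
                rest_regions = [regions[i] for i in rest]
                rest_sds = (
                    [prior_sds[i] for i in rest] if prior_sds is not None else None
                )
                post = shared_posterior(rest_regions, priors, rest_sds).posterior_share
            if post > best_post:
                best_post, best_drop = post, drop
        assert best_drop is not None
        recurse([best_drop])
        recurse([i for i in idx if i != best_drop])

    recurse(list(range(len(regions))))
    return result
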