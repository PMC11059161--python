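"""Binary-outcome MR power and minimum-detectable odds ratio.

Implements the non-centrality-parameter approximation for two-sample MR with
a binary outcome: with case fraction ``K = n_case/N``, instrument variance
explained ``rsq`` and true odds ratio ``OR``, the attenuated risk-difference
slope is ``b = K*(OR/(1 + K*(OR-1)) - 1)`` and the 1-df chi-square
non-centrality is ``NCP = N*rsq*b**2 / (K*(1-K) - b**2)``.  Power is the
upper-tail mass of the non-central chi-square beyond the central
``1 - alpha`` quantile.  The minimum detectable OR is found on a 0.01 grid,
matching how such thresholds are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class PowerSpec:
    """Study design for a binary-outcome MR power calculation."""

    n_case: float
    n_control: float
    rsq: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise InvalidParameterError("case and control counts must be positive")
        if not (0 < self.rsq < 1):
            raise InvalidParameterError("rsq must lie in (0,1)")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0,1)")
        if not (0 < self.target_power < 1):
            raise InvalidParameterError("target_power must lie in (0,1)")

    @property
    def n_total(self) -> float:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n_total


def mr_power_binary(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` at ``spec.alpha`` (two-sided, 1 df)."""
    if odds_ratio <= 0:
        raise InvalidParameterError("odds_ratio must be positive")
    K = spec.case_fraction
    b = K * (odds_ratio / (1.0 + K * (odds_ratio - 1.0)) - 1.0)
    denom = K * (1.0 - K) - b * b
    if denom <= 0:
        raise InvalidParameterError("K*(1-K) <= b**2: outside the approximation's domain")
    ncp = spec.n_total * spec.rsq * b * b / denom
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def detectable_or(spec: PowerSpec, grid_step: float = 0.01, or_max: float = 10.0) -> float:
    """Smallest OR above 1 on the grid reaching ``spec.target_power``.

    Returns the first grid point ``1 + k*grid_step`` whose power is at least
    the target; raises :class:`InvalidParameterError` when none up to
    ``or_max`` does.
    """
    if grid_step <= 0:
        raise InvalidParameterError("grid_step must be positive")
    k = 1
    while True:
        odds = round(1.0 + k * grid_step, 10)
        if odds > or_max:
            raise InvalidParameterError(
                f"target power not achievable for OR <= {or_max}"
            )
        if mr_power_binary(spec, odds) >= spec.target_power:
            return odds
        k += 1
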