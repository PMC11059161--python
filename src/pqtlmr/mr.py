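"""Mendelian-randomisation effect estimation.

The model object is :class:`MendelianRandomization`, built from harmonized
exposure/outcome effect estimates; :meth:`MendelianRandomization.fit` returns
an :class:`MRResults` carrying the causal-effect estimate ``theta`` (per SD of
exposure; log-odds scale for case-control outcomes), its standard error, the
odds ratio with 95% CI, the p-value and method metadata.

Estimators
----------
wald
    Single-instrument ratio ``beta_out / beta_exp`` with first-order delta
    standard error ``SE(beta_out) / |beta_exp|``.
ivw
    Fixed-effect inverse-variance-weighted mean of the per-instrument ratios.
weighted_median
    Weight-ordered 50% point of the ratio estimates (robust to up to 50%
    invalid instrument weight); SE by seeded parametric bootstrap.
egger
    Weighted least-squares regression of outcome on exposure effects with an
    intercept; a nonzero intercept indicates directional pleiotropy.

Module-level convenience functions (:func:`wald_ratio`, :func:`ivw`,
:func:`weighted_median`, :func:`egger`) wrap the model class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    EmptyInputError,
    InsufficientInstrumentsError,
)
from .summary_io import AssocRecord

#: 97.5% standard-normal quantile used for all 95% intervals.
Z_95 = 1.959964


@dataclass
class MRResults:
    """Results of one MR fit; mirrors a statsmodels results object in spirit."""

    theta: float
    se_theta: float
    pvalue: float
    method: str
    n_snp: int
    exposure_id: str = ""
    outcome_id: str = ""
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    snp_rsids: list[str] = field(default_factory=list)

    @property
    def or_value(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.theta - Z_95 * self.se_theta))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.theta + Z_95 * self.se_theta))

    def conf_int(self, scale: str = "or") -> tuple[float, float]:
        """95% interval on the ``"or"`` (default) or ``"theta"`` scale."""
        lo = self.theta - Z_95 * self.se_theta
        hi = self.theta + Z_95 * self.se_theta
        if scale == "theta":
            return (lo, hi)
        return (float(np.exp(lo)), float(np.exp(hi)))

    def summary(self) -> str:
        lines = [
            "Mendelian randomization results",
            "=" * 46,
            f"{'method':<22}{self.method}",
            f"{'exposure':<22}{self.exposure_id or '-'}",
            f"{'outcome':<22}{self.outcome_id or '-'}",
            f"{'n_snp':<22}{self.n_snp}",
            f"{'theta (per SD)':<22}{self.theta:.6g}",
            f"{'se(theta)':<22}{self.se_theta:.6g}",
            f"{'OR per SD':<22}{self.or_value:.4f}",
            f"{'95% CI (OR)':<22}({self.ci_low:.4f}, {self.ci_high:.4f})",
            f"{'p-value':<22}{self.pvalue:.3g}",
        ]
        if self.egger_intercept is not None:
            lines.append(f"{'Egger intercept':<22}{self.egger_intercept:.6g}")
            lines.append(f"{'intercept p':<22}{self.egger_intercept_p:.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "method": self.method,
            "n_snp": self.n_snp,
            "theta": self.theta,
            "se_theta": self.se_theta,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


class MendelianRandomization:
    """Two-sample MR model over harmonized per-variant effect estimates.

    Parameters
    ----------
    beta_exp, se_exp : array-like
        Variant effects on the exposure and their standard errors.
    beta_out, se_out : array-like
        Variant effects on the outcome (same effect alleles as the exposure
        estimates) and their standard errors.
    """

    def __init__(
        self,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        rsids: Sequence[str] | None = None,
        exposure_id: str = "",
        outcome_id: str = "",
    ) -> None:
        self.beta_exp = np.asarray(beta_exp, dtype=float)
        self.se_exp = np.asarray(se_exp, dtype=float)
        self.beta_out = np.asarray(beta_out, dtype=float)
        self.se_out = np.asarray(se_out, dtype=float)
        if not (
            self.beta_exp.shape
            == self.se_exp.shape
            == self.beta_out.shape
            == self.se_out.shape
        ):
            raise ValueError("effect/SE arrays must share one shape")
        if self.beta_exp.ndim != 1:
            raise ValueError("effect arrays must be one-dimensional")
        if np.any(self.se_out <= 0) or np.any(self.se_exp <= 0):
            raise ValueError("standard errors must be positive")
        self.rsids = list(rsids) if rsids is not None else [""] * len(self.beta_exp)
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[AssocRecord, AssocRecord]]
    ) -> "MendelianRandomization":
        """Build from harmonized (exposure, outcome) record pairs."""
        if len(pairs) == 0:
            raise EmptyInputError("no instrument pairs supplied")
        exp0, out0 = pairs[0]
        return cls(
            beta_exp=[e.beta for e, _ in pairs],
            se_exp=[e.se for e, _ in pairs],
            beta_out=[o.beta for _, o in pairs],
            se_out=[o.se for _, o in pairs],
            rsids=[e.variant.rsid for e, _ in pairs],
            exposure_id=exp0.trait_id,
            outcome_id=out0.trait_id,
        )

    @property
    def n_snp(self) -> int:
        return len(self.beta_exp)

    # -- per-instrument ratios ---------------------------------------------

    def _ratios(self) -> tuple[np.ndarray, np.ndarray]:
        if np.any(self.beta_exp == 0):
            raise DegenerateInstrumentError("exposure beta of zero instrument")
        theta = self.beta_out / self.beta_exp
        sigma = self.se_out / np.abs(self.beta_exp)
        return theta, sigma

    # -- estimators --------------------------------------------------------

    def fit(self, method: str = "ivw", n_boot: int = 2000, seed: int = 0) -> MRResults:
        if method == "wald":
            return self._fit_wald()
        if method == "ivw":
            return self._fit_ivw()
        if method == "weighted_median":
            return self._fit_weighted_median(n_boot=n_boot, seed=seed)
        if method == "egger":
            return self._fit_egger()
        raise ValueError(f"unknown MR method {method!r}")

    def _result(self, theta: float, se: float, pvalue: float, method: str, **kw):
        return MRResults(
            theta=float(theta),
            se_theta=float(se),
            pvalue=float(pvalue),
            method=method,
            n_snp=self.n_snp,
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            snp_rsids=list(self.rsids),
            **kw,
        )

    @staticmethod
    def _norm_p(z: float) -> float:
        # Two-sided normal p, clipped into (0, 1].
        return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1))))

    def _fit_wald(self) -> MRResults:
        if self.n_snp != 1:
            raise InsufficientInstrumentsError(
                "the Wald ratio is a single-instrument estimator"
            )
        theta, sigma = self._ratios()
        theta, sigma = float(theta[0]), float(sigma[0])
        p = 1.0 if theta == 0 else self._norm_p(theta / sigma)
        return self._result(theta, sigma, p, "wald")

    def _fit_ivw(self) -> MRResults:
        theta_j, sigma_j = self._ratios()
        w = 1.0 / sigma_j**2
        theta = float(np.sum(w * theta_j) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        p = 1.0 if theta == 0 else self._norm_p(theta / se)
        return self._result(theta, se, p, "ivw")

    @staticmethod
    def _weighted_median(theta_j: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(theta_j)
        th = theta_j[order]
        w = weights[order] / np.sum(weights)
        # Cumulative midpoint position of each ordered ratio.
        pos = np.cumsum(w) - w / 2.0
        return float(np.interp(0.5, pos, th))

    def _fit_weighted_median(self, n_boot: int, seed: int) -> MRResults:
        if self.n_snp < 3:
            raise InsufficientInstrumentsError(
                "the weighted median requires at least 3 instruments"
            )
        theta_j, sigma_j = self._ratios()
        w = 1.0 / sigma_j**2
        theta = self._weighted_median(theta_j, w)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            draw = rng.normal(theta_j, sigma_j)
            boots[b] = self._weighted_median(draw, w)
        se = float(np.std(boots, ddof=1))
        if se == 0:
            p = 1.0 if theta == 0 else np.nextafter(0, 1)
        else:
            p = self._norm_p(theta / se)
        return self._result(theta, se, p, "weighted_median")

    def _fit_egger(self) -> MRResults:
        if self.n_snp < 2:
            raise InsufficientInstrumentsError("MR-Egger requires at least 2 instruments")
        # Orient so every exposure effect is positive (flip both betas).
        sign = np.where(self.beta_exp < 0, -1.0, 1.0)
        bx = self.beta_exp * sign
        by = self.beta_out * sign
        w = 1.0 / self.se_out**2
        design = sm.add_constant(bx, has_constant="add")
        fit = sm.WLS(by, design, weights=w).fit()
        intercept, slope = fit.params
        if self.n_snp == 2:
            # Exact fit: no residual df, no inference.
            se_slope = se_int = np.nan
            p_slope = p_int = np.nan
        else:
            se_int, se_slope = fit.bse
            df = self.n_snp - 2
            p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df))
            p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
        return self._result(
            slope,
            se_slope,
            p_slope,
            "egger",
            egger_intercept=float(intercept),
            egger_intercept_se=float(se_int),
            egger_intercept_p=p_int,
        )


# ---------------------------------------------------------------------------
# Functional wrappers over the model class
# ---------------------------------------------------------------------------


def wald_ratio(exposure: AssocRecord, outcome: AssocRecord) -> MRResults:
    """Single-instrument Wald ratio from one harmonized record pair."""
    if exposure.beta == 0:
        raise DegenerateInstrumentError(
            f"{exposure.variant.rsid}: exposure beta is zero"
        )
    return MendelianRandomization.from_pairs([(exposure, outcome)]).fit("wald")


def ivw(pairs: Sequence[tuple[AssocRecord, AssocRecord]]) -> MRResults:
    """Fixed-effect inverse-variance-weighted estimate over harmonized pairs."""
    return MendelianRandomization.from_pairs(pairs).fit("ivw")


def weighted_median(
    pairs: Sequence[tuple[AssocRecord, AssocRecord]],
    n_boot: int = 2000,
    seed: int = 0,
) -> MRResults:
    """Weighted-median estimate with seeded parametric-bootstrap SE."""
    return MendelianRandomization.from_pairs(pairs).fit(
        "weighted_median", n_boot=n_boot, seed=seed
    )


def egger(pairs: Sequence[tuple[AssocRecord, AssocRecord]]) -> MRResults:
    """MR-Egger weighted regression (slope = effect, intercept = pleiotropy)."""
    return MendelianRandomization.from_pairs(pairs).fit("egger")
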