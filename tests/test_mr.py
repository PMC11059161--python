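"""MR estimators: Wald ratio, IVW, weighted median, Egger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqtlmr.exceptions import (
    DegenerateInstrumentError,
    EmptyInputError,
    InsufficientInstrumentsError,
)
from pqtlmr.mr import (
    MendelianRandomization,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)

from conftest import make_record


def _pair(beta_exp, se_exp, beta_out, se_out, rsid="rs1", pos=100):
    exp = make_record(rsid=rsid, pos=pos, beta=beta_exp, se=se_exp)
    out = make_record(
        rsid=rsid, pos=pos, beta=beta_out, se=se_out, trait_id="cancer",
        trait_type="case_control", n=20_000, n_case=10_000, n_control=10_000,
    )
    return exp, out


class TestWaldRatio:
    def test_worked_example(self):
        res = wald_ratio(*_pair(0.5, 0.02, 0.41, 0.05))
        assert res.theta == pytest.approx(0.82)
        assert res.se_theta == pytest.approx(0.10)
        assert res.or_value == pytest.approx(2.2705, abs=1e-4)
        assert res.conf_int() == (
            pytest.approx(1.8664, abs=1e-4),
            pytest.approx(2.7621, abs=1e-4),
        )
        assert res.method == "wald" and res.n_snp == 1

    def test_null_outcome(self):
        res = wald_ratio(*_pair(0.5, 0.02, 0.0, 0.05))
        assert res.theta == 0.0
        assert res.or_value == 1.0
        assert res.pvalue == 1.0

    def test_allele_flip_invariance(self):
        exp, out = _pair(0.5, 0.02, 0.41, 0.05)
        base = wald_ratio(exp, out)
        from dataclasses import replace

        flipped_exp = replace(
            exp,
            beta=-exp.beta,
            eaf=1 - exp.eaf,
            variant=replace(exp.variant, effect_allele="G", other_allele="A"),
        )
        flipped_out = replace(
            out,
            beta=-out.beta,
            eaf=1 - out.eaf,
            variant=replace(out.variant, effect_allele="G", other_allele="A"),
        )
        other = wald_ratio(flipped_exp, flipped_out)
        assert other.theta == pytest.approx(base.theta)
        assert other.se_theta == pytest.approx(base.se_theta)
        assert other.pvalue == pytest.approx(base.pvalue)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(*_pair(0.0, 0.02, 0.41, 0.05))


class TestIvw:
    def test_single_pair_reduces_to_wald(self):
        pair = _pair(0.5, 0.02, 0.41, 0.05)
        w = wald_ratio(*pair)
        i = ivw([pair])
        assert i.theta == pytest.approx(w.theta)
        assert i.se_theta == pytest.approx(w.se_theta)
        assert i.pvalue == pytest.approx(w.pvalue)

    def test_equal_weights_average(self):
        pairs = [
            _pair(0.5, 0.02, 0.05, 0.05, rsid="rs1"),
            _pair(0.5, 0.02, 0.15, 0.05, rsid="rs2", pos=101),
        ]
        # ratios 0.1 and 0.3 with equal sigma -> mean 0.2
        assert ivw(pairs).theta == pytest.approx(0.2)

    def test_heterogeneous_weighted_mean(self):
        beta_exp = [0.5, 0.4, 0.25]
        beta_out = [0.05, 0.08, 0.02]
        se_out = [0.05, 0.03, 0.02]
        pairs = [
            _pair(bx, 0.02, by, so, rsid=f"rs{i}", pos=100 + i)
            for i, (bx, by, so) in enumerate(zip(beta_exp, beta_out, se_out))
        ]
        theta_j = np.array(beta_out) / np.array(beta_exp)
        sigma_j = np.array(se_out) / np.abs(beta_exp)
        w = 1 / sigma_j**2
        expected = np.sum(w * theta_j) / np.sum(w)
        res = ivw(pairs)
        assert res.theta == pytest.approx(expected)
        assert res.se_theta == pytest.approx(np.sum(w) ** -0.5)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            ivw([])


class TestWeightedMedian:
    def test_equal_weight_median(self):
        pairs = [
            _pair(0.5, 0.02, 0.05, 0.05, rsid="rs1"),
            _pair(0.5, 0.02, 0.10, 0.05, rsid="rs2", pos=101),
            _pair(0.5, 0.02, 0.15, 0.05, rsid="rs3", pos=102),
        ]
        res = weighted_median(pairs, n_boot=200, seed=1)
        assert res.theta == pytest.approx(0.2)

    def test_identical_ratios_zero_spread(self):
        pairs = [
            _pair(0.5, 0.02, 0.1, 0.001, rsid=f"rs{i}", pos=100 + i) for i in range(3)
        ]
        res = weighted_median(pairs, n_boot=500, seed=1)
        assert res.theta == pytest.approx(0.2)
        assert res.se_theta < 0.01

    def test_dominant_weight_pins_the_estimate(self):
        # One ratio carries ~98% of the weight; the median must equal it.
        pairs = [
            _pair(0.5, 0.02, 0.25, 0.005, rsid="rs1"),          # ratio 0.5, tiny sigma
            _pair(0.5, 0.02, 0.05, 0.07, rsid="rs2", pos=101),  # ratio 0.1
            _pair(0.5, 0.02, 0.45, 0.07, rsid="rs3", pos=102),  # ratio 0.9
        ]
        sigma = np.array([0.005, 0.07, 0.07]) / 0.5
        w = (1 / sigma**2) / np.sum(1 / sigma**2)
        assert w[0] > 0.97
        res = weighted_median(pairs, n_boot=200, seed=1)
        assert res.theta == pytest.approx(0.5, abs=0.02)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([_pair(0.5, 0.02, 0.1, 0.05)] * 2)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 0.5)), min_size=3, max_size=8))
    def test_estimate_within_ratio_range(self, ratios_sigmas):
        model = MendelianRandomization(
            beta_exp=np.ones(len(ratios_sigmas)),
            se_exp=np.full(len(ratios_sigmas), 0.02),
            beta_out=[r for r, _ in ratios_sigmas],
            se_out=[s for _, s in ratios_sigmas],
        )
        res = model.fit("weighted_median", n_boot=10, seed=0)
        ratios = [r for r, _ in ratios_sigmas]
        assert min(ratios) - 1e-12 <= res.theta <= max(ratios) + 1e-12


class TestEgger:
    def test_two_point_exact_line(self):
        pairs = [
            _pair(0.2, 0.02, 0.1, 0.05, rsid="rs1"),
            _pair(0.4, 0.02, 0.3, 0.05, rsid="rs2", pos=101),
        ]
        res = egger(pairs)
        assert res.theta == pytest.approx(1.0)
        assert res.egger_intercept == pytest.approx(-0.1)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.5, 10)
        by = 0.5 * bx  # zero pleiotropy, slope 0.5
        model = MendelianRandomization(bx, np.full(10, 0.02), by, np.full(10, 0.03))
        res = model.fit("egger")
        assert res.theta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.5, 8)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 8)
        base = MendelianRandomization(bx, np.full(8, 0.02), by, np.full(8, 0.03)).fit("egger")
        flip = np.array([1, -1] * 4, dtype=float)
        other = MendelianRandomization(
            bx * flip, np.full(8, 0.02), by * flip, np.full(8, 0.03)
        ).fit("egger")
        assert other.theta == pytest.approx(base.theta)
        assert other.egger_intercept == pytest.approx(base.egger_intercept)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([_pair(0.5, 0.02, 0.1, 0.05)])


def test_summary_renders(capsys):
    res = wald_ratio(*_pair(0.5, 0.02, 0.41, 0.05))
    text = res.summary()
    assert "OR per SD" in text and "2.27" in text
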