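"""Colocalization: Wakefield ABFs, posteriors, conditional signals."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqtlmr.coloc import (
    Colocalization,
    ColocPriors,
    _posteriors_from_labf,
    coloc_posteriors,
    conditional_signals,
    iterative_coloc,
    log_abf,
)
from pqtlmr.exceptions import EmptyOverlapError, InvalidParameterError
from pqtlmr.simulate import SimScenario, make_ld, simulate_pair
from pqtlmr.summary_io import LdMatrix, RegionStats

from conftest import make_record, region_from_z


def brute_force_posteriors(l1, l2, priors):
    """Enumeration over all two-trait causal configurations (oracle)."""
    m = len(l1)
    h = np.zeros(5)
    for a in range(m + 1):  # 0 = null, j = causal at j-1
        for b in range(m + 1):
            w = 1.0
            if a > 0:
                w *= priors.p1 * math.exp(l1[a - 1])
            if b > 0:
                shared = a == b and a > 0
                w *= (priors.p12 / priors.p1 if shared else priors.p2) * math.exp(
                    l2[b - 1]
                )
            if a == 0 and b == 0:
                h[0] += w
            elif b == 0:
                h[1] += w
            elif a == 0:
                h[2] += w
            elif a != b:
                h[3] += w
            else:
                h[4] += w
    return h / h.sum()


class TestLogAbf:
    def test_worked_example(self):
        rec = make_record(beta=0.5, se=0.1)
        assert log_abf(rec, prior_sd=0.15) == pytest.approx(8.064519, abs=1e-6)

    def test_null_z_gives_negative_evidence(self):
        rec = make_record(beta=0.0, se=0.1)
        value = log_abf(rec, prior_sd=0.15)
        r = 0.15**2 / (0.1**2 + 0.15**2)
        assert value == pytest.approx(0.5 * math.log(1 - r))
        assert value < 0

    def test_no_information_limit(self):
        rec = make_record(beta=0.5, se=1e6)
        assert log_abf(rec, prior_sd=0.15) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_prior_sd(self):
        with pytest.raises(InvalidParameterError):
            log_abf(make_record(), prior_sd=0.0)


class TestColocPosteriors:
    def test_single_snp_pp3_is_zero(self):
        r1 = region_from_z([5.0], trait_id="prot")
        r2 = region_from_z([4.0], trait_id="cancer")
        res = coloc_posteriors(r1, r2)
        assert res.pp3 == 0.0
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_matches_enumeration_oracle(self, m, rng):
        priors = ColocPriors()
        for _ in range(5):
            z1 = rng.normal(0, 4, m)
            z2 = rng.normal(0, 4, m)
            r1 = region_from_z(z1, trait_id="prot")
            r2 = region_from_z(z2, trait_id="cancer")
            res = coloc_posteriors(r1, r2, priors, prior_sd_1=0.15, prior_sd_2=0.15)
            l1 = np.array([log_abf(r, 0.15) for r in r1.records])
            l2 = np.array([log_abf(r, 0.15) for r in r2.records])
            expected = brute_force_posteriors(l1, l2, priors)
            assert np.abs(res.posteriors - expected).max() < 1e-10

    def test_permutation_invariance(self, rng):
        z1, z2 = rng.normal(0, 3, 6), rng.normal(0, 3, 6)
        base = coloc_posteriors(region_from_z(z1, "a"), region_from_z(z2, "b"))
        perm = rng.permutation(6)
        shuffled = coloc_posteriors(
            region_from_z(z1, "a").subset([f"rs{i}" for i in perm]),
            region_from_z(z2, "b").subset([f"rs{i}" for i in perm]),
        )
        assert np.allclose(base.posteriors, shuffled.posteriors, atol=1e-12)

    def test_empty_overlap_raises(self):
        r1 = region_from_z([3.0], trait_id="a")
        r2 = region_from_z([3.0], trait_id="b", prefix="xx")
        with pytest.raises(EmptyOverlapError):
            coloc_posteriors(r1, r2)

    def test_boosting_shared_snp_cannot_decrease_pp4(self, rng):
        l1 = rng.normal(0, 2, 8)
        l2 = rng.normal(0, 2, 8)
        priors = ColocPriors()
        base = _posteriors_from_labf(l1, l2, priors)[4]
        for c in (0.5, 1.0, 3.0):
            b1, b2 = l1.copy(), l2.copy()
            b1[3] += c
            b2[3] += c
            boosted = _posteriors_from_labf(b1, b2, priors)[4]
            assert boosted >= base - 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_posteriors_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        l1 = rng.normal(0, 5, 12)
        l2 = rng.normal(0, 5, 12)
        pp = _posteriors_from_labf(l1, l2, ColocPriors())
        assert pp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((pp >= 0) & (pp <= 1))


class TestConditionalSignals:
    def test_single_clear_signal_returns_originals(self):
        sc = SimScenario(m=50, causal_config=[[(25, 0.3)], []], seed=5)
        r1, _, ld = simulate_pair(sc)
        signals = conditional_signals(r1, ld)
        assert len(signals) == 1
        assert signals[0].records == r1.records

    def test_pure_ld_shadow_conditions_to_zero(self):
        # z_j = r_js * z_s exactly: conditioning on s must annihilate all z.
        sc = SimScenario(m=20, seed=0)
        ld = make_ld(sc)
        z_s = 10.0
        z = ld.r[:, 10] * z_s
        from dataclasses import replace

        region = region_from_z(z, trait_id="prot")
        # align rsids with the LD panel's variant names
        region = RegionStats(
            records=[
                replace(r, variant=ld.variants[i])
                for i, r in enumerate(region.records)
            ]
        )
        signals = conditional_signals(region, ld, p_stop=1e-6)
        assert len(signals) == 1  # the shadow is fully explained by one signal

    def test_two_independent_causals_recovered(self):
        hits = 0
        for seed in range(20):
            sc = SimScenario(m=200, causal_config=[[(50, 0.25), (150, 0.25)], []], seed=seed)
            r1, _, ld = simulate_pair(sc)
            hits += len(conditional_signals(r1, ld)) == 2
        assert hits >= 19

    def test_no_signal_below_stop_returns_empty(self):
        sc = SimScenario(m=30, causal_config=[[], []], seed=1)
        r1, _, ld = simulate_pair(sc)
        assert conditional_signals(r1, ld, p_stop=1e-10) == []


class TestIterativeColoc:
    def test_single_signals_reduce_to_conventional(self):
        sc = SimScenario(m=100, causal_config=[[(50, 0.3)], [(50, 0.25)]], seed=7)
        r1, r2, ld = simulate_pair(sc)
        conv = coloc_posteriors(r1, r2)
        it = iterative_coloc(r1, r2, ld)
        assert it.pp4 == pytest.approx(conv.pp4, abs=1e-9)
        assert it.pp4_max >= conv.pp4

    def test_pp4_max_dominates_conventional(self):
        for seed in range(5):
            sc = SimScenario(
                m=150, causal_config=[[(40, 0.4), (110, 0.2)], [(110, 0.2)]], seed=seed
            )
            r1, r2, ld = simulate_pair(sc)
            conv = coloc_posteriors(r1, r2)
            it = iterative_coloc(r1, r2, ld)
            assert it.pp4_max >= conv.pp4 - 1e-12

    def test_model_class_fit_both(self):
        sc = SimScenario(m=80, causal_config=[[(40, 0.3)], [(40, 0.25)]], seed=11)
        r1, r2, ld = simulate_pair(sc)
        res = Colocalization(r1, r2, ld=ld).fit("both")
        assert res.pp4_max >= res.conventional.pp4
        assert "PP4_max" in res.summary()


def test_priors_validated():
    with pytest.raises(InvalidParameterError):
        ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)
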