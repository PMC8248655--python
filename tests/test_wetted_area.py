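"""Wetted surface area: power-law estimates, direct hull formula, TWSA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselppp import (
    DomainError,
    HullParams,
    UnsupportedRouteError,
    ValidationError,
    VesselType,
    VesselTypeParams,
    compute_direct_wsa,
    compute_twsa,
    compute_twsa_composite,
    default_params,
    estimate_wsa_from_gt,
    refit_regression,
)
from vesselppp.params import REGRESSION_TYPES

REGRESSION_CODES = sorted(t.value for t in REGRESSION_TYPES)


class TestPowerLawEstimate:
    def test_gt_one_returns_slope_for_every_type(self, params_table):
        # WSA = m * 1**b == m, exactly
        for code in REGRESSION_TYPES:
            p = params_table[code]
            assert estimate_wsa_from_gt(1.0, p) == p.m

    @pytest.mark.parametrize(
        "vtype, gt, expected",
        [
            ("container", 50_000, 12093.655816909999),  # calculator oracle
            ("passenger", 50_000, 10079.678792058321),  # calculator oracle
        ],
    )
    def test_matches_hand_calculator_oracle(self, params_table, vtype, gt, expected):
        got = estimate_wsa_from_gt(gt, params_table[VesselType(vtype)])
        assert got == pytest.approx(expected, rel=1e-12)

    @given(
        gt1=st.floats(1.0, 3e5),
        gt2=st.floats(1.0, 3e5),
        code=st.sampled_from(REGRESSION_CODES),
    )
    @settings(deadline=None, max_examples=200)
    def test_strictly_monotone_in_gt(self, gt1, gt2, code):
        p = default_params()[VesselType(code)]
        w1, w2 = estimate_wsa_from_gt(gt1, p), estimate_wsa_from_gt(gt2, p)
        if gt1 < gt2:
            assert w1 < w2
        elif gt1 > gt2:
            assert w1 > w2
        else:
            assert w1 == w2

    def test_nonpositive_tonnage_rejected(self, params_table):
        p = params_table[VesselType.CONTAINER]
        with pytest.raises(DomainError):
            estimate_wsa_from_gt(0.0, p)
        with pytest.raises(DomainError):
            estimate_wsa_from_gt(-10.0, p)

    def test_composite_types_routed_to_direct_formula(self, params_table):
        with pytest.raises(UnsupportedRouteError, match="directly"):
            estimate_wsa_from_gt(5_000, params_table[VesselType.ATB])


class TestDirectWsa:
    HULL = dict(length_waterline=100, beam=30, draft=5, midship_coeff=0.99,
                block_coeff=0.90, waterplane_coeff=0.92)

    def test_matches_spreadsheet_oracle(self):
        got = compute_direct_wsa(HullParams(**self.HULL, bulb_transverse_area=0))
        assert got == pytest.approx(3530.7805797185642, rel=1e-12)

    def test_zero_bulb_area_leaves_first_term_only(self):
        base = compute_direct_wsa(HullParams(**self.HULL))
        with_bulb = compute_direct_wsa(
            HullParams(**self.HULL, bulb_transverse_area=20)
        )
        assert with_bulb == pytest.approx(base + 2.38 * 20 / 0.90, rel=1e-12)

    def test_linear_in_length(self):
        base = compute_direct_wsa(HullParams(**self.HULL))
        doubled = compute_direct_wsa(
            HullParams(**{**self.HULL, "length_waterline": 200})
        )
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_missing_fields_listed(self):
        with pytest.raises(Exception, match="beam"):
            HullParams(length_waterline=100, draft=5, midship_coeff=0.99,
                       block_coeff=0.9, waterplane_coeff=0.92)

    def test_agrees_with_independent_one_liner_on_random_hulls(self):
        rng = np.random.default_rng(20240612)
        for _ in range(100):
            L = rng.uniform(20, 400)
            B = rng.uniform(5, 60)
            T = rng.uniform(2, 20)
            cm = rng.uniform(0.5, 1.0)
            cb = rng.uniform(0.4, 1.0)
            cwp = rng.uniform(0.5, 1.0)
            abt = rng.uniform(0, 30)
            expected = L * (2 * T + B) * math.sqrt(cm) * (
                0.453 + 0.4425 * cb - 0.2862 * cm - 0.003467 * B / T
                + 0.3696 * cwp
            ) + 2.38 * abt / cb
            got = compute_direct_wsa(
                HullParams(length_waterline=L, beam=B, draft=T,
                           midship_coeff=cm, block_coeff=cb,
                           waterplane_coeff=cwp, bulb_transverse_area=abt)
            )
            assert got == pytest.approx(expected, rel=1e-14)


class TestTwsa:
    @pytest.mark.parametrize(
        "wsa, niche, expected",
        [(1000, 0.0, 1000), (1000, 0.09, 1090), (10_000, 0.27, 12_700)],
    )
    def test_direct_arithmetic(self, wsa, niche, expected):
        assert compute_twsa(wsa, niche) == pytest.approx(expected, rel=1e-12)

    @given(wsa=st.floats(1e-3, 1e6), niche=st.floats(0, 0.999))
    @settings(deadline=None)
    def test_never_below_wsa(self, wsa, niche):
        t = compute_twsa(wsa, niche)
        assert t >= wsa
        if niche == 0:
            assert t == wsa
        elif niche > 1e-9:  # below that, 1 + niche rounds to 1 in floats
            assert t > wsa

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            compute_twsa(-1.0, 0.1)
        with pytest.raises(DomainError):
            compute_twsa(100.0, -0.1)
        with pytest.raises(DomainError):
            compute_twsa(100.0, 1.0)


class TestCompositeTwsa:
    def test_per_component_arithmetic(self):
        assert compute_twsa_composite(1000, 100) == pytest.approx(1158, rel=1e-12)

    def test_linearity(self):
        assert compute_twsa_composite(2000, 200) == pytest.approx(
            2 * compute_twsa_composite(1000, 100), rel=1e-12
        )

    def test_summed_mode(self):
        assert compute_twsa_composite(1000, 100, mode="summed") == pytest.approx(
            1100 * 1.283, rel=1e-12
        )

    def test_both_components_required(self):
        with pytest.raises(DomainError):
            compute_twsa_composite(1000, 0)
        with pytest.raises(DomainError):
            compute_twsa_composite(0, 100)


class TestRefitRegression:
    def test_noiseless_recovery_of_each_packaged_type(self, params_table):
        gts = np.array([1e3, 1e4, 1e5])
        for code in REGRESSION_TYPES:
            p = params_table[code]
            pairs = [(g, p.m * g**p.b) for g in gts]
            fit = refit_regression(pairs, code)
            assert fit.m == pytest.approx(p.m, rel=1e-6)
            assert fit.b == pytest.approx(p.b, rel=1e-6)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(3)
        m_true, b_true = 15.0, 0.6294
        gt = rng.uniform(1e3, 2e5, size=500)
        wsa = m_true * gt**b_true * np.exp(rng.normal(0, 0.1, size=500))
        fit = refit_regression(list(zip(gt, wsa)), VesselType.BULKER)
        assert fit.b == pytest.approx(b_true, abs=0.02)

    def test_too_few_or_invalid_pairs(self):
        with pytest.raises(ValidationError):
            refit_regression([(1e3, 5e3), (1e4, 2e4)])
        with pytest.raises(ValidationError):
            refit_regression([(1e3, 5e3), (-1e4, 2e4), (1e5, 9e4)])


class TestParamsValidation:
    def test_packaged_defaults_match_printed_table(self, params_table):
        p = params_table[VesselType.CONTAINER]
        assert (p.m, p.b, p.niche_proportion) == (10.66, 0.6501, 0.09)
        assert params_table[VesselType.ATB].component_niches == (0.033, 0.25)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            VesselTypeParams(VesselType.TANKER, m=-1, b=0.5, niche_proportion=0.1)
        with pytest.raises(DomainError):
            VesselTypeParams(VesselType.TANKER, m=10, b=1.2, niche_proportion=0.1)
        with pytest.raises(ValidationError):
            VesselTypeParams(VesselType.ATB)
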