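import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdiffuse import (
    BiochemParams,
    CurveSet,
    GasExchangeRecord,
    InsufficientDataError,
    KineticConstants,
    dA_dCc,
    fit_aci_ethier,
    fit_aci_standard,
    fvcb_forward,
    limitation_state,
)
from leafdiffuse.fvcb import GM_IDENTIFIABLE_MAX, ethier_forward
from leafdiffuse.synthetic_data import simulate_aci


def _k(gamma_star=40.0, km=710.0):
    # choose kc so that kc*(1+o/ko) == km with the default o/ko ratio
    ratio = 1.0 + 210.0 / 278.4
    return KineticConstants(kc=km / ratio, gamma_star=gamma_star)


def test_forward_at_compensation_point_is_minus_rd():
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=60.0, rd=1.5)
    assert fvcb_forward(k.gamma_star, p, k) == pytest.approx(-1.5, abs=1e-12)


def test_forward_rubisco_asymptote():
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=1e6, rd=1.5)
    assert fvcb_forward(1e9, p, k) == pytest.approx(30.0 - 1.5, rel=1e-6)


def test_forward_hand_value_rubisco_limited():
    # Vcmax=30, GammaStar=40, Km=710, Rd=1.5 at Cc=239 in the Rubisco regime
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=1e5, rd=1.5)
    expected = 30.0 * (239.0 - 40.0) / (239.0 + 710.0) - 1.5
    assert expected == pytest.approx(4.7908, abs=5e-4)
    assert fvcb_forward(239.0, p, k) == pytest.approx(expected, rel=1e-12)


def test_derivative_hand_value():
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=1e5, rd=1.5)
    assert dA_dCc(p, k, 239.0) == pytest.approx(30.0 * 750.0 / 949.0**2, rel=1e-12)
    assert dA_dCc(p, k, 239.0) == pytest.approx(0.02498, abs=1e-5)


def test_derivative_vanishes_at_saturation():
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=60.0, rd=1.5)
    assert dA_dCc(p, k, 1e8) < 1e-12


@settings(max_examples=40, deadline=None)
@given(cc=st.floats(5.0, 1500.0), vcmax=st.floats(10.0, 120.0), jcmax=st.floats(20.0, 250.0))
def test_derivative_matches_finite_differences(cc, vcmax, jcmax):
    k = _k()
    p = BiochemParams(vcmax=vcmax, jcmax=jcmax, rd=1.5)
    h = 1e-3 * max(cc, 1.0)
    # skip points straddling the Rubisco/RuBP crossover, where A is not smooth
    if limitation_state(cc - h, p, k) != limitation_state(cc + h, p, k):
        return
    fd = (fvcb_forward(cc + h, p, k) - fvcb_forward(cc - h, p, k)) / (2 * h)
    assert dA_dCc(p, k, cc) == pytest.approx(fd, rel=1e-5)


@settings(max_examples=30, deadline=None)
@given(lo=st.floats(45.0, 400.0), hi=st.floats(401.0, 1500.0))
def test_forward_nondecreasing_above_compensation(lo, hi):
    k = _k()
    p = BiochemParams(vcmax=30.0, jcmax=60.0, rd=1.5)
    assert fvcb_forward(hi, p, k) >= fvcb_forward(lo, p, k) - 1e-12


def _curve_from(cc, a, gs=0.1):
    records = [
        GasExchangeRecord(a=float(ai), ci=float(ci), ca=float(ci) + float(ai) / gs, gs=gs,
                          e=1.0, ppfd=300.0, tleaf=25.0)
        for ci, ai in zip(cc, a)
    ]
    return CurveSet(kind="aci", genotype="x", replicate="r1", records=records)


def test_standard_fit_recovers_generating_parameters(kin):
    k = kin.with_gamma_star(41.3)
    truth = BiochemParams(vcmax=30.5, jcmax=57.8, rd=1.61)
    cc = np.array([50.0, 100.0, 150.0, 220.0, 300.0, 420.0, 600.0, 800.0])
    a = fvcb_forward(cc, truth, k)
    fit = fit_aci_standard(_curve_from(cc, a), k, rd=1.61, cc=cc)
    assert fit.params.vcmax == pytest.approx(30.5, rel=1e-3)
    assert fit.params.jcmax == pytest.approx(57.8, rel=1e-3)
    assert set(fit.states) == {"rubisco", "rubp"}


def test_standard_fit_flags_single_regime(kin):
    k = kin.with_gamma_star(41.3)
    truth = BiochemParams(vcmax=30.5, jcmax=300.0, rd=1.61)
    cc = np.array([50.0, 80.0, 110.0, 140.0, 170.0, 195.0])
    a = fvcb_forward(cc, truth, k)
    fit = fit_aci_standard(_curve_from(cc, a), k, rd=1.61, cc=cc)
    assert "jcmax" in fit.unidentifiable


def test_standard_fit_needs_five_points(kin):
    cc = np.array([100.0, 200.0, 300.0])
    with pytest.raises(InsufficientDataError):
        fit_aci_standard(_curve_from(cc, cc * 0.01), kin, rd=1.0, cc=cc)


def test_standard_fit_noisy_median_bias_small(kin):
    k = kin.with_gamma_star(41.3)
    truth = BiochemParams(vcmax=30.5, jcmax=57.8, rd=1.61)
    cc = np.array([50.0, 100.0, 150.0, 220.0, 300.0, 420.0, 600.0, 800.0])
    a0 = fvcb_forward(cc, truth, k)
    rng = np.random.default_rng(42)
    vs = []
    for _ in range(200):
        a = a0 * (1 + 0.02 * rng.standard_normal(a0.size))
        vs.append(fit_aci_standard(_curve_from(cc, a), k, rd=1.61, cc=cc).params.vcmax)
    assert abs(np.median(vs) / 30.5 - 1) < 0.02


def test_ethier_forward_matches_self_consistent_solution(kin):
    # the quadratic root must satisfy A = FvCB(Ci - A/gm) exactly
    k = kin.with_gamma_star(40.0)
    p = BiochemParams(vcmax=30.0, jcmax=60.0, rd=1.5, gm=0.15)
    for ci in (100.0, 300.0, 700.0, 1200.0):
        a = ethier_forward(ci, 30.0, 60.0, 0.15, 1.5, k)
        assert fvcb_forward(max(ci - a / 0.15, 0.0), p, k) == pytest.approx(a, rel=1e-10)


def test_ethier_fit_recovers_finite_gm(colwt_leaf, kin):
    curve = simulate_aci(colwt_leaf)
    fit = fit_aci_ethier(curve, kin.with_gamma_star(colwt_leaf.gamma_star), colwt_leaf.rd)
    assert fit.params.gm == pytest.approx(colwt_leaf.gm, rel=0.01)
    assert fit.params.vcmax == pytest.approx(colwt_leaf.vcmax, rel=0.01)


def test_ethier_fit_flags_effectively_infinite_gm(kin):
    # data generated on a Ci basis with no mesophyll drawdown at all
    k = kin.with_gamma_star(41.3)
    truth = BiochemParams(vcmax=30.5, jcmax=57.8, rd=1.61)
    ci = np.array([60.0, 120.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1000.0])
    a = fvcb_forward(ci, truth, k)
    fit = fit_aci_ethier(_curve_from(ci, a), k, rd=1.61)
    assert "gm" in fit.unidentifiable or fit.params.gm > GM_IDENTIFIABLE_MAX


def test_ethier_fit_requires_ci_span(kin):
    ci = np.array([100.0, 120.0, 140.0, 160.0, 180.0, 200.0])
    with pytest.raises(InsufficientDataError):
        fit_aci_ethier(_curve_from(ci, ci * 0.01), kin, rd=1.0)
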