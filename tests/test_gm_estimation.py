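import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdiffuse import (
    CurveSet,
    DegeneracyError,
    DomainError,
    GasExchangeRecord,
    InsufficientDataError,
    NoIntersectionError,
    cc_variable_j,
    fit_laisk,
    gm_variable_j,
    total_conductance,
    variable_j_curve,
)
from leafdiffuse.synthetic_data import simulate_aci, simulate_laisk_set


def test_cc_hand_value():
    assert cc_variable_j(10.0, 1.0, 40.0, 100.0) == pytest.approx(40.0 * 188.0 / 56.0, rel=1e-12)


def test_cc_collapses_to_gamma_star_at_zero_gross_uptake():
    for j in (5.0, 50.0, 500.0):
        assert cc_variable_j(-1.0, 1.0, 40.0, j) == pytest.approx(40.0, rel=1e-12)


def test_cc_degeneracy_error():
    with pytest.raises(DegeneracyError):
        cc_variable_j(10.0, 1.0, 40.0, 44.0)


@settings(max_examples=100, deadline=None)
@given(
    a=st.floats(0.5, 30.0),
    rd=st.floats(0.0, 3.0),
    gamma_star=st.floats(20.0, 60.0),
    margin=st.floats(1.05, 4.0),
)
def test_cc_is_exact_inverse_of_rubp_limited_fvcb(a, rd, gamma_star, margin):
    """Substituting Cc back into Aj = J(Cc - G*)/(4Cc + 8G*) returns A + Rd."""
    j = 4.0 * (a + rd) * margin
    cc = cc_variable_j(a, rd, gamma_star, j)
    aj = j * (cc - gamma_star) / (4.0 * cc + 8.0 * gamma_star)
    assert aj == pytest.approx(a + rd, rel=1e-10)


@pytest.mark.parametrize(
    "a,ci,cc,printed",
    [(3.86, 309.0, 132.0, 0.022), (4.72, 341.0, 293.0, 0.098)],
)
def test_gm_drawdown_reproduces_published_rounding(a, ci, cc, printed):
    assert round(gm_variable_j(a, ci, cc), 3) == printed


def test_gm_zero_assimilation_and_singularity():
    assert gm_variable_j(0.0, 300.0, 250.0) == 0.0
    with pytest.raises(DegeneracyError):
        gm_variable_j(5.0, 300.0, 300.0)


@pytest.mark.parametrize(
    "gs,gm,printed",
    [(0.085, 0.152, 0.054), (0.100, 0.098, 0.049), (0.049, 0.022, 0.015)],
)
def test_total_conductance_published_values(gs, gm, printed):
    assert total_conductance(gs, gm) == pytest.approx(printed, abs=1e-3)


def test_total_conductance_symmetry_and_halving():
    assert total_conductance(0.1, 0.1) == pytest.approx(0.05, rel=1e-12)
    assert total_conductance(0.03, 0.2) == total_conductance(0.2, 0.03)


@settings(max_examples=100, deadline=None)
@given(gs=st.floats(1e-3, 1.0), gm=st.floats(1e-3, 1.0), bump=st.floats(1.01, 3.0))
def test_total_conductance_bounded_and_monotone(gs, gm, bump):
    gt = total_conductance(gs, gm)
    assert gt < min(gs, gm)
    assert total_conductance(gs * bump, gm) > gt
    assert total_conductance(gs, gm * bump) > gt


def test_total_conductance_domain_error():
    with pytest.raises(DomainError):
        total_conductance(0.0, 0.1)


def test_variable_j_round_trip_with_generator(colwt_leaf):
    curve = simulate_aci(colwt_leaf)
    res = variable_j_curve(curve, rd=colwt_leaf.rd, gamma_star=colwt_leaf.gamma_star,
                           alpha_beta=colwt_leaf.alpha_beta)
    ok = res.physical
    # every point with positive net uptake is usable; the lowest setpoint can
    # sit below the compensation point and is then rightly excluded
    assert ok.sum() >= len(curve) - 1
    assert np.max(np.abs(res.gm[ok] - colwt_leaf.gm) / colwt_leaf.gm) < 1e-8
    assert res.operating is not None and res.operating["cc"] < res.operating["ci"]
    assert res.gt == pytest.approx(total_conductance(colwt_leaf.gs, colwt_leaf.gm), rel=1e-8)


# ---------------------------------------------------------------- Laisk


def _laisk_lines(slopes=(0.02, 0.04, 0.08), ci_star=35.0, rd=1.2, cis=(50.0, 80.0, 110.0, 140.0)):
    curves = []
    for i, s in enumerate(slopes):
        records = [
            GasExchangeRecord(a=s * (ci - ci_star) - rd, ci=ci, ca=ci + 10.0, gs=0.08,
                              e=1.0, ppfd=50.0 * (i + 1), tleaf=25.0)
            for ci in cis
        ]
        curves.append(CurveSet(kind="laisk", genotype="x", replicate=f"L{i}", records=records))
    return curves


def test_laisk_constructed_intersection():
    res = fit_laisk(_laisk_lines())
    assert res.ci_star == pytest.approx(35.0, rel=1e-10)
    assert res.rd == pytest.approx(1.2, rel=1e-10)
    assert res.residual < 1e-10
    assert not res.quality_warning


def test_laisk_gamma_star_conversion():
    res = fit_laisk(_laisk_lines(), gm=0.1)
    assert res.gamma_star == pytest.approx(35.0 + 1.2 / 0.1, rel=1e-10)


def test_laisk_parallel_lines_raise():
    with pytest.raises(NoIntersectionError):
        fit_laisk(_laisk_lines(slopes=(0.04, 0.04, 0.04)))


def test_laisk_needs_three_distinct_irradiances():
    curves = _laisk_lines()[:2]
    with pytest.raises(InsufficientDataError):
        fit_laisk(curves)


def test_laisk_recovers_generator_truth(colwt_leaf):
    curves = simulate_laisk_set(colwt_leaf)
    res = fit_laisk(curves)
    assert res.rd == pytest.approx(colwt_leaf.rd, rel=1e-6)
    assert res.ci_star == pytest.approx(colwt_leaf.ci_star, rel=1e-6)
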