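import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdiffuse import (
    DataValidationError,
    DomainError,
    InsufficientDataError,
    OperatingPoint,
    limitation_contributions,
    lsd_groups,
    pnue,
    relative_limitations,
    total_conductance,
)


def _op(gs=0.1, gm=0.1, dadcc=0.05, a=5.0, cc=250.0, vcmax=30.0):
    return OperatingPoint(a=a, gs=gs, gm=gm, gt=total_conductance(gs, gm), cc=cc,
                          vcmax=vcmax, dadcc=dadcc)


def test_relative_limitations_hand_value():
    ls, lm, lb = relative_limitations(_op())
    assert ls == pytest.approx(0.25, rel=1e-12)
    assert lm == pytest.approx(0.25, rel=1e-12)
    assert lb == pytest.approx(0.5, rel=1e-12)


def test_relative_limitations_limits():
    ls, lm, lb = relative_limitations(_op(dadcc=1e9))
    assert lb < 1e-9 and ls + lm == pytest.approx(1.0, abs=1e-9)
    ls, lm, lb = relative_limitations(_op(dadcc=1e-12))
    assert lb == pytest.approx(1.0, abs=1e-9)


def test_operating_point_requires_consistent_gt():
    with pytest.raises(DataValidationError):
        OperatingPoint(a=5.0, gs=0.1, gm=0.1, gt=0.06, cc=250.0, vcmax=30.0, dadcc=0.05)


@settings(max_examples=200, deadline=None)
@given(gs=st.floats(5e-3, 1.0), gm=st.floats(5e-3, 1.0), dadcc=st.floats(1e-4, 1.0))
def test_relative_limitations_close_to_one(gs, gm, dadcc):
    """Algebraic identity: ls + lm + lb = 1 under the series constraint."""
    ls, lm, lb = relative_limitations(_op(gs=gs, gm=gm, dadcc=dadcc))
    assert ls + lm + lb == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= ls <= 1.0 and 0.0 <= lm <= 1.0 and 0.0 <= lb <= 1.0


def test_contributions_of_identical_leaves_vanish():
    res = limitation_contributions(_op(), _op())
    assert res.Ls == res.Lm == res.Lb == 0.0
    assert res.dA_over_A == 0.0


def test_contributions_hand_decomposition():
    # halving gs and gm with unchanged Vcmax: dA decomposition 0.125+0.125+0
    ref = _op(a=8.0)
    mut = _op(gs=0.05, gm=0.05, a=6.0)
    res = limitation_contributions(ref, mut)
    assert res.Ls == pytest.approx(0.5 * 0.25)
    assert res.Lm == pytest.approx(0.5 * 0.25)
    assert res.Lb == 0.0
    assert res.Ls + res.Lm + res.Lb == pytest.approx(0.25)
    assert res.dA_over_A == pytest.approx(0.25)
    assert res.mismatch == pytest.approx(0.0, abs=1e-12)


def test_mesophyll_dominates_published_mutant_contrasts(kin):
    """With default kinetics and the published operating points, the mesophyll
    share of the mutants' assimilation loss exceeds the stomatal share, and
    biochemistry is minor."""
    from leafdiffuse import BiochemParams, dA_dCc
    from leafdiffuse.synthetic_data import REFERENCE_TRAITS, WILD_TYPE_OF

    def op(name):
        t = REFERENCE_TRAITS[name]
        k = kin.with_gamma_star(t["gamma_star"])
        p = BiochemParams(vcmax=t["vcmax"], jcmax=t["jcmax"], rd=t["rd"])
        return OperatingPoint(a=t["a"], gs=t["gs"], gm=t["gm_harley"],
                              gt=total_conductance(t["gs"], t["gm_harley"]),
                              cc=t["cc"], vcmax=t["vcmax"],
                              dadcc=float(dA_dCc(p, k, t["cc"])))

    for mut, wt in WILD_TYPE_OF.items():
        res = limitation_contributions(op(wt), op(mut))
        assert res.Lm > res.Ls > res.Lb > 0


def test_pnue_values_and_scaling():
    assert pnue(3.32, 0.613) == pytest.approx(5.42, abs=5e-3)
    assert pnue(0.0, 0.5) == 0.0
    assert pnue(3.32, 2 * 0.613) == pytest.approx(pnue(3.32, 0.613) / 2, rel=1e-12)
    with pytest.raises(DomainError):
        pnue(3.0, 0.0)


# ------------------------------------------------------------------- LSD


def test_lsd_identical_groups_share_letter():
    rng = np.random.default_rng(0)
    base = rng.normal(10.0, 1.0, 5)
    groups = {"g1": base, "g2": base.copy(), "g3": base.copy()}
    letters = lsd_groups(groups)
    assert set(letters.values()) == {"a"}


def test_lsd_three_separated_groups_get_distinct_letters():
    rng = np.random.default_rng(1)
    groups = {c: rng.normal(mu, 0.1, 3) for c, mu in zip("xyz", (20.0, 10.0, 0.0))}
    letters = lsd_groups(groups)
    assert letters["x"] == "a" and letters["y"] == "b" and letters["z"] == "c"


def test_lsd_groups_below_lsd_share_letter():
    rng = np.random.default_rng(2)
    a = rng.normal(10.0, 1.0, 4)
    b = a + 0.05  # far below the least significant difference
    letters = lsd_groups({"a": a, "b": b})
    assert letters["a"] == letters["b"]


def test_lsd_chain_produces_overlapping_letters():
    rng = np.random.default_rng(3)
    sd, n = 1.0, 4
    groups = {"hi": rng.normal(6.0, sd, n), "mid": rng.normal(4.3, sd, n), "lo": rng.normal(0.0, sd, n)}
    letters = lsd_groups(groups)
    # hi ~ mid and mid !~ lo must share/not-share letters accordingly
    assert set(letters["hi"]) & set(letters["mid"])
    assert not (set(letters["hi"]) & set(letters["lo"]))


def test_lsd_degenerate_variance_raises():
    with pytest.raises(DomainError):
        lsd_groups({"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0])})
    with pytest.raises(InsufficientDataError):
        lsd_groups({"a": np.array([1.0, 2.0])})
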