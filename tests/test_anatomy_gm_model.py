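import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdiffuse import (
    DomainError,
    LeafAnatomy,
    PhysicalConstants,
    component_conductance,
    gas_phase_conductance,
    gm_from_anatomy,
    sensitivity_grid,
)
from leafdiffuse.synthetic_data import REFERENCE_TRAITS, WILD_TYPE_OF

PC = PhysicalConstants()


def _anatomy(name: str) -> LeafAnatomy:
    t = REFERENCE_TRAITS[name]
    return LeafAnatomy(fias=t["fias"], sm=t["sm"], sc=t["sc"], tcw=t["tcw"], tcyt=t["tcyt"],
                       tstr=t["tstr"], tmes=t["tmes"], tleaf=t["tleaf"])


anatomy_strategy = st.builds(
    LeafAnatomy,
    fias=st.floats(0.05, 0.6),
    sm=st.just(20.0),
    sc=st.floats(2.0, 15.0),
    tcw=st.floats(0.05, 0.6),
    tcyt=st.floats(0.03, 0.5),
    tstr=st.floats(0.5, 4.0),
    tmes=st.floats(30.0, 200.0),
    tleaf=st.just(80.0),
)


def test_gas_phase_conductance_arithmetic():
    g = gas_phase_conductance(0.234, 68.4, PC)
    assert g == pytest.approx(0.0658, abs=1e-4)
    assert PC.molar(g) == pytest.approx(2.690, abs=2e-3)


def test_gas_phase_conductance_scalings():
    g = gas_phase_conductance(0.2, 60.0, PC)
    assert gas_phase_conductance(0.4, 60.0, PC) == pytest.approx(2 * g, rel=1e-12)
    assert gas_phase_conductance(0.2, 120.0, PC) == pytest.approx(g / 2, rel=1e-12)


def test_component_conductance_arithmetic_and_linearity():
    gi = component_conductance(1.79e-9, 1.0, 1.0, 1e-6)
    assert gi == pytest.approx(1.79e-3, rel=1e-12)
    assert component_conductance(1.79e-9, 1.0, 0.5, 1e-6) == pytest.approx(gi / 2, rel=1e-12)
    with pytest.raises(DomainError):
        component_conductance(1.79e-9, 1.0, 1.0, 0.0)


def test_membranes_use_fixed_conductance():
    part = gm_from_anatomy(_anatomy("colwt"), PC)
    assert part.gpl == PC.g_pl == 0.0035
    assert part.gen == PC.g_en == 0.0035


def test_partition_closure_on_reference_anatomies():
    for name in REFERENCE_TRAITS:
        part = gm_from_anatomy(_anatomy(name), PC)
        total = part.lias + part.lcw + part.lpl + part.len_ + part.lcyt + part.lstr
        assert total == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=200, deadline=None)
@given(an=anatomy_strategy)
def test_partition_closure_random_anatomies(an):
    part = gm_from_anatomy(an, PC)
    total = part.lias + part.lcw + part.lpl + part.len_ + part.lcyt + part.lstr
    assert total == pytest.approx(1.0, abs=1e-9)


def test_each_wild_type_exceeds_its_mutant():
    gm = {name: gm_from_anatomy(_anatomy(name), PC).gm_mol for name in REFERENCE_TRAITS}
    for mut, wt in WILD_TYPE_OF.items():
        assert gm[wt] > gm[mut]


def test_stroma_is_largest_liquid_limitation():
    for name in REFERENCE_TRAITS:
        part = gm_from_anatomy(_anatomy(name), PC)
        liquid = part.liquid_fractions
        assert liquid["lstr"] == max(liquid.values())
        # roughly half of the cellular-phase resistance sits in the stroma
        assert liquid["lstr"] > 0.45


def test_removing_any_liquid_resistance_increases_gm():
    an = _anatomy("colwt")
    base = gm_from_anatomy(an, PC).gm_mol
    # vanishing wall, cytosol or stroma path -> resistance of that leg -> 0
    for trait in ("tcw", "tcyt", "tstr"):
        boosted = dataclasses.replace(an, **{trait: 1e-6})
        assert gm_from_anatomy(boosted, PC).gm_mol > base
    relaxed = dataclasses.replace(PC, g_pl=1e6, g_en=1e6)
    assert gm_from_anatomy(an, relaxed).gm_mol > base


def test_sc_scaling_with_negligible_gas_phase_resistance():
    an = _anatomy("colwt")
    fast_gas = dataclasses.replace(PC, da=1e3)
    g1 = gm_from_anatomy(an, fast_gas).gm_mol
    g2 = gm_from_anatomy(dataclasses.replace(an, sm=2 * an.sm, sc=2 * an.sc), fast_gas).gm_mol
    assert g2 == pytest.approx(2 * g1, rel=1e-6)


@pytest.mark.parametrize("trait,direction", [("tcw", -1), ("tcyt", -1), ("tstr", -1), ("sc", +1), ("fias", +1)])
def test_sensitivity_monotonicities(trait, direction):
    ranges = {"tcw": np.linspace(0.05, 0.6, 15), "tcyt": np.linspace(0.03, 0.5, 15),
              "tstr": np.linspace(0.5, 4.0, 15), "sc": np.linspace(2.0, 8.0, 15),
              "fias": np.linspace(0.05, 0.5, 15)}
    table = sensitivity_grid(_anatomy("colwt"), PC, {trait: ranges[trait]})
    diffs = np.diff(table["gm_mol"].to_numpy())
    assert np.all(direction * diffs > 0)


def test_thin_walls_amplify_sc_sensitivity():
    """Losing Sc costs more gm (in absolute terms) when the cell wall is
    thin: gm is then high and its loss per unit Sc, (liquid share)*gm/Sc,
    is dominated by the larger gm."""
    an = _anatomy("colwt")
    out = {}
    for tcw in (0.1, 0.55):
        grid = sensitivity_grid(an, PC, {"tcw": [tcw], "sc": [8.0, 6.0]})
        g_hi, g_lo = grid["gm_mol"].to_numpy()
        out[tcw] = g_hi - g_lo
    assert out[0.1] > out[0.55]


def test_two_trait_grid_shape():
    grid = sensitivity_grid(_anatomy("colwt"), PC, {"tcw": [0.1, 0.2, 0.3], "sc": [4.0, 8.0]})
    assert len(grid) == 6 and set(grid.columns) == {"tcw", "sc", "gm_mol"}
    with pytest.raises(DomainError):
        sensitivity_grid(_anatomy("colwt"), PC, {})
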