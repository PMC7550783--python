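import pytest

from dermadiff import (
    FENTANYL,
    LayerStack,
    MaterialProps,
    MeshControls,
    ReservoirSpec,
    ScenarioConfig,
    initial_reservoir_mass,
    partition_coefficient,
    preset,
    preset_names,
    sc_thickness_from_age,
    series_resistance_flux,
)
from dermadiff.domain_model import with_replaced_layer


def test_initial_reservoir_mass_exact():
    # 80 kg/m^3 * (40 mm)^2 * 50 um = 6.4 mg, exact arithmetic
    res = ReservoirSpec(40e-3, 50e-6, 80.0, "finite")
    assert initial_reservoir_mass(res) == pytest.approx(6.4, abs=1e-12)


def test_initial_mass_undefined_for_infinite():
    res = ReservoirSpec(40e-3, 50e-6, 80.0, "infinite")
    with pytest.raises(ValueError):
        initial_reservoir_mass(res)


def test_material_validation():
    with pytest.raises(ValueError):
        MaterialProps("stratum_corneum", -1e-6, 7.2e-15, 1.05e-12, 0.14)
    with pytest.raises(ValueError):
        MaterialProps("unknown_layer", 1e-6, 1e-14, 1e-14, 1.0)
    with pytest.raises(ValueError):
        # the reservoir capacity anchors the potential scale and must be 1
        MaterialProps("patch", 50e-6, 1e-13, 1e-13, 2.0)


def test_partition_coefficient_is_capacity_ratio():
    sc = preset("base_case").stack.get("stratum_corneum")
    vep = preset("base_case").stack.get("viable_epidermis")
    k = partition_coefficient(sc, vep)
    assert k.value == pytest.approx(0.14 / 0.00084)


def test_stack_requires_reservoir_on_top():
    sc = preset("base_case").stack.get("stratum_corneum")
    patch = preset("base_case").stack.get("patch")
    with pytest.raises(ValueError):
        LayerStack((sc, patch))


def test_scenario_regime_consistency():
    cfg = preset("base_case")
    with pytest.raises(ValueError):
        # infinite regime must not carry a meshed reservoir layer
        ScenarioConfig(
            stack=cfg.stack,
            reservoir=ReservoirSpec(40e-3, 50e-6, 80.0, "infinite"),
        )
    with pytest.raises(ValueError):
        # removal outside the horizon
        ScenarioConfig(
            stack=cfg.stack, reservoir=cfg.reservoir, removal_time_h=300.0
        )


def test_age_correlation_values_and_warning():
    assert sc_thickness_from_age(18.0) == pytest.approx(14.05e-6)
    assert sc_thickness_from_age(70.0) == pytest.approx(20.55e-6)
    with pytest.warns(UserWarning):
        sc_thickness_from_age(90.0)


def test_series_resistance_closed_form():
    cfg = preset("infinite")
    # 80 / [d_sc/(D_sc,z K_sc) + d_vep/(D_vep K_vep)]
    R = 15e-6 / (7.2e-15 * 0.14) + 70e-6 / (2e-11 * 0.00084)
    expected = 80.0 / R
    assert series_resistance_flux(cfg.stack, 80.0) == pytest.approx(expected)
    # in reported units this sits near the commercial flux band
    assert expected * 3.6e8 == pytest.approx(1.512, rel=1e-3)


def test_presets_complete_and_valid():
    for name in preset_names():
        cfg = preset(name)
        assert cfg.stack.skin_thickness > 0
        assert cfg.drug == FENTANYL


def test_margin_default_is_twenty_skin_thicknesses():
    cfg = preset("base_case")
    assert cfg.margin == pytest.approx(20.0 * 85e-6)


def test_with_replaced_layer_re_meshes_geometry():
    cfg = preset("base_case")
    thicker = with_replaced_layer(cfg, "stratum_corneum", thickness=30e-6)
    assert thicker.stack.get("stratum_corneum").thickness == 30e-6
    # untouched layers are shared unchanged
    assert thicker.stack.get("viable_epidermis") == cfg.stack.get("viable_epidermis")


def test_mesh_controls_validation():
    with pytest.raises(ValueError):
        MeshControls(cells_per_layer=1)
    with pytest.raises(ValueError):
        MeshControls(grading_ratio=0.5)
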