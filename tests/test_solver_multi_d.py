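import numpy as np
import pytest

from dermadiff import preset, series_resistance_flux
from dermadiff.domain_model import with_replaced_layer
from dermadiff.solver_multi_d import (
    build_mesh_multi_d,
    reservoir_count_for_flow,
    solve_steady_footprint,
    solve_transient_footprint,
    sweep_reservoir_sizes,
)


@pytest.fixture(scope="module")
def micro_40um():
    return solve_steady_footprint(preset("reservoir_sweep", L_pt=40e-6))


def test_steady_flux_balance(micro_40um):
    # direct linear solve: inflow and outflow agree to solver precision
    assert micro_40um.flux_balance < 1e-9


def test_wide_footprint_recovers_unidirectional_limit():
    """Below the center of a 40 mm reservoir the field is locally 1D: the
    local uptake flux matches the series-resistance value to <0.4%, and the
    footprint-average flux only carries the small perimeter enhancement."""
    cfg = preset("reservoir_sweep", L_pt=40e-3)
    res = solve_steady_footprint(cfg)
    g_1d = series_resistance_flux(cfg.stack, cfg.surface_potential)
    mesh = res.mesh
    g_center = 2.0 * mesh.D_z[-1] * mesh.K[-1] / mesh.hz[-1] * res.psi[-1, 0, 0]
    assert g_center == pytest.approx(g_1d, rel=4e-3)
    assert res.g_pt_rel == pytest.approx(g_1d, rel=2e-2)
    assert res.g_pt_rel > g_1d  # edge effect can only add flux


def test_enhancement_monotone_in_inverse_width():
    table = sweep_reservoir_sizes((4e-3, 400e-6, 40e-6))
    enh = table["enhancement"].to_numpy()
    assert np.all(np.diff(enh) > 0)
    assert (table["flux_balance"] < 1e-9).all()
    # threshold behavior: clearly more than double below ~10 epidermis depths
    below = table[table["L_over_d_ep"] < 10.0]
    assert (below["enhancement"] > 2.0).all()


def test_anisotropy_increases_enhancement(micro_40um):
    """Lateral spreading through the stratum corneum (D_xy >> D_z) feeds the
    edge singularity; an isotropic stratum corneum must enhance less."""
    cfg = preset("reservoir_sweep", L_pt=40e-6)
    iso_cfg = with_replaced_layer(cfg, "stratum_corneum", D_xy=7.2e-15)
    g_1d = series_resistance_flux(cfg.stack, cfg.surface_potential)
    g_iso = solve_steady_footprint(iso_cfg).g_pt_rel
    assert micro_40um.g_pt_rel > g_iso > g_1d


def test_mesh_refinement_is_nested_and_convergent():
    cfg = preset("reservoir_sweep", L_pt=40e-6)
    g0 = solve_steady_footprint(cfg, refinement=0).g_pt_rel
    g1 = solve_steady_footprint(cfg, refinement=1).g_pt_rel
    # refinement resolves more of the edge singularity: flux grows, but by
    # a bounded fraction once the contact boundary layer is resolved
    assert g1 > g0
    assert abs(g1 / g0 - 1.0) < 0.05


def test_transient_micro_reservoir_conserves_mass():
    cfg = preset("reservoir_sweep", L_pt=40e-6, regime="finite")
    from dataclasses import replace

    cfg = replace(cfg, horizon_h=24.0)
    t, g_rel, m_res = solve_transient_footprint(cfg)
    assert np.all(np.diff(m_res) <= 1e-18)
    released = np.trapezoid(g_rel, t) * cfg.reservoir.width**2
    assert released == pytest.approx(m_res[0] - m_res[-1], rel=5e-2)
    # a micro-reservoir depletes fast: initial load is tiny
    assert m_res[0] == pytest.approx(80.0 * (40e-6) ** 2 * 50e-6, rel=1e-12)


def test_mesh_validation_and_geometry():
    cfg = preset("reservoir_sweep", L_pt=40e-6)
    mesh = build_mesh_multi_d(cfg)
    assert mesh.n_fp >= 4
    # vertical top cells shrink by the anisotropy contrast of the stratum
    # corneum so the contact boundary layer is resolved
    assert mesh.hz[0] < mesh.hx[mesh.n_fp - 1]
    # footprint edge coincides with a cell face
    assert np.sum(mesh.hx[: mesh.n_fp]) == pytest.approx(20e-6)


def test_reservoir_count_arithmetic():
    count, frac = reservoir_count_for_flow(
        40e-6, 100.0, patch_area_cm2=16.0, flow_per_reservoir_ug_h=0.3
    )
    assert count == 334  # ceil(100 / 0.3)
    assert frac == pytest.approx(334 * (40e-4) ** 2 / 16.0)
    with pytest.raises(ValueError):
        reservoir_count_for_flow(40e-6, 100.0, flow_per_reservoir_ug_h=0.0)
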