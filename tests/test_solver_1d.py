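import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import expm

from dermadiff import (
    LayerStack,
    MeshControls,
    ReservoirSpec,
    ScenarioConfig,
    build_mesh,
    grid_convergence_study,
    preset,
    series_resistance_flux,
    simulate,
    steady_infinite_flux,
)
from dermadiff.domain_model import isotropic
from dermadiff.solver_1d import _assemble
from dermadiff.units import S_PER_H


def small_mesh_config():
    """Base case coarsened to 36 cells total (12 per layer)."""
    cfg = preset("base_case")
    return replace(cfg, mesh=MeshControls(cells_per_layer=12), horizon_h=24.0)


def test_matrix_exponential_oracle_finite():
    """On a <=40-cell mesh the integrated field must match the dense matrix
    exponential of the semi-discrete operator to 1e-8 of the potential scale."""
    cfg = small_mesh_config()
    res = simulate(cfg, rtol=1e-11)
    mesh = res.mesh
    assert mesh.n_cells <= 40
    sys_ = _assemble(mesh, None)
    B = np.diag(1.0 / sys_.M) @ sys_.A.toarray()
    psi0 = np.where(mesh.cells_of("patch"), cfg.surface_potential, 0.0)
    scale = cfg.surface_potential
    for i in (1, len(res.t) // 2, len(res.t) - 1):
        oracle = expm(B * res.t[i]) @ psi0
        assert np.max(np.abs(res.psi[i] - oracle)) / scale < 1e-8


def test_matrix_exponential_oracle_infinite():
    """Dirichlet (constant surface potential) variant of the oracle check."""
    cfg = replace(
        preset("infinite"), mesh=MeshControls(cells_per_layer=16), horizon_h=24.0
    )
    res = simulate(cfg, rtol=1e-11)
    mesh = res.mesh
    assert mesh.n_cells <= 40
    sys_ = _assemble(mesh, cfg.surface_potential)
    Minv = np.diag(1.0 / sys_.M)
    B = Minv @ sys_.A.toarray()
    c = Minv @ sys_.b
    psi_ss = -np.linalg.solve(B, c)
    scale = cfg.surface_potential
    for i in (1, len(res.t) // 2, len(res.t) - 1):
        oracle = psi_ss + expm(B * res.t[i]) @ (-psi_ss)
        assert np.max(np.abs(res.psi[i] - oracle)) / scale < 1e-8


def test_single_slab_analytic_transient():
    """Uptake flux through a single homogeneous slab held at a constant
    surface potential must match the classical series solution to 0.1%."""
    L, D, K, psi_top = 50.8e-6, 3.0e-14, 0.14, 80.0
    stack = LayerStack((isotropic("lumped_epidermis", L, D, K),))
    cfg = ScenarioConfig(
        stack=stack,
        reservoir=ReservoirSpec(40e-3, 50e-6, psi_top, "infinite"),
        horizon_h=48.0,
        name="slab",
    )
    res = simulate(cfg, refinement=1, rtol=1e-10)

    def analytic_flux(t):
        s = sum(
            (-1) ** n * np.exp(-(n**2) * np.pi**2 * D * t / L**2)
            for n in range(1, 80)
        )
        return D * K * psi_top / L * (1.0 + 2.0 * s)

    for t_h in (6.0, 12.0, 24.0, 48.0):
        g = res.at_time(t_h, res.g_bl_up)
        g_ref = analytic_flux(t_h * S_PER_H)
        assert g == pytest.approx(g_ref, rel=1e-3)


def test_richardson_discretization_error():
    """Grid-convergence study on 72 h uptake: observed order near 2 and a
    discretization error of the finest level below 0.1%."""
    cfg = replace(preset("base_case"), horizon_h=80.0)
    study = grid_convergence_study(cfg, levels=(0, 1, 2))
    assert study["relative_error"] < 1e-3
    assert 1.2 < study["order"] < 3.0


def test_interface_concentration_ratio(base_run):
    """Concentration jump at the reservoir/stratum-corneum interface must
    approach the partition coefficient K_sc/K_pt = 0.14 under refinement."""
    target = 0.14

    def jump(res, t_h=24.0):
        mesh = res.mesh
        i = int(np.sum(mesh.cells_of("patch")))  # first skin cell
        f = res.field_at(t_h)
        c = f.concentration
        return c[i] / c[i - 1]

    coarse = simulate(preset("base_case"), refinement=0, rtol=1e-10)
    fine = simulate(preset("base_case"), refinement=1, rtol=1e-10)
    e0 = abs(jump(coarse) - target)
    e1 = abs(jump(fine) - target)
    assert e1 < e0  # converging toward the partition ratio
    assert jump(fine) == pytest.approx(target, rel=5e-3)


def test_mass_balance_and_internal_consistency(base_run):
    res = base_run
    m_ini = res.m_pt_ini
    residual = np.abs(m_ini - res.m_pt_res - res.m_ep_stor - res.m_bl_up) / m_ini
    assert residual.max() < 1e-6
    # cumulative release feeds storage plus uptake (initially empty skin)
    rel_residual = np.abs(res.m_pt_rel - res.m_ep_stor - res.m_bl_up) / m_ini
    assert rel_residual.max() < 1e-6


def test_monotonicity_and_positivity(base_run):
    res = base_run
    assert np.all(np.diff(res.m_bl_up) >= -1e-15)
    assert np.all(np.diff(res.m_pt_res) <= 1e-15)
    assert np.all(res.g_bl_up >= 0.0)
    assert np.all(res.psi >= 0.0)


def test_infinite_maximum_principle(infinite_run):
    assert infinite_run.psi.max() <= infinite_run.config.surface_potential * (1 + 1e-9)


def test_removal_books_and_conserves(removal_run):
    res = removal_run
    i_rm = int(np.argmin(np.abs(res.t_h - 72.0)))
    store_at_removal = res.m_ep_stor[i_rm]
    uptake_gain = res.m_bl_up[-1] - res.m_bl_up[i_rm]
    store_drained = store_at_removal - res.m_ep_stor[-1]
    assert uptake_gain == pytest.approx(store_drained, rel=1e-9)
    # patch mass booked out exactly once
    assert res.removed_with_patch == pytest.approx(res.m_pt_res[i_rm], rel=1e-12)
    assert np.all(res.m_pt_res[i_rm + 1 :] == 0.0)
    # epidermal store is essentially drained by the 240 h horizon
    assert res.m_ep_stor[-1] < 1e-3 * store_at_removal


def test_steady_flux_matches_series_resistance():
    cfg = preset("infinite")
    g_direct = steady_infinite_flux(cfg)
    g_closed = series_resistance_flux(cfg.stack, cfg.surface_potential)
    assert g_direct == pytest.approx(g_closed, rel=1e-10)


def test_transient_approaches_steady(infinite_run):
    g_ss = steady_infinite_flux(infinite_run.config)
    assert infinite_run.g_bl_up[-1] == pytest.approx(g_ss, rel=1e-3)


def test_mesh_resolves_all_layers():
    mesh = build_mesh(preset("base_case"))
    assert set(mesh.labels) == {"patch", "stratum_corneum", "viable_epidermis"}
    assert mesh.faces[-1] == pytest.approx(50e-6 + 15e-6 + 70e-6)
    # graded widths: smallest cells sit at layer boundaries
    w = mesh.widths
    patch = mesh.cells_of("patch")
    assert w[patch][0] < w[patch].mean()
    assert w[patch][-1] < w[patch].mean()
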