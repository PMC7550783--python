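"""Steady and transient solvers on 2D/3D graded tensor-product grids.

Used for the reservoir-miniaturization study: a square drug reservoir of
side L_pt sits on a laterally extended two-layer epidermis. Once L_pt is no
longer large compared to the epidermal thickness, drug spreads transversely
— strongly so in the stratum corneum, whose transverse diffusivity is more
than two orders of magnitude above its longitudinal one — and the per-area
released flux rises far above the unidirectional value.

Geometry: quarter-symmetric domain (symmetry planes at x=0 and y=0), lateral
extent L_pt/2 + margin, zero-flux on outer lateral boundaries, potential
pinned to 0 at the epidermis–dermis interface. The infinite-reservoir regime
pins the potential to c_ini/K_pt on the footprint portion of the skin
surface; the finite regime meshes the patch explicitly above the footprint.

Meshing: cells grow geometrically away from the footprint edge and away from
layer interfaces. The contact boundary layer in the anisotropic stratum
corneum has a vertical extent ~ sqrt(D_z/D_xy) times its lateral extent, so
the top-cell height is scaled down by that factor relative to the lateral
edge cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain_model import ScenarioConfig, preset, series_resistance_flux
from .units import FLUX_SI_TO_UG_PER_CM2_H, S_PER_H

__all__ = [
    "MeshMultiD",
    "SteadyFootprintResult",
    "build_mesh_multi_d",
    "solve_steady_footprint",
    "solve_transient_footprint",
    "sweep_reservoir_sizes",
    "reservoir_count_for_flow",
]


def _geometric_sizes(length: float, h0: float, ratio: float) -> np.ndarray:
    """Cell sizes starting at h0, growing by ``ratio`` until ``length`` is
    filled, then rescaled so they sum to ``length`` exactly."""
    if h0 >= length:
        return np.array([length])
    sizes = [h0]
    while sum(sizes) < length:
        sizes.append(sizes[-1] * ratio)
    s = np.asarray(sizes)
    return s * (length / s.sum())


def _double_graded_sizes(length: float, h0: float, ratio: float) -> np.ndarray:
    half = _geometric_sizes(length / 2.0, h0, ratio)
    return np.concatenate([half, half[::-1]])


@dataclass(frozen=True)
class MeshMultiD:
    """Tensor-product graded grid on the quarter domain.

    ``hx``/``hy`` are lateral cell sizes (x=0 is the symmetry plane, the
    footprint edge lies at a cell face); ``hz`` runs from the skin surface
    (or patch top when the patch is meshed) downward. ``n_fp`` is the number
    of lateral cells inside the footprint per direction; ``layer`` indexes
    ``labels`` per z-cell.
    """

    hx: np.ndarray
    hy: np.ndarray
    hz: np.ndarray
    n_fp: int
    layer: np.ndarray
    labels: tuple
    D_xy: np.ndarray  # per z-cell
    D_z: np.ndarray
    K: np.ndarray
    two_d: bool = False

    @property
    def shape(self):
        return (len(self.hz), len(self.hy), len(self.hx))

    @property
    def n_cells(self):
        nz, ny, nx = self.shape
        return nz * ny * nx


def build_mesh_multi_d(
    config: ScenarioConfig,
    refinement: int = 0,
    two_d: bool = False,
    include_patch: bool = False,
) -> MeshMultiD:
    """Graded quarter-domain mesh for a given reservoir width.

    ``refinement`` halves the edge and top cell targets per level (used for
    the mesh-convergence log). ``two_d`` collapses the y direction to a
    single unit-depth cell (plane cross-section mode, exploration only).
    """
    res = config.reservoir
    L_half = res.width / 2.0
    margin = config.margin
    ratio = max(config.mesh.grading_ratio, 1.3)
    fac = 2.0**refinement

    h_edge = min(L_half / (8 * fac), 40e-6 / fac)
    skin = config.stack.skin_layers
    sc = skin[0]
    aniso = sqrt(sc.D_z / sc.D_xy)
    h_top = min(max(h_edge * aniso, 1e-10), sc.thickness / (10 * fac))

    inner = _geometric_sizes(L_half, h_edge, ratio)[::-1]  # fine at the edge
    if len(inner) < 4:
        raise ValueError("mesh cannot resolve the footprint (need >= 4 cells across L_pt/2)")
    outer = _geometric_sizes(margin, h_edge, ratio)
    hx = np.concatenate([inner, outer])
    hy = np.array([1.0]) if two_d else hx.copy()

    hz_parts, layer, labels = [], [], []
    z_layers = list(skin)
    if include_patch:
        z_layers = [config.stack.layers[0]] + z_layers if config.stack.has_reservoir else z_layers
    li0 = 0
    for mat in z_layers:
        if mat.label == "patch":
            sizes = _double_graded_sizes(mat.thickness, mat.thickness / (6 * fac), ratio)
        elif mat is sc:
            sizes = _geometric_sizes(mat.thickness, h_top, ratio)
        else:
            sizes = _double_graded_sizes(
                mat.thickness, min(2e-6 / fac, mat.thickness / 8), ratio
            )
        hz_parts.append(sizes)
        labels.append(mat.label)
        layer += [li0] * len(sizes)
        li0 += 1
    hz = np.concatenate(hz_parts)
    layer = np.asarray(layer)
    D_xy = np.array([z_layers[i].D_xy for i in layer])
    D_z = np.array([z_layers[i].D_z for i in layer])
    K = np.array([z_layers[i].K for i in layer])
    return MeshMultiD(
        hx=hx, hy=hy, hz=hz, n_fp=len(inner), layer=layer, labels=tuple(labels),
        D_xy=D_xy, D_z=D_z, K=K, two_d=two_d,
    )


def _harm(h1, a1, h2, a2):
    return 1.0 / (0.5 * h1 / a1 + 0.5 * h2 / a2)


def _assemble(mesh: MeshMultiD, psi_top: Optional[float]):
    """Sparse operator A psi + b for the steady problem (quarter domain).

    Returns (A, b, gtop, gbot) where gtop are the Dirichlet-face conductances
    (area-weighted) over the footprint cells and gbot over the bottom plane.
    When the patch is meshed (finite regime), psi_top is None and the top
    boundary is zero-flux.
    """
    hx, hy, hz = mesh.hx, mesh.hy, mesh.hz
    nz, ny, nx = mesh.shape
    DKxy = (mesh.D_xy * mesh.K)[:, None, None]
    DKz = (mesh.D_z * mesh.K)[:, None, None]
    HX = hx[None, None, :]
    HY = hy[None, :, None]
    HZ = hz[:, None, None]
    N = mesh.n_cells
    IDX = np.arange(N).reshape(nz, ny, nx)
    rows, cols, vals = [], [], []
    diag = np.zeros((nz, ny, nx))

    def couple(g, p, q, sl_p, sl_q):
        rows.extend([p.ravel(), q.ravel()])
        cols.extend([q.ravel(), p.ravel()])
        vals.extend([g.ravel(), g.ravel()])
        diag[sl_p] -= g
        diag[sl_q] -= g

    g = _harm(HX[:, :, :-1], DKxy, HX[:, :, 1:], DKxy) * (HY * HZ)
    couple(g, IDX[:, :, :-1], IDX[:, :, 1:],
           (slice(None), slice(None), slice(None, -1)),
           (slice(None), slice(None), slice(1, None)))
    if ny > 1:
        g = _harm(HY[:, :-1, :], DKxy, HY[:, 1:, :], DKxy) * (HX * HZ)
        couple(g, IDX[:, :-1, :], IDX[:, 1:, :],
               (slice(None), slice(None, -1)), (slice(None), slice(1, None)))
    g = _harm(HZ[:-1], DKz[:-1], HZ[1:], DKz[1:]) * (HX * HY)
    couple(g, IDX[:-1], IDX[1:], (slice(None, -1),), (slice(1, None),))

    b = np.zeros((nz, ny, nx))
    n_fp = mesh.n_fp
    gtop = None
    if psi_top is not None:
        area_fp = hx[None, :n_fp] * (hy[:n_fp, None] if ny > 1 else hy[:, None])
        gtop = (2 * float(DKz[0, 0, 0]) / hz[0]) * area_fp
        jsl = slice(None, n_fp) if ny > 1 else slice(None)
        diag[0, jsl, :n_fp] -= gtop
        b[0, jsl, :n_fp] -= gtop * psi_top
    area_all = hx[None, :] * hy[:, None]
    gbot = (2 * float(DKz[-1, 0, 0]) / hz[-1]) * area_all
    diag[-1] -= gbot
    rows.append(np.arange(N))
    cols.append(np.arange(N))
    vals.append(diag.ravel())
    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return A, b.ravel(), gtop, gbot


@dataclass(frozen=True)
class SteadyFootprintResult:
    """Steady infinite-reservoir solution on the quarter domain."""

    mesh: MeshMultiD
    psi: np.ndarray  # (nz, ny, nx)
    g_pt_rel: float  # released flux per footprint area, kg m^-2 s^-1
    flow_per_reservoir: float  # whole-reservoir drug flow, kg s^-1
    flux_balance: float  # |in - out| / in across top/bottom

    @property
    def g_pt_rel_ug_cm2_h(self) -> float:
        return self.g_pt_rel * FLUX_SI_TO_UG_PER_CM2_H


def solve_steady_footprint(
    config: ScenarioConfig, refinement: int = 0, two_d: bool = False
) -> SteadyFootprintResult:
    """Steady released flux for a constant-potential reservoir footprint.

    The reservoir is replaced by a Dirichlet patch psi = c_ini/K_pt on the
    skin surface under the footprint; the reported flux is the
    whole-reservoir flow divided by the footprint area (quarter-domain flow
    and area scale identically).
    """
    mesh = build_mesh_multi_d(config, refinement=refinement, two_d=two_d)
    psi_top = config.surface_potential
    A, b, gtop, gbot = _assemble(mesh, psi_top)
    psi = spla.spsolve(A, b).reshape(mesh.shape)
    n_fp = mesh.n_fp
    jsl = slice(None, n_fp) if not mesh.two_d else slice(None)
    flow_top = float((gtop * (psi_top - psi[0, jsl, :n_fp])).sum())
    flow_bot = float((gbot * psi[-1]).sum())
    L_half = config.reservoir.width / 2.0
    area_quarter = L_half**2 if not mesh.two_d else L_half * mesh.hy[0]
    g = flow_top / area_quarter
    flow_full = flow_top * (4.0 if not mesh.two_d else 2.0)
    return SteadyFootprintResult(
        mesh=mesh,
        psi=psi,
        g_pt_rel=g,
        flow_per_reservoir=flow_full,
        flux_balance=abs(flow_top - flow_bot) / flow_top,
    )


def solve_transient_footprint(
    config: ScenarioConfig,
    refinement: int = 0,
    two_d: bool = False,
    n_steps: int = 240,
    dt_min: float = 1.0,
):
    """Transient finite-reservoir release for a meshed micro-reservoir.

    The patch is retained as an explicit layer above the footprint
    (zero-flux top). Implicit-Euler steps on a geometric time grid capture
    the fast depletion of small reservoirs; the operator is factorized once
    per distinct step size. Returns (t [s], g_pt_rel(t) [kg m^-2 s^-1],
    m_pt_res(t) [kg]).
    """
    if config.reservoir.regime != "finite":
        raise ValueError("transient footprint run requires the finite regime")
    mesh = build_mesh_multi_d(
        config, refinement=refinement, two_d=two_d, include_patch=True
    )
    nz, ny, nx = mesh.shape
    A, b, _, gbot = _assemble(mesh, None)
    # zero the operator rows coupling patch cells laterally outside footprint:
    # the patch exists only above the footprint. Build a mask and remove cells.
    patch_z = mesh.layer == list(mesh.labels).index("patch")
    keep = np.ones(mesh.shape, dtype=bool)
    n_fp = mesh.n_fp
    if not two_d:
        keep[patch_z, :, n_fp:] = False
        keep[patch_z, n_fp:, :] = False
    else:
        keep[patch_z, :, n_fp:] = False
    keep_flat = keep.ravel()
    idx_map = -np.ones(mesh.n_cells, dtype=int)
    idx_map[keep_flat] = np.arange(keep_flat.sum())
    A = A.tocsr()
    # dropping a neighbor must turn that face into a zero-flux wall: add the
    # conductance to the removed cell back onto the diagonal, otherwise the
    # cut rows behave as if facing a zero-potential sink
    leak = np.asarray(A[keep_flat][:, ~keep_flat].sum(axis=1)).ravel()
    A = A[keep_flat][:, keep_flat].tocsc() + sp.diags(leak)
    hx, hy, hz = mesh.hx, mesh.hy, mesh.hz
    vol = (hz[:, None, None] * hy[None, :, None] * hx[None, None, :])
    M = (vol * mesh.K[:, None, None]).ravel()[keep_flat]
    psi = np.where(patch_z[:, None, None] & keep, config.surface_potential, 0.0).ravel()[keep_flat]

    horizon = config.horizon_h * S_PER_H
    # geometric time grid from dt_min up to the output cadence cap
    t = [0.0]
    dt = dt_min
    while t[-1] < horizon:
        t.append(min(t[-1] + dt, horizon))
        dt = min(dt * 1.2, config.max_time_step_s)
    t = np.asarray(t)
    patch_cells = (patch_z[:, None, None] & keep).ravel()[keep_flat]
    m_res = [float((M * psi)[patch_cells].sum()) * 4.0]
    g_rel = []
    # release flux: flow across the patch/sc z-interface
    k_if = int(np.sum(patch_z))  # first skin z-index
    g_if = _harm(hz[k_if - 1], mesh.D_z[k_if - 1] * mesh.K[k_if - 1],
                 hz[k_if], mesh.D_z[k_if] * mesh.K[k_if])
    area_fp = hx[None, :n_fp] * (hy[:n_fp, None] if not two_d else hy[:, None])
    IDX = np.arange(mesh.n_cells).reshape(mesh.shape)
    jsl = slice(None, n_fp) if not two_d else slice(None)
    up_idx = idx_map[IDX[k_if - 1, jsl, :n_fp].ravel()]
    lo_idx = idx_map[IDX[k_if, jsl, :n_fp].ravel()]

    def release_flow(psi_v):
        return float((g_if * area_fp.ravel() * (psi_v[up_idx] - psi_v[lo_idx])).sum())

    g_rel.append(release_flow(psi) / (config.reservoir.width / 2.0) ** 2 / (1 if not two_d else 1))

    Mdiag = sp.diags(M)
    lu = None
    last_dt = None
    for k in range(1, len(t)):
        dtk = t[k] - t[k - 1]
        if lu is None or abs(dtk - last_dt) > 1e-12:
            lu = spla.splu((Mdiag / dtk - A).tocsc())
            last_dt = dtk
        psi = lu.solve(M * psi / dtk)
        m_res.append(float((M * psi)[patch_cells].sum()) * 4.0)
        g_rel.append(release_flow(psi) / (config.reservoir.width / 2.0) ** 2)
    return t, np.asarray(g_rel), np.asarray(m_res)


def sweep_reservoir_sizes(
    sizes,
    regime: str = "infinite",
    refinement: int = 0,
    d_ep: float = 85e-6,
    convergence_levels: Optional[tuple] = None,
) -> pd.DataFrame:
    """Released flux vs reservoir width for the miniaturization study.

    One row per size with the dimensionless width L_pt/d_ep, the steady
    per-area flux (infinite regime), and the enhancement factor relative to
    the wide-reservoir unidirectional limit. ``convergence_levels`` records
    the flux at additional refinement levels (mesh-convergence log columns).
    """
    sizes = list(sizes)
    if any(s <= 0 for s in sizes) or sorted(sizes) != sizes and sorted(sizes, reverse=True) != sizes:
        raise ValueError("sizes must be positive and sorted")
    cfg0 = preset("reservoir_sweep", L_pt=max(sizes), regime="infinite")
    g_1d = series_resistance_flux(cfg0.stack, cfg0.surface_potential)
    rows = []
    for L in sizes:
        cfg = preset("reservoir_sweep", L_pt=L, regime=regime)
        if regime == "infinite":
            res = solve_steady_footprint(cfg, refinement=refinement)
            g = res.g_pt_rel
            row = {
                "L_pt_m": L,
                "L_over_d_ep": L / d_ep,
                "g_pt_rel_ug_cm2_h": g * FLUX_SI_TO_UG_PER_CM2_H,
                "enhancement": g / g_1d,
                "flux_balance": res.flux_balance,
                "flow_per_reservoir_ug_h": res.flow_per_reservoir * 3.6e12,
            }
            if convergence_levels:
                for lv in convergence_levels:
                    r2 = solve_steady_footprint(cfg, refinement=lv)
                    row[f"g_ref{lv}_ug_cm2_h"] = r2.g_pt_rel * FLUX_SI_TO_UG_PER_CM2_H
                row["mesh_convergence"] = abs(
                    row[f"g_ref{max(convergence_levels)}_ug_cm2_h"]
                    / row["g_pt_rel_ug_cm2_h"]
                    - 1.0
                )
        else:
            t, g_rel, m_res = solve_transient_footprint(cfg, refinement=refinement)
            row = {
                "L_pt_m": L,
                "L_over_d_ep": L / d_ep,
                "g_peak_ug_cm2_h": float(g_rel.max()) * FLUX_SI_TO_UG_PER_CM2_H,
                "g_72h_ug_cm2_h": float(np.interp(72 * S_PER_H, t, g_rel))
                * FLUX_SI_TO_UG_PER_CM2_H,
                "depletion_half_time_h": float(
                    np.interp(0.5 * m_res[0], m_res[::-1], t[::-1] / S_PER_H)
                ),
            }
        rows.append(row)
    return pd.DataFrame(rows)


def reservoir_count_for_flow(
    L_pt: float,
    target_flow_ug_h: float,
    patch_area_cm2: float = 16.0,
    flow_per_reservoir_ug_h: Optional[float] = None,
    refinement: int = 0,
):
    """Number of micro-reservoirs of side ``L_pt`` needed to match a target
    whole-patch drug flow, and the fraction of patch area they occupy."""
    if flow_per_reservoir_ug_h is None:
        cfg = preset("reservoir_sweep", L_pt=L_pt, regime="infinite")
        flow_per_reservoir_ug_h = (
            solve_steady_footprint(cfg, refinement=refinement).flow_per_reservoir
            * 3.6e12
        )
    if flow_per_reservoir_ug_h <= 0:
        raise ValueError("per-reservoir flow must be positive")
    count = ceil(target_flow_ug_h / flow_per_reservoir_ug_h)
    area_fraction = count * (L_pt * 100) ** 2 / patch_area_cm2
    return count, area_fraction
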