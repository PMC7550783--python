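"""Local (central-difference) relative sensitivity of outputs to parameters.

For an output quantity U(t) and a parameter X, the relative sensitivity is

    S_U,X(t) = | (U(X+dX; t) - U(X-dX; t)) / (2 dX/X) / U(t) |

with dX/X = 1% by default, i.e. the absolute value of the central-difference
elasticity normalized by the nominal solution. Geometry parameters re-mesh
the perturbed domain (the boundary moves; coordinates are not rescaled).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .domain_model import ScenarioConfig, with_replaced_layer
from .solver_1d import simulate

__all__ = ["PARAMETERS", "perturb", "sensitivity_scan"]

#: supported parameter names -> (layer label, field) or special handling
PARAMETERS = (
    "d_sc",
    "d_vep",
    "D_sc_z",
    "D_vep",
    "K_pt_sc",
    "c_ini",
    "d_pt",
    "D_pt",
)


def perturb(config: ScenarioConfig, parameter: str, factor: float) -> ScenarioConfig:
    """Return a config with one scalar parameter scaled by ``factor``.

    ``K_pt_sc`` (the patch/stratum-corneum partition coefficient) is realized
    by scaling K_sc by 1/factor with K_pt fixed at 1, since K_pt/sc = 1/K_sc.
    """
    sc = "stratum_corneum" if "stratum_corneum" in [m.label for m in config.stack.layers] else "lumped_epidermis"
    if parameter == "d_sc":
        d = config.stack.get(sc).thickness
        return with_replaced_layer(config, sc, thickness=d * factor)
    if parameter == "d_vep":
        d = config.stack.get("viable_epidermis").thickness
        return with_replaced_layer(config, "viable_epidermis", thickness=d * factor)
    if parameter == "D_sc_z":
        m = config.stack.get(sc)
        return with_replaced_layer(config, sc, D_z=m.D_z * factor)
    if parameter == "D_vep":
        m = config.stack.get("viable_epidermis")
        return with_replaced_layer(
            config, "viable_epidermis", D_z=m.D_z * factor, D_xy=m.D_xy * factor
        )
    if parameter == "K_pt_sc":
        m = config.stack.get(sc)
        return with_replaced_layer(config, sc, K=m.K / factor)
    if parameter == "c_ini":
        res = replace(
            config.reservoir,
            initial_concentration=config.reservoir.initial_concentration * factor,
        )
        return replace(config, reservoir=res)
    if parameter == "d_pt":
        m = config.stack.get("patch")
        res = replace(config.reservoir, thickness=config.reservoir.thickness * factor)
        cfg = with_replaced_layer(config, "patch", thickness=m.thickness * factor)
        return replace(cfg, reservoir=res)
    if parameter == "D_pt":
        m = config.stack.get("patch")
        return with_replaced_layer(config, "patch", D_z=m.D_z * factor, D_xy=m.D_xy * factor)
    raise ValueError(f"unknown parameter {parameter!r}")


def _extract(result, output: str, times_h: Sequence[float]) -> np.ndarray:
    if output == "g_bl_up":
        series = result.g_bl_up
    elif output == "m_bl_up":
        series = result.m_bl_up
    else:
        raise ValueError(f"unknown output {output!r}")
    return np.array([result.at_time(t, series) for t in times_h])


def sensitivity_scan(
    config: ScenarioConfig,
    parameters: Iterable[str] = ("d_sc", "d_vep", "D_sc_z", "D_vep", "K_pt_sc", "c_ini"),
    outputs: Iterable[str] = ("g_bl_up", "m_bl_up"),
    times_h: Sequence[float] = (12.0, 24.0, 48.0, 72.0),
    delta: float = 0.01,
) -> pd.DataFrame:
    """Central-difference sensitivity table.

    Two full simulations per parameter (at X(1±delta)) around one shared
    nominal run; S is reported per parameter, output and time. Where the
    nominal U(t) is zero, S is undefined and reported as NaN.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be a fraction in (0, 1)")
    horizon = max(times_h) * 1.05
    cfg = replace(config, horizon_h=min(config.horizon_h, horizon))
    nominal = simulate(cfg)
    rows = []
    for p in parameters:
        hi = simulate(perturb(cfg, p, 1.0 + delta))
        lo = simulate(perturb(cfg, p, 1.0 - delta))
        for out in outputs:
            u0 = _extract(nominal, out, times_h)
            up = _extract(hi, out, times_h)
            um = _extract(lo, out, times_h)
            with np.errstate(divide="ignore", invalid="ignore"):
                S = np.abs((up - um) / (2.0 * delta) / np.where(u0 != 0, u0, np.nan))
            for t, s in zip(times_h, S):
                rows.append(
                    {"parameter": p, "output": out, "time_h": t, "S": float(s)}
                )
    return pd.DataFrame(rows)
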