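"""End-to-end study designs: body-site and age variability, infinite vs
finite reservoirs, patch removal, reservoir miniaturization, and the
benchmark against commercial patch specifications.

All patient-variability studies run the unidirectional (1D) model; the
reservoir study delegates to the multi-dimensional solver. Every study is
fully deterministic — no random numbers anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .domain_model import ScenarioConfig, preset
from .metrics import ReleaseSummary, release_summary
from .solver_1d import simulate, steady_infinite_flux
from .solver_multi_d import sweep_reservoir_sizes
from .units import FLUX_SI_TO_UG_PER_CM2_H, KG_TO_MG

__all__ = [
    "StudyReport",
    "COMMERCIAL_PATCHES",
    "run_body_site_study",
    "run_age_study",
    "run_reservoir_study",
    "run_benchmark_comparison",
    "run_regime_study",
]

#: labeled delivery rates of commercial fentanyl systems:
#: product -> (delivery rate range ug/h, active area range cm2, flux ug/cm2/h)
COMMERCIAL_PATCHES = {
    "Durogesic": {"rate_ug_h": (12, 100), "area_cm2": (5.3, 42), "flux_ug_cm2_h": (2.3, 2.4)},
    "Matrifen": {"rate_ug_h": (12, 100), "area_cm2": (4.2, 33.6), "flux_ug_cm2_h": (2.9, 3.0)},
    "Fentalis": {"rate_ug_h": (25, 100), "area_cm2": (10, 40), "flux_ug_cm2_h": (2.5, 2.5)},
    "Fentadolon": {"rate_ug_h": (25, 25), "area_cm2": (15, 15), "flux_ug_cm2_h": (1.7, 1.7)},
}


@dataclass
class StudyReport:
    """Results of one named study: per-scenario summaries plus derived
    contrasts. Percent differences are 100*(a-b)/b with b the named
    reference scenario."""

    study_id: str
    summaries: Dict[str, ReleaseSummary]
    contrasts: Dict[str, float]
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "summaries": {k: v.to_dict() for k, v in self.summaries.items()},
            "contrasts": self.contrasts,
        }


def _uptake_72h_mg(result) -> float:
    return result.at_time(72.0, result.m_bl_up) * KG_TO_MG


def run_body_site_study(horizon_h: float = 240.0) -> StudyReport:
    """Anatomical-location panel: forearm, shoulder, buttock and all-sites
    thicknesses at the mean and at ±2 standard deviations (both sublayers
    perturbed jointly).

    Contrasts: shoulder-vs-forearm uptake at 72 h (reference forearm) and
    the ±2σ uptake range of each site relative to its mean run.
    """
    sites = ("forearm_dorsal", "shoulder", "buttock", "all_sites")
    quantiles = ("mean", "minus2sd", "plus2sd")
    summaries, rows = {}, []
    uptake = {}
    for site in sites:
        for q in quantiles:
            cfg = preset("body_site", site=site, quantile=q)
            cfg = ScenarioConfig(**{**cfg.__dict__, "horizon_h": horizon_h})
            res = simulate(cfg)
            label = f"{site}_{q}"
            summaries[label] = release_summary(res)
            uptake[label] = _uptake_72h_mg(res)
            rows.append(
                {
                    "site": site,
                    "quantile": q,
                    "d_sc_um": cfg.stack.get("stratum_corneum").thickness * 1e6,
                    "d_vep_um": cfg.stack.get("viable_epidermis").thickness * 1e6,
                    "m_bl_up_72h_mg": uptake[label],
                    "hut_h": summaries[label].hut_h,
                }
            )
    contrasts = {
        "shoulder_vs_forearm_72h_pct": 100.0
        * (uptake["shoulder_mean"] - uptake["forearm_dorsal_mean"])
        / uptake["forearm_dorsal_mean"],
        "buttock_vs_forearm_72h_pct": 100.0
        * (uptake["buttock_mean"] - uptake["forearm_dorsal_mean"])
        / uptake["forearm_dorsal_mean"],
    }
    for site in sites:
        contrasts[f"{site}_2sd_range_pct_of_mean"] = (
            100.0
            * (uptake[f"{site}_minus2sd"] - uptake[f"{site}_plus2sd"])
            / uptake[f"{site}_mean"]
        )
    return StudyReport("body_site", summaries, contrasts, pd.DataFrame(rows))


def run_age_study(ages: Iterable[float] = (18.0, 30.0, 40.0, 55.0, 70.0),
                  horizon_h: float = 240.0) -> StudyReport:
    """Age panel: stratum-corneum thickness from the age correlation with
    all other base-case properties fixed.

    Contrasts: uptake reduction of the oldest vs youngest age at 72 h
    (reference = youngest) and the time to take up 0.5 mg per age.
    """
    ages = sorted(ages)
    summaries, rows, uptake, t_half_mg = {}, [], {}, {}
    for a in ages:
        cfg = preset("age", years=a)
        cfg = ScenarioConfig(**{**cfg.__dict__, "horizon_h": horizon_h})
        res = simulate(cfg)
        label = f"age_{a:g}"
        summaries[label] = release_summary(res)
        uptake[label] = _uptake_72h_mg(res)
        m_mg = res.m_bl_up * KG_TO_MG
        t_half_mg[label] = (
            float(np.interp(0.5, m_mg, res.t_h)) if m_mg[-1] >= 0.5 else None
        )
        rows.append(
            {
                "age_y": a,
                "d_sc_um": cfg.stack.get("stratum_corneum").thickness * 1e6,
                "m_bl_up_72h_mg": uptake[label],
                "time_to_0p5mg_h": t_half_mg[label],
                "hut_h": summaries[label].hut_h,
            }
        )
    young, old = f"age_{ages[0]:g}", f"age_{ages[-1]:g}"
    contrasts = {
        "oldest_vs_youngest_72h_pct": 100.0
        * (uptake[young] - uptake[old])
        / uptake[young],
        f"time_to_0p5mg_{ages[0]:g}y_h": t_half_mg[young],
        f"time_to_0p5mg_{ages[-1]:g}y_h": t_half_mg[old],
    }
    return StudyReport("age", summaries, contrasts, pd.DataFrame(rows))


def run_regime_study(horizon_h: float = 240.0) -> StudyReport:
    """Finite base case vs infinite reservoir vs removal after 72 h."""
    fin = simulate(preset("base_case"))
    inf_cfg = preset("infinite")
    inf = simulate(inf_cfg)
    rem = simulate(preset("removal_72h"))
    m_fin = _uptake_72h_mg(fin)
    m_inf = _uptake_72h_mg(inf)
    summaries = {
        "base_case": release_summary(fin),
        "removal_72h": release_summary(rem),
    }
    g_steady = steady_infinite_flux(inf_cfg)
    contrasts = {
        "infinite_vs_finite_72h_pct": 100.0 * (m_inf - m_fin) / m_fin,
        "infinite_steady_flux_ug_cm2_h": g_steady * FLUX_SI_TO_UG_PER_CM2_H,
        "flux_72h_fraction_of_peak": float(
            fin.at_time(72.0, fin.g_bl_up) / fin.g_bl_up.max()
        ),
        "removal_residual_uptake_mg": (rem.m_bl_up[-1] - rem.at_time(72.0, rem.m_bl_up))
        * KG_TO_MG,
    }
    table = pd.DataFrame(
        {
            "time_h": fin.t_h,
            "m_bl_up_finite_mg": fin.m_bl_up * KG_TO_MG,
            "m_bl_up_infinite_mg": np.interp(fin.t, inf.t, inf.m_bl_up) * KG_TO_MG,
        }
    )
    return StudyReport("regimes", summaries, contrasts, table)


def run_reservoir_study(
    sizes=(40e-3, 4e-3, 400e-6, 40e-6, 4e-6),
    regime: str = "infinite",
    refinement: int = 0,
    convergence_levels: Optional[tuple] = (1,),
) -> StudyReport:
    """Reservoir miniaturization sweep (multi-dimensional solver) with the
    dimensionless width L_pt/d_ep (d_ep = 85 µm) and enhancement factors."""
    table = sweep_reservoir_sizes(
        sorted(sizes, reverse=True),
        regime=regime,
        refinement=refinement,
        convergence_levels=convergence_levels if regime == "infinite" else None,
    )
    contrasts = {}
    if regime == "infinite":
        for _, row in table.iterrows():
            contrasts[f"enhancement_L{row.L_pt_m*1e6:g}um"] = float(row.enhancement)
    return StudyReport(f"reservoir_{regime}", {}, contrasts, table)


def run_benchmark_comparison() -> StudyReport:
    """Base-case uptake flow tabulated against commercial patch labels, with
    the infinite-reservoir steady flux alongside."""
    res = simulate(preset("base_case"))
    summ = release_summary(res)
    g_steady = steady_infinite_flux(preset("infinite"))
    rows = [
        {
            "product": name,
            "rate_ug_h_low": spec["rate_ug_h"][0],
            "rate_ug_h_high": spec["rate_ug_h"][1],
            "flux_ug_cm2_h_low": spec["flux_ug_cm2_h"][0],
            "flux_ug_cm2_h_high": spec["flux_ug_cm2_h"][1],
        }
        for name, spec in COMMERCIAL_PATCHES.items()
    ]
    contrasts = {
        "peak_G_bl_up_ug_h": summ.peak_G_bl_up_ug_h,
        "peak_time_h": summ.peak_time_h,
        "G_bl_up_72h_ug_h": summ.G_bl_up_72h_ug_h,
        "infinite_steady_flux_ug_cm2_h": g_steady * FLUX_SI_TO_UG_PER_CM2_H,
        "commercial_flux_band_ug_cm2_h_low": 1.7,
        "commercial_flux_band_ug_cm2_h_high": 3.0,
    }
    return StudyReport("benchmark", {"base_case": summ}, contrasts, pd.DataFrame(rows))
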