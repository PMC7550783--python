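"""Reservoir regimes: depleting patch vs constant-concentration reservoir,
and what happens after the patch is peeled off at 72 h.

The infinite regime holds the skin surface at the initial potential and
settles to a constant flux; the finite patch depletes and its flux decays.
After removal the epidermal depot keeps feeding the blood for hours.
"""

from dermadiff import preset, simulate, steady_infinite_flux
from dermadiff.units import FLUX_SI_TO_UG_PER_CM2_H, KG_TO_MG

finite = simulate(preset("base_case"))
infinite = simulate(preset("infinite"))
removal = simulate(preset("removal_72h"))

g_ss = steady_infinite_flux(preset("infinite")) * FLUX_SI_TO_UG_PER_CM2_H
m_fin = finite.at_time(72.0, finite.m_bl_up) * KG_TO_MG
m_inf = infinite.at_time(72.0, infinite.m_bl_up) * KG_TO_MG

print(f"steady infinite-reservoir flux   {g_ss:.3f} ug/cm^2/h")
print(f"uptake at 72 h, finite           {m_fin:.3f} mg")
print(f"uptake at 72 h, infinite         {m_inf:.3f} mg  (+{100*(m_inf-m_fin)/m_fin:.1f} %)")

m_at_removal = removal.at_time(72.0, removal.m_bl_up) * KG_TO_MG
m_final = removal.m_bl_up[-1] * KG_TO_MG
print(f"patch removed at 72 h: a further {m_final - m_at_removal:.3f} mg "
      "reaches the blood from the epidermal depot")
print(f"booked out with the patch        {removal.removed_with_patch * KG_TO_MG:.3f} mg")
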