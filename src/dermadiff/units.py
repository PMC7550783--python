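"""Unit conversion constants.

All internal computation is SI (kg, m, s). Reported quantities use the
conventional pharmaceutics units: mg for masses, µg h⁻¹ for drug flows,
µg cm⁻² h⁻¹ for fluxes, hours for times. Conversions are exact.
"""

#: seconds per hour
S_PER_H = 3600.0

#: kg -> mg
KG_TO_MG = 1e6

#: kg -> µg
KG_TO_UG = 1e9

#: kg s⁻¹ -> µg h⁻¹  (1e9 µg/kg × 3600 s/h)
FLOW_SI_TO_UG_PER_H = KG_TO_UG * S_PER_H

#: kg m⁻² s⁻¹ -> µg cm⁻² h⁻¹  (1e9 µg/kg × 3600 s/h ÷ 1e4 cm²/m²)
FLUX_SI_TO_UG_PER_CM2_H = KG_TO_UG * S_PER_H / 1e4

#: m -> µm
M_TO_UM = 1e6

#: m² -> cm²
M2_TO_CM2 = 1e4
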