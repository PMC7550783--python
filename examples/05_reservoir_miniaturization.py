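"""Shrinking the reservoir: edge-driven flux enhancement.

When the contact footprint of a constant-concentration reservoir shrinks
toward the epidermis thickness (85 um), drug spreads laterally under the
edge and the per-area steady flux rises steeply. The sweep reports the
enhancement over the wide-patch unidirectional limit and how many
micro-reservoirs would be needed to match a 100 ug/h delivery target.

Runs the 3D steady solver; the two smallest sizes take a couple of minutes.
"""

from dermadiff.solver_multi_d import reservoir_count_for_flow, sweep_reservoir_sizes

table = sweep_reservoir_sizes((40e-3, 4e-3, 400e-6, 40e-6), regime="infinite")
print(table[["L_pt_m", "L_over_d_ep", "g_pt_rel_ug_cm2_h", "enhancement"]]
      .to_string(index=False))

count, frac = reservoir_count_for_flow(40e-6, target_flow_ug_h=100.0)
print(f"\n{count} reservoirs of 40 um side deliver 100 ug/h "
      f"using {100*frac:.2f} % of a 16 cm^2 patch area")
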