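"""Two-step FBA (maximise CA, then minimise the Manhattan norm) and the
shadow-price reading of which metabolites limit production.

Shadow prices are the duals of the metabolite balances: negative values
mark metabolites limiting the objective, positive values metabolites in
surplus, zero insensitivity.
"""

from redgem import classify_shadow_prices, fba, generate_toy_network, two_step_fba

model, truth = generate_toy_network()

# state: growth pinned at 30% of its maximum, succinate export capped —
# the disposal of the clavam by-product becomes the bottleneck
state = model.copy()
mu_max = fba(model, "BIOMASS").objective_value
growth = state.reaction("BIOMASS")
growth.lower_bound = growth.upper_bound = 0.3 * mu_max
state.reaction("EX_succ").upper_bound = 1.0

sol = two_step_fba(state)
print(f"CA flux: {sol.objective_value:.4f} mmol/gDCW/h "
      f"(L1 norm of fluxes: {sol.sum_abs_flux:.2f})")
classes = classify_shadow_prices(sol)
for met in ("glyc_e", "succ_c", "ca_c", "akg_c"):
    print(f"  {met}: shadow price {sol.shadow_prices[met]:+.3f} -> "
          f"{classes[met]}")
# succ_c comes out 'surplus' (positive): absorbing the succinate by-product
# internally would raise CA production — the export cap is the bottleneck.
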