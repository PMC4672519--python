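"""FBA, parsimonious FBA, and FVA on a packaged member model.

Loads the streptococcal fixture model, applies the milk medium, and shows the
three solver entry points.
"""

from lactoflux import (
    build_system,
    fixture_path,
    fva,
    read_medium,
    read_model,
    solve_fba,
    solve_pfba,
)

model = read_model(fixture_path("ST.json"))
milk = read_medium(fixture_path("milk.tsv"))
system = build_system(model, milk)

fba = solve_fba(system)
print(f"FBA growth rate: {fba.objective_value:.4f} h^-1")
# maximum biomass flux given milk uptake bounds (lactose is limiting)

pfba = solve_pfba(system)
total = sum(abs(v) for v in pfba.fluxes.values())
print(f"pFBA keeps growth at {pfba.objective_value:.4f} with total |flux| "
      f"{total:.1f}")
# the canonical, minimal-total-flux distribution among near-optimal solutions

ranges = fva(system, ["LACt", "GALts", "SUCCts"], fraction_of_optimum=1.0)
for rid, (lo, hi) in ranges.items():
    print(f"FVA {rid}: [{lo:.3f}, {hi:.3f}]")
# fully-determined reactions have lo == hi: at optimum the model must import
# lactose and must release galactose and succinate
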