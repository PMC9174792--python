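"""Elemental C/N budget and recipe of the packaged NLDM definition.

Loads the 64-metabolite defined medium, prints the per-tier organic carbon
and nitrogen budget (mg/L, rounded as in a bench report), the C:N ratio
under both conventions, and the first weigh-out lines of the recipe.
"""

from exomedium import cn_ratio, load_fixture, recipe, stoichiometry_table

medium = load_fixture("nldm_medium")

print("Per-tier organic C and N budget (mg/L, integer-rounded):")
print(stoichiometry_table(medium, rounded=True).to_string())
# Each tier is equimolar; the totals row is rounded from full precision,
# which is why it can exceed the sum of the rounded tier rows by 1.

print()
print(f"C:N (molar, organic only):        {cn_ratio(medium):.2f}")
print(
    "C:N (molar, + 1 mM ammonium N):   "
    f"{cn_ratio(medium, include_inorganic_n=True):.2f}  <- rounds to the design target 9:1"
)

r = recipe(medium)
print()
print("First five weigh-out lines (mg per litre of medium):")
print(r[r.kind == "metabolite"].head(5).to_string(index=False))
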