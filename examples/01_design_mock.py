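"""Design a 16S-copy-balanced mock community.

Equal DNA masses would over-represent small genomes with many 16S
copies, so each member's mass is chosen to contribute the same number
of 16S gene copies to the stock.
"""

from mockamp import design_equal_mock, packaged_members, recipe_frame

members = packaged_members()
recipe = design_equal_mock(members, target_total_16s_copies=2e9)
frame = recipe_frame(recipe)

print(frame[["name", "genome_size_bp", "n_16s_copies", "copies_per_ug", "mass_ug"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(f"each of the {len(members)} members contributes "
      f"{recipe.per_member_target_copies:.3g} copies "
      f"({100 / len(members):.0f}% of the {recipe.target_total_16s_copies:.3g}-copy stock)")
print("mass_ug is the micrograms of that member's genomic DNA to pipette;")
print("members with large genomes or many 16S copies need less/more mass accordingly.")
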