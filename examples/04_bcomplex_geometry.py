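"""B-complex span arithmetic and splicing-construct distances.

Inside the pre-catalytic spliceosome the 5'SS pairs with U6 in a 17-nt
helix and the branch-site region with U2 in a 14-nt helix; the helices sit
~15 nm apart, which fully extended RNA covers in ~21 nt. An intron therefore
needs ~52 nt between its 5'SS and branch site to span both helices and the
gap without deforming the complex. Truncation constructs shorten an intron
only between the 5'SS and the BS, conserving the BS-to-3'SS block.
"""
from juncture import GeometryModel, construct_distance, extended_span_nt, min_span_nt

model = GeometryModel()
print(f"5'SS/U6 helix: {model.helix_5ss_nt} nt")
print(f"BS/U2 helix:   {model.helix_bs_nt} nt")
print(f"inter-helix gap: {model.gap_nm} nm "
      f"= {extended_span_nt(model)} nt extended RNA")
print(f"minimum 5'SS-BS span: {min_span_nt(model)} nt\n")

print("120-nt reference intron, 96-nt 5'SS-BS distance; truncation series:")
for new_len in (150, 120, 90, 80, 70):
    d = construct_distance(120, 96, new_len)
    marker = "  <- at/below the structural minimum" if d <= 56 else ""
    print(f"  {new_len:>3}-nt intron -> 5'SS-BS distance {d:>3} nt{marker}")

print("\n211-nt intron with 151-nt distance, shortened to 116 nt:")
print(f"  -> 5'SS-BS distance {construct_distance(211, 151, 116)} nt "
      "(same as the 80-nt construct above)")
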