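"""Diffusion sensing as an evolutionary spandrel.

Takes three strains evolved purely for density sensing (clonal,
intermediate-relatedness and low-relatedness backgrounds), fixes the cell
density at a quorate level, and sweeps the mass-transfer loss rate m.
Each strain switches cooperation OFF above a critical m* — a
diffusion-sensing capability none of them was selected for.
"""

from quorumevo.experiments import spandrel_profiles

table = spandrel_profiles()
print("strain              p (uM/s)    S_Th (uM)   m* (uL/s)")
for _, row in table.iterrows():
    print(f"{row['strain']:18s}  {row['p']:.2e}   {row['S_Th']:7.2f}   {row['m_star']:.3g}")

print("\nclonal and intermediate strains evolved different signal/response "
      "pairs along the same constraint line, so they share a near-identical "
      "mass-transfer threshold; the low-relatedness strain's inflated "
      "response threshold makes it far more sensitive to signal loss")
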