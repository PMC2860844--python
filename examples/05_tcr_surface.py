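"""TCR-face topology and electrostatic comparison of two complexes.

Maps the solvent-accessible surface facing up out of the cleft, with the
Coulomb potential of coarse formal charges (clipped to +/-10 kT/e), and
compares a glutamate-containing peptide against its isosteric glutamine
variant: same shape, different charge.
"""

from pmhcforge import PMHCComplex, compare_surfaces, surface_potential, thread_sequence
from pmhcforge.fixtures import FixtureSpec, make_toy_cleft

glu = make_toy_cleft(FixtureSpec(seed=0, peptide_seq="AAAEAAAAA"))
gln = PMHCComplex(glu.mhc.copy(), thread_sequence("AAAQAAAAA", glu))

map_glu = surface_potential(glu)
map_gln = surface_potential(gln)

print(f"E-peptide map: {len(map_glu.points)} surface points, potential range "
      f"[{map_glu.values.min():.2f}, {map_glu.values.max():.2f}] kT/e")
print(f"Q-peptide map: {len(map_gln.points)} surface points, potential range "
      f"[{map_gln.values.min():.2f}, {map_gln.values.max():.2f}] kT/e")

topo, pot, frac = compare_surfaces(map_glu, map_gln)
print(f"topology RMS {topo:.2f} A, potential RMS {pot:.2f} kT/e, "
      f"matched fraction {frac:.2f}")

# The E->Q exchange barely changes the surface shape (low topology RMS) but
# removes a negative patch (nonzero potential RMS) - the kind of contrast
# used to rank cross-reactivity candidates.
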