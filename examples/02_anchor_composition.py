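"""Anchor-position composition of the curated H-2Db ligand set.

Loads the packaged table of H-2Db peptide ligands (28 distinct epitopes)
and tabulates residue usage at the p5 anchor and at the C terminus.
"""

from pmhcforge import composition_at, h2db_ligands

records = h2db_ligands(distinct_only=True)
print(f"{len(records)} distinct H-2Db epitopes "
      f"(lengths {sorted({r.length for r in records})})")

seqs = [(r.pdb_code, r.sequence) for r in records]

p5 = composition_at(seqs, 5)
print(f"p5 anchor: {p5.counts} -> classes {p5.class_counts}")
non_asn = sorted(code for code, seq in seqs if seq[4] != "N")
print(f"non-asparagine p5: {non_asn}")

cterm = composition_at(seqs, -1)
print(f"C-terminal anchor: {cterm.counts} -> classes {cterm.class_counts}")

# p5 is dominated by asparagine (the canonical H-2Db anchor) with three
# nonpolar exceptions; the C terminus is nonpolar except one cysteine.
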