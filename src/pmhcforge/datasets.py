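"""Packaged reference data: the curated H-2Db ligand set.

The table lists the peptide ligands of the murine MHC-I allele H-2Db with
crystal structures in the PDB, as curated for the allele-pattern analysis:
one row per PDB entry, with the bound peptide sequence, its length and a
flag marking the 28 distinct-epitope entries retained for structural and
sequence analyses (entries with duplicated epitopes or incomplete epitope
density are kept in the table but flagged 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = ["LigandRecord", "h2db_ligands"]


@dataclass(frozen=True)
class LigandRecord:
    pdb_code: str
    description: str
    sequence: str
    length: int
    distinct: bool


def h2db_ligands(distinct_only: bool = False) -> list[LigandRecord]:
    """The packaged H-2Db ligand table (28 distinct epitopes when filtered)."""
    text = resources.files("pmhcforge.data").joinpath("h2db_ligands.tsv").read_text()
    records = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        rec = LigandRecord(
            pdb_code=row["pdb_code"],
            description=row["description"],
            sequence=row["sequence"],
            length=int(row["length"]),
            distinct=row["distinct"] == "1",
        )
        if len(rec.sequence) != rec.length:
            raise ValueError(f"{rec.pdb_code}: sequence length mismatch")
        if distinct_only and not rec.distinct:
            continue
        records.append(rec)
    return records
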