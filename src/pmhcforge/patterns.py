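"""Allele-specific epitope backbone patterns and anchor-position analytics.

Peptides bound to the same MHC-I allele adopt a shared main-chain
conformation in the cleft.  This module formalizes that observation: a
:class:`BackbonePattern` holds, for one allele and one peptide length, the
per-position mean backbone (N/CA/C/O) coordinates over a set of complexes
fitted into a common receptor frame, together with the per-position RMS
dispersion.  New complexes can be scored against the pattern
(:func:`deviation_from_pattern`), with an exception flag for outliers such
as ligands that bind without the canonical anchor and bulge out of the
cleft.  Sequence-level anchor analysis (:func:`composition_at`), relative
side-chain burial (:func:`burial_profile`) and conserved cleft-residue
contact reports complete the picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PmhcError
from .geometry import bond_angle
from .structio import BACKBONE_ATOMS, PMHCComplex, Residue
from .superpose import apply_transform, kabsch

__all__ = [
    "BackbonePattern",
    "PatternDeviationReport",
    "CompositionTable",
    "ContactReport",
    "PHYSICOCHEMICAL_CLASSES",
    "AROMATIC",
    "classify_residue",
    "extract_pattern",
    "deviation_from_pattern",
    "composition_at",
    "burial_profile",
    "conserved_contact_report",
]

#: residue classes used in anchor-composition analysis (a partition)
PHYSICOCHEMICAL_CLASSES = {
    "nonpolar": set("AVLIMFWPG"),
    "polar": set("STNQYC"),
    "positive": set("KRH"),
    "negative": set("DE"),
}

#: aromatic overlay (reported alongside, not part of the partition)
AROMATIC = set("FYW")

#: default exception rule: overall backbone RMSD above this flags an outlier
EXCEPTION_RMSD = 2.0


def classify_residue(code1: str) -> str:
    for name, members in PHYSICOCHEMICAL_CLASSES.items():
        if code1 in members:
            return name
    return "other"


@dataclass
class BackbonePattern:
    """Mean backbone geometry and dispersion for one allele/length class."""

    allele: str
    length: int
    frame_id: str
    frame_ca: dict  # (seqnum, icode) -> coords of the frame receptor C-alpha
    mean_coords: np.ndarray  # (length, 4, 3): N/CA/C/O per position
    dispersion: np.ndarray  # (length,) RMS deviation per position
    member_mean_dev: np.ndarray  # (length,) mean member deviation per position
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise PmhcError("pattern must have at least one member")
        if np.any(self.dispersion < -1e-12):
            raise PmhcError("dispersion must be non-negative")


@dataclass
class PatternDeviationReport:
    complex_id: str
    overall_backbone_rmsd: float
    per_position: np.ndarray  # (length,)
    exception: bool
    worst_position: int  # 1-based


@dataclass
class CompositionTable:
    position: int
    counts: dict  # residue one-letter -> count
    class_counts: dict  # class name -> count
    aromatic_count: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ContactReport:
    complex_id: str
    residue: str | None  # three-letter code at the queried position, None if absent
    hbonds: list  # (peptide position, mhc atom, peptide atom, distance)
    warning: str | None = None


# ---------------------------------------------------------------------------
# pattern extraction


def _fit_to_frame(complex: PMHCComplex, frame_ca: dict) -> PMHCComplex:
    ca = complex.mhc_ca()
    common = [k for k in frame_ca if k in ca]
    if len(common) < 3:
        raise PmhcError("complex shares too few receptor C-alpha positions with the frame")
    fit = kabsch(np.array([frame_ca[k] for k in common]),
                 np.array([ca[k] for k in common]))
    return apply_transform(complex, fit)


def _backbone_array(complex: PMHCComplex) -> np.ndarray:
    rows = []
    for res in complex.peptide_residues:
        rows.append([res.get(n).pos for n in BACKBONE_ATOMS])
    return np.array(rows)  # (n, 4, 3)


def _complex_label(c: PMHCComplex) -> str:
    return str(c.provenance.get("source", c.mhc.id) or "complex")


def extract_pattern(complexes: list[PMHCComplex], allele: str = "unknown",
                    frame_index: int = 0):
    """Backbone pattern of a set of same-allele complexes.

    All members are fitted to the frame member's receptor by C-alpha; the
    per-position mean backbone and RMS dispersion are computed over members.
    Mixed-allele input is an error.  Mixed lengths are split into one
    pattern per length class (with a warning); a single class returns its
    :class:`BackbonePattern` directly, otherwise a dict length -> pattern.
    """
    if not complexes:
        raise PmhcError("need at least one complex")
    alleles = {c.provenance.get("allele") for c in complexes} - {None}
    if len(alleles) > 1:
        raise PmhcError(f"mixed alleles in pattern input: {sorted(alleles)}")
    if len(alleles) == 1:
        allele = next(iter(alleles))

    by_length: dict[int, list[PMHCComplex]] = {}
    for c in complexes:
        by_length.setdefault(len(c.peptide_residues), []).append(c)
    if len(by_length) > 1:
        warnings.warn(
            f"mixed peptide lengths {sorted(by_length)}; building one pattern per length",
            stacklevel=2,
        )

    patterns = {}
    for length, members in sorted(by_length.items()):
        frame = members[min(frame_index, len(members) - 1)]
        frame_ca = {k: v.copy() for k, v in frame.mhc_ca().items()}
        fitted = [_fit_to_frame(c, frame_ca) for c in members]
        stack = np.array([_backbone_array(c) for c in fitted])  # (m, n, 4, 3)
        mean = stack.mean(axis=0)
        dev = np.linalg.norm(stack - mean[None], axis=3)  # (m, n, 4)
        dispersion = np.sqrt(np.mean(dev**2, axis=(0, 2)))  # per position
        member_dev = np.sqrt(np.mean(dev**2, axis=2))  # (m, n)
        patterns[length] = BackbonePattern(
            allele=allele,
            length=length,
            frame_id=_complex_label(frame),
            frame_ca=frame_ca,
            mean_coords=mean,
            dispersion=dispersion,
            member_mean_dev=member_dev.mean(axis=0),
            members=[_complex_label(c) for c in members],
        )
    if len(patterns) == 1:
        return next(iter(patterns.values()))
    return patterns


def deviation_from_pattern(pattern: BackbonePattern, complex: PMHCComplex,
                           exception_rmsd: float = EXCEPTION_RMSD) -> PatternDeviationReport:
    """Per-position backbone deviation of a complex from a pattern.

    The complex is fitted into the pattern frame by receptor C-alpha; the
    exception flag fires when the overall backbone RMSD exceeds
    ``exception_rmsd`` or any position deviates by more than the members'
    mean deviation plus three dispersions at that position.
    """
    if len(complex.peptide_residues) != pattern.length:
        raise PmhcError(
            f"length mismatch: pattern {pattern.length} vs complex {len(complex.peptide_residues)}"
        )
    fitted = _fit_to_frame(complex, pattern.frame_ca)
    bb = _backbone_array(fitted)
    dev = np.linalg.norm(bb - pattern.mean_coords, axis=2)  # (n, 4)
    per_position = np.sqrt(np.mean(dev**2, axis=1))
    overall = float(np.sqrt(np.mean(dev**2)))
    threshold = pattern.member_mean_dev + 3.0 * pattern.dispersion
    exception = overall > exception_rmsd or bool(np.any(per_position > threshold + 1e-9))
    worst = int(np.argmax(per_position)) + 1
    return PatternDeviationReport(_complex_label(complex), overall, per_position,
                                  exception, worst)


# ---------------------------------------------------------------------------
# sequence-level anchor analysis


def composition_at(sequences: list[tuple[str, str]], position: int) -> CompositionTable:
    """Residue and class composition at an absolute position from the N terminus.

    ``position`` is 1-based; -1 selects the last residue of each sequence
    (the C-terminal anchor regardless of length).  Sequences shorter than
    the requested position are skipped.
    """
    if not sequences:
        raise PmhcError("no sequences given")
    counts: dict[str, int] = {}
    class_counts = {name: 0 for name in PHYSICOCHEMICAL_CLASSES}
    aromatic = 0
    for _, seq in sequences:
        seq = seq.strip().upper()
        if position == -1:
            aa = seq[-1]
        else:
            if position < 1 or position > len(seq):
                continue
            aa = seq[position - 1]
        counts[aa] = counts.get(aa, 0) + 1
        cls = classify_residue(aa)
        if cls != "other":
            class_counts[cls] += 1
        if aa in AROMATIC:
            aromatic += 1
    if not counts:
        raise PmhcError(f"no sequence covers position {position}")
    return CompositionTable(position, counts, class_counts, aromatic)


# ---------------------------------------------------------------------------
# burial and contacts


def burial_profile(complex: PMHCComplex, buried_below: float = 0.1,
                   exposed_above: float = 0.4,
                   n_points: int = 960) -> list[tuple[int, float, str]]:
    """Per-position relative side-chain ASA classified buried/intermediate/exposed."""
    from .surface import relative_sidechain_asa

    rel = relative_sidechain_asa(complex, n_points=n_points)
    out = []
    for i, value in enumerate(rel, start=1):
        if value < buried_below:
            label = "buried"
        elif value > exposed_above:
            label = "exposed"
        else:
            label = "intermediate"
        out.append((i, float(value), label))
    return out


#: heavy-atom hydrogen-bond criterion: donor-acceptor distance and minimum
#: antecedent-donor-acceptor angle (no hydrogens in crystal structures)
HBOND_MAX_DIST = 3.5
HBOND_MIN_ANGLE = 90.0

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}


def _polar_atoms(res: Residue) -> list:
    return [a for a in res.atoms if a.element in _DONOR_ACCEPTOR_ELEMENTS]


def _antecedent_of(res: Residue, atom) -> np.ndarray | None:
    best, best_d = None, np.inf
    for other in res.atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(other.pos - atom.pos))
        if d < best_d and d < 2.0:
            best, best_d = other, d
    return None if best is None else best.pos


def _geometric_hbond(res_a: Residue, res_b: Residue) -> list[tuple[str, str, float]]:
    """Polar-atom contacts satisfying the heavy-atom hydrogen-bond criterion."""
    found = []
    for a in _polar_atoms(res_a):
        for b in _polar_atoms(res_b):
            d = float(np.linalg.norm(a.pos - b.pos))
            if d > HBOND_MAX_DIST:
                continue
            ante = _antecedent_of(res_a, a)
            if ante is not None and bond_angle(ante, a.pos, b.pos) < HBOND_MIN_ANGLE:
                continue
            found.append((a.name, b.name, d))
    return found


def conserved_contact_report(complexes: list[PMHCComplex],
                             alpha_position: int) -> list[ContactReport]:
    """Identity of the alpha-chain residue at a position and its peptide H-bonds.

    Used to inspect conserved cleft residues (e.g. the tryptophans that wall
    off the central cleft, or a serine that hydrogen-bonds the p5 anchor).
    A missing residue yields a per-complex warning, not an error.
    """
    reports = []
    for c in complexes:
        res = next((r for r in c.alpha_chain if r.seqnum == alpha_position), None)
        if res is None:
            reports.append(ContactReport(_complex_label(c), None, [],
                                         warning=f"no residue {alpha_position} in alpha chain"))
            continue
        hbonds = []
        for p, pep_res in enumerate(c.peptide_residues, start=1):
            for (ma, pa, d) in _geometric_hbond(res, pep_res):
                hbonds.append((p, ma, pa, round(d, 3)))
        reports.append(ContactReport(_complex_label(c), res.code3, hbonds))
    return reports
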