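# Methods

This note documents the models, parameters and numerical choices behind
`pmhcforge`, and what the synthetic test surface does and does not show.

## Coordinate model and I/O

Structures are parsed from fixed-column PDB coordinate records into a small
chain/residue/atom hierarchy. Hydrogens and deuteriums are dropped at parse
time (crystal structures of this class mostly lack them, and all RMSDs are
heavy-atom); alternate locations other than `A`/blank are dropped; insertion
codes order after their base number. Peptide positions are renumbered
p1..pn from the N terminus while author numbering is preserved per residue.
`split_pmhc` requires exactly one protein chain of 8–12 residues with
complete N/CA/C/O backbones — structures with incomplete epitope density are
rejected, mirroring the curation rule used for the packaged ligand table.
Modified (non-canonical) residues are retained and flagged; threading
refuses them.

## Superposition and RMSD conventions

Kabsch superposition is computed by SVD with reflection correction
(det R = +1); collinear point sets are rejected. Two validation conventions
are exposed: fit the peptides by Cα and report all-heavy-atom peptide RMSD,
or fit the *receptor* α-chains by Cα (matched by residue number) and report
the peptide RMSD without refitting. The second is the default validation
metric because it also measures placement error inside the cleft; 2.2 Å is
the conventional upper bound for a valid reproduction. The α chain is taken
as the longest receptor chain; β2-microglobulin is not used in the fit.

## Backbone patterns

A pattern is computed per allele *and* per length class (length adjustments
happen mid-chain, so mixing lengths would blur the mean). All members are
fitted to the first member's receptor frame (the frame is a parameter); the
pattern stores per-position mean backbone coordinates, the RMS dispersion
over members, and the members' mean deviation. The literature describes
pattern exceptions qualitatively; the formal rule here is: exception ⇔
overall backbone RMSD > 2.0 Å (just under the 2.2 Å validity bound) or any
per-position deviation > member mean + 3 × dispersion. Physicochemical
classes for anchor composition are nonpolar {A,V,L,I,M,F,W,P,G}, polar
{S,T,N,Q,Y,C}, positive {K,R,H}, negative {D,E}, with aromatics {F,Y,W}
reported as an overlay, matching common usage for anchor analysis. For
mixed-length sets, composition uses absolute positions from the N terminus.

## Ideal geometry and threading

Side chains are built by natural-extension (NeRF) placement from a packaged
internal-coordinate table (bond lengths, angles, and torsion offsets per
atom, chirality consistent with L-amino-acid reference geometry; carboxylate
oxygens symmetrized to 1.249 Å). Threading copies the template backbone
bit-exactly, keeps template side chains at identical positions, and rebuilds
substituted side chains at default staples (χ1 = −60°, sp³ χ = 180°,
sp² ring χ2 = 90°, amide/carboxylate terminal χ = 0°). The rotamer library
is the minimal staple product (χ1/χ2 exhaustive, deeper χ at the first
staple); no backbone-dependent statistics are used — the docking stage's χ
resampling with ±20° jitter supplies the conformational search.

## Scoring function

Pairwise-additive over heavy atoms, sharp 8 Å cutoff, arbitrary score units:

* **Steric:** 12-6 Lennard-Jones, `4ε((σ/r)¹² − (σ/r)⁶)` with σ the sum of
  element radii (C 1.7, N 1.55, O 1.52, S 1.8 Å) and ε the geometric mean of
  element well depths (0.10–0.25).
* **Electrostatic:** Coulomb `332.06·q₁q₂/(ε(r)·r)` on coarse formal
  charges (Lys NZ +1, Arg CZ +1, Asp/Glu carboxylate O −0.5 each, His ring
  N +0.05 each; chain termini ±1 unless the structure is flagged capped —
  synthetic fixture peptides are built capped). Default dielectric ε = 4r;
  a constant-ε mode exists for the surface maps.
* **Hydrogen bond:** 10-4 well `(ε/6)(4(r₀/r)¹⁰ − 10(r₀/r)⁴)`, r₀ = 2.9 Å,
  ε = 2.0, between donors (N, hydroxyl O) and acceptors (O), weighted by
  cos²θ of the antecedent–donor–acceptor angle (zero under 90°). The
  angular factor is held fixed in the analytic gradient; the line search
  still guarantees monotone energies.
* **Torsion:** `k(1 + cos 3χ)`, k = 0.5, per side-chain χ — a soft bias
  toward the staple rotamers.

Bond topology is inferred from distances once (intra-residue < 1.95 Å,
2.1 Å with sulfur; inter-residue only the peptide C–N bond) and 1-2/1-3
pairs are excluded; 1-4 pairs interact fully. The cutoff is unsmoothed —
a documented discontinuity, acceptable at desk scale. These scores are
deliberately *not* calibrated to kcal/mol; published binding energies from
black-box docking engines are not reproduction targets for this package.

## Minimization

Steepest descent with backtracking line search (halving, up to 16 trials;
initial step capped at 0.1 Å max displacement). The objective adds soft
harmonic restraints on 1-2 (k = 300 units/Å²) and 1-3 (k = 60) distances
toward their input values, so covalent geometry survives minimization while
torsions relax freely; scaffold pseudo-atoms (see below) are positionally
tethered (k = 50). Convergence at gradient norm ≤ 1e-3 per Å or when no
decreasing step exists; the trace records accepted steps only and is
non-increasing by construction. Defaults follow the protocol: 100 steps for
the threaded peptide, 1000 for the complex.

## Docking protocol (D1–EM–D2)

The peptide backbone is never refolded: sampling combines whole-body rigid
perturbations (uniform translation ≤ 1.0 Å per axis, rotation ≤ 10° about a
random axis through the centroid) with side-chain rebuilds at staple ± 20°
jitter. Each run scores `iterations` candidates (the unperturbed input is
always candidate 0, making the search strictly local) and retains the best
`n_out_per_run`; `n_runs` independent runs are pooled. Defaults are 20 runs
× 50 poses, the published population size; `iterations` defaults to 60 as
the sampling-effort analog of a docking engine's exhaustiveness, which has
no literal translation here. Pose energies are interaction + peptide
internal energy. Selection clusters the pooled population greedily by
pairwise heavy-atom RMSD (1.0 Å cutoff, visiting poses by increasing
energy); the most populous cluster wins and its lowest-energy member is the
representative — a literal reading of frequency-first selection, with an
energy-first switch in the config. The receptor is rigid during both
dockings and moves only in the intervening complex EM. One master seed
derives per-run generator streams via fixed (seed, stage, run) tuples, so
runs are reproducible bit-for-bit and adding runs never reshuffles earlier
ones.

## Surface analysis

Shrake–Rupley ASA uses a deterministic golden-spiral point set (960 points,
probe 1.4 Å, Chothia-style radii). Signatures are whole-residue ASA per
peptide position with the receptor occluding (a side-chain-only mode backs
the burial classifier: relative side-chain ASA vs the isolated residue,
buried < 0.1, exposed > 0.4; glycine uses its CA as surrogate). The
TCR-face map keeps accessible-surface sample points whose outward normal
has a positive component along the cleft-plane normal (plane fit to
receptor Cα, oriented toward the peptide); each point carries its elevation
above the plane and the Coulomb potential of the formal charges in kT/e
(kT = 0.593 kcal/mol), clipped to ±10 — the clip bounds the potential RMS
and matches the conventional display scale. The hydrogen-bond criterion for
contact reports is heavy-atom only: donor–acceptor ≤ 3.5 Å and
antecedent–donor–acceptor angle ≥ 90°.

## Synthetic fixtures: scope and limits

The toy cleft is a scaffold of single-atom pseudo-residues (`PSD`): a floor
grid at z = 0, two walls (default spacing 15 Å, height 6.8 Å), optional
anchor pockets (open-topped atom cages around a chosen side chain, carved
so they never clash with the planted peptide), and optional mid-cleft
blockers above which the placed peptide arches — emulating, respectively,
the deep anchor pockets and the conserved bulky cleft residues of real
alleles. The peptide is ideal-geometry extended (φ = −140°, ψ = 135°),
oriented with anchor side chains downward, side chains tucked away from the
walls deterministically. Scaffold atoms occlude and repel real atoms but
are inert among themselves and tethered during EM: they model a rigid
environment, not a molecule.

What passing tests show: the geometric, energetic and statistical
contracts hold — superposition, occlusion, clustering, seeding, planted
pose recovery. What they do not show: performance on real MHC folds, real
side-chain packing in pockets, crystallographic noise, or binder/non-binder
discrimination; the toy receptor has no secondary structure and no charges,
and the planted truth is built by the same geometry engine that threading
uses. The packaged ligand table provides the real-sequence surface for the
anchor statistics.

## Problem sizes

The test suite and the acceptance script run the protocol at desk scale
(3 runs × 12 poses, 20 sampling iterations, EM 40/120 steps, 10 seeds) —
the same stages and selection logic as the 20 × 50 default, reduced as the
package's own benchmark size. The pattern-dispersion calibration uses 1000
noisy copies at σ = 0.3 Å, where the per-atom RMS deviation of isotropic
Gaussian noise has the closed form σ√3 ≈ 0.52 Å.

## Known limitations

* The potential is minimal: no solvation, no polarization, unsmoothed
  cutoff, coarse charges; energies rank poses but mean nothing absolutely.
* Proline's ring is built from fixed pseudo-torsions and does not close
  exactly; minimization restraints keep it sane.
* Side-chain placement is staple-based, not rotamer-statistical; crowded
  interfaces rely on EM and resampling rather than combinatorial packing.
* Pattern extraction assumes receptors superposable residue-by-residue
  (same allele); no sequence-alignment-driven structural alignment.
* The exception threshold (2.0 Å / mean + 3σ) formalizes what the source
  analyses flag qualitatively; it is a convention, exposed as a parameter.
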