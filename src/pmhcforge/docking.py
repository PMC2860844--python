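"""Rigid-receptor, flexible-side-chain conformer sampling and the D1-EM-D2 protocol.

A new peptide:MHC complex is built from sequence alone in five stages:
thread the target sequence onto an allele-pattern template backbone, relax it
briefly, dock it into the receptor (D1), energy-minimize the whole complex,
then separate the partners and dock again (D2).  Each docking stage draws
``n_runs`` independent replicate runs; every run samples local rigid-body
perturbations of the peptide combined with side-chain chi resampling from the
rotamer staples, and retains its ``n_out_per_run`` best-scoring poses.  The
pooled population is clustered by pairwise heavy-atom RMSD and the
representative is taken from the most populous cluster (lowest energy within
it) -- frequency first, energy as tie-break.

Everything is driven by one master seed; per-run generator streams are
derived by fixed offsets so results are reproducible bit-for-bit and
individual runs are independent of how many others are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import EnergyBreakdown, InternalPotential, ScoringParams, score_pose
from .errors import PmhcError, ThreadingError
from .geometry import rotation_about_axis
from .modeling import EMTrace, build_sidechain, chi_staples, minimize, n_chi, thread_sequence
from .structio import PMHCComplex, Structure
from .superpose import rmsd_between

__all__ = [
    "ProtocolConfig",
    "ConformerPopulation",
    "DockingResult",
    "sample_conformers",
    "select_representative",
    "run_d1_em_d2",
]


@dataclass
class ProtocolConfig:
    """Tunable knobs of the docking protocol (defaults follow the published setup)."""

    n_runs: int = 20
    n_out_per_run: int = 50
    iterations: int = 60  # sampling iterations per run (exhaustiveness analog)
    em_short: int = 100
    em_long: int = 1000
    cluster_rmsd: float = 1.0
    seed: int = 0
    translation_amplitude: float = 1.0  # angstrom, per move
    rotation_amplitude: float = 10.0  # degrees, per move
    chi_jitter: float = 20.0  # degrees around staple values
    sample_sidechains: bool = True  # False: keep the input side chains as-is
    frequency_first: bool = True  # False: pick the global-best-energy cluster

    def __post_init__(self):
        for name in ("n_runs", "n_out_per_run", "iterations", "em_short", "em_long"):
            if getattr(self, name) < 1:
                raise PmhcError(f"{name} must be >= 1")
        if self.cluster_rmsd <= 0:
            raise PmhcError("cluster_rmsd must be > 0")


@dataclass
class ConformerPopulation:
    """Scored peptide poses with clustering results."""

    conformers: list[tuple[Structure, EnergyBreakdown]] = field(default_factory=list)
    clusters: list[tuple[list[int], int]] = field(default_factory=list)  # (members, medoid)
    representative: int | None = None

    def energies(self) -> np.ndarray:
        return np.array([e.total for _, e in self.conformers])


@dataclass
class DockingResult:
    complex: PMHCComplex
    d1_energy: EnergyBreakdown
    d2_energy: EnergyBreakdown
    population_d1: ConformerPopulation
    population_d2: ConformerPopulation
    seed: int
    config: ProtocolConfig
    em_traces: dict[str, EMTrace] = field(default_factory=dict)


def _resample_sidechains(peptide: Structure, rng: np.random.Generator,
                         jitter: float) -> Structure:
    """Rebuild side chains with chis drawn from staples plus uniform jitter."""
    out = peptide.copy()
    for res in out.chains[0][1]:
        nchis = n_chi(res.code3)
        if nchis == 0:
            continue
        chis = []
        for k in range(nchis):
            staples = chi_staples(res.code3, k)
            base = staples[rng.integers(len(staples))]
            chi = base + rng.uniform(-jitter, jitter)
            chi = (chi + 180.0) % 360.0 - 180.0
            chis.append(chi if chi != -180.0 else 180.0)
        side = build_sidechain(res.code3, res, tuple(chis))
        res.atoms = [res.get(n) for n in ("N", "CA", "C", "O")] + side
    return out


def _rigid_perturb(peptide: Structure, rng: np.random.Generator,
                   translation: float, rotation_deg: float) -> Structure:
    out = peptide.copy()
    coords = out.coords()
    center = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-rotation_deg, rotation_deg)
    shift = rng.uniform(-translation, translation, size=3)
    if angle == 0.0 and not shift.any():
        return out  # bit-identical poses for the degenerate sampler
    R = rotation_about_axis(axis, angle)
    out.set_coords((coords - center) @ R.T + center + shift)
    return out


def _pose_energy(receptor: Structure, pose: Structure,
                 pose_potential: InternalPotential,
                 params: ScoringParams | None) -> EnergyBreakdown:
    inter = score_pose(receptor, pose, params)
    intra = pose_potential.energy(pose.coords())
    return inter + intra


def sample_conformers(receptor: Structure, peptide: Structure, config: ProtocolConfig,
                      rng: np.random.Generator,
                      params: ScoringParams | None = None) -> ConformerPopulation:
    """One docking run: local sampling around the input pose, keep the best.

    The input pose itself is always evaluated (iteration 0), so the sampler
    is a strict local search around the pattern-placed peptide.  The peptide
    backbone's internal geometry is never altered: moves are whole-body rigid
    perturbations plus side-chain rebuilds on the fixed backbone.
    """
    pose_potential = InternalPotential(peptide, params)
    scored: list[tuple[Structure, EnergyBreakdown]] = []
    for it in range(config.iterations):
        if it == 0:
            pose = peptide.copy()
        else:
            pose = (_resample_sidechains(peptide, rng, config.chi_jitter)
                    if config.sample_sidechains else peptide.copy())
            pose = _rigid_perturb(pose, rng, config.translation_amplitude,
                                  config.rotation_amplitude)
        # topology (bonds/exclusions) comes from the clean input pose and is
        # shared across samples; only coordinates differ between poses
        energy = _pose_energy(receptor, pose, pose_potential, params)
        scored.append((pose, energy))
    scored.sort(key=lambda t: t[1].total)
    return ConformerPopulation(conformers=scored[: config.n_out_per_run])


def select_representative(population: ConformerPopulation, cluster_rmsd: float = 1.0,
                          frequency_first: bool = True) -> int:
    """Greedy RMSD clustering; most populous cluster wins, energy breaks ties.

    Conformers are visited in order of increasing energy; each joins the
    first existing cluster whose founder (medoid) is within ``cluster_rmsd``
    heavy-atom RMSD, else founds a new cluster.  The representative is the
    lowest-energy member of the winning cluster (lowest index on exact ties).
    """
    if not population.conformers:
        raise PmhcError("empty conformer population")
    energies = population.energies()
    order = np.argsort(energies, kind="stable")
    coords = [pose.coords() for pose, _ in population.conformers]
    clusters: list[tuple[list[int], int]] = []
    for idx in order:
        placed = False
        for members, medoid in clusters:
            if rmsd_between(coords[idx], coords[medoid]) <= cluster_rmsd:
                members.append(int(idx))
                placed = True
                break
        if not placed:
            clusters.append(([int(idx)], int(idx)))

    def cluster_key(entry):
        members, _ = entry
        best = min((energies[m], m) for m in members)
        size_rank = -len(members) if frequency_first else 0.0
        return (size_rank, best[0], best[1])

    clusters.sort(key=cluster_key)
    population.clusters = clusters
    winner_members = clusters[0][0]
    representative = min(winner_members, key=lambda m: (energies[m], m))
    population.representative = int(representative)
    return int(representative)


def _check_allele(a: PMHCComplex, b: PMHCComplex) -> None:
    allele_a = a.provenance.get("allele")
    allele_b = b.provenance.get("allele")
    if allele_a and allele_b and allele_a != allele_b:
        raise PmhcError(f"allele mismatch: donor {allele_a!r} vs template {allele_b!r}")


def _dock_stage(receptor: Structure, peptide: Structure, config: ProtocolConfig,
                stage: int, params: ScoringParams | None) -> ConformerPopulation:
    pooled = ConformerPopulation()
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, stage, run])
        pop = sample_conformers(receptor, peptide, config, rng, params)
        pooled.conformers.extend(pop.conformers)
    select_representative(pooled, config.cluster_rmsd, config.frequency_first)
    return pooled


def run_d1_em_d2(target_seq: str, mhc_donor: PMHCComplex, template: PMHCComplex,
                 config: ProtocolConfig | None = None,
                 params: ScoringParams | None = None) -> DockingResult:
    """Full construction of a peptide:MHC complex from sequence.

    ``template`` provides the allele backbone pattern (its peptide); the
    receptor comes from ``mhc_donor`` (which may be a different entry of the
    same allele).  Returns the final complex with both stage populations,
    their energies and the EM traces.
    """
    config = config or ProtocolConfig()
    target_seq = target_seq.strip().upper()
    if len(target_seq) != len(template.peptide_residues):
        raise ThreadingError(
            f"target length {len(target_seq)} != template length {len(template.peptide_residues)}"
        )
    _check_allele(mhc_donor, template)
    receptor = mhc_donor.mhc.copy()
    receptor_coords0 = receptor.coords()

    # thread onto the pattern template, then a short relaxation
    threaded = thread_sequence(target_seq, template)
    relaxed, trace_short = minimize(threaded, nsteps=config.em_short, params=params)

    # D1: dock the relaxed peptide into the rigid receptor
    pop_d1 = _dock_stage(receptor, relaxed, config, stage=1, params=params)
    best_d1_pose, d1_energy = pop_d1.conformers[pop_d1.representative]

    # EM of the whole complex (receptor side chains adapt to the new ligand)
    assert np.array_equal(receptor.coords(), receptor_coords0)
    merged = PMHCComplex(receptor, best_d1_pose.copy(),
                         provenance=dict(template.provenance)).to_structure("d1_complex")
    merged.metadata["capped"] = True
    minimized, trace_long = minimize(merged, nsteps=config.em_long, params=params)

    # separate and dock again
    chain_ids = [cid for cid, _ in minimized.chains]
    pep_chain = chain_ids[-1]
    receptor_min = Structure("receptor_min",
                             [(cid, rs) for cid, rs in minimized.chains if cid != pep_chain],
                             metadata=dict(receptor.metadata))
    peptide_min = Structure("peptide_min",
                            [(pep_chain, minimized.chain(pep_chain))],
                            metadata={"capped": True})
    pop_d2 = _dock_stage(receptor_min, peptide_min, config, stage=2, params=params)
    best_d2_pose, d2_energy = pop_d2.conformers[pop_d2.representative]

    provenance = {
        "template": template.provenance.get("source", template.mhc.id),
        "donor": mhc_donor.provenance.get("source", mhc_donor.mhc.id),
        "target_seq": target_seq,
        "seed": config.seed,
        "protocol": "D1-EM-D2",
    }
    final = PMHCComplex(receptor_min.copy(), best_d2_pose.copy(), provenance=provenance,
                        energy=d2_energy)
    return DockingResult(
        complex=final,
        d1_energy=d1_energy,
        d2_energy=d2_energy,
        population_d1=pop_d1,
        population_d2=pop_d2,
        seed=config.seed,
        config=replace(config),
        em_traces={"short": trace_short, "long": trace_long},
    )
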