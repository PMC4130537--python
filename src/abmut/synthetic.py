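"""Synthetic germline/clone pairs and toy structures with known ground truth.

The sequence generator emulates the mutation structure of a small panel of
clonally related antibody V genes: a germline open reading frame annotated
with FR/CDR intervals, and clones carrying planted substitutions at
region-specific rates with a configurable transition/transversion bias.
Every planted mutation is labelled (position, bases, Ti/Tv, codon-level
R/S, region) so downstream classification can be tested for exact label
recovery.

The structure generator builds toy receptor/ligand atom clouds with
pinnable pairwise distances and Gaussian-noise trajectories, giving the
geometric operators fixtures whose answers are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .mutations import (
    PURINES,
    classify_codon_effect,
    classify_substitution,
    translate_codon,
)
from .regions import JUNCTION, AnnotatedSequence, RegionMap, RegionMapError
from .structure.model import Atom, StructureModel, Trajectory

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_codon(a + b + c) != "*"
)

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass(frozen=True)
class PlantedMutation:
    """Ground-truth record of one planted substitution."""

    codon_index: int  # 1-based
    within_codon_pos: int  # 1..3
    base_from: str
    base_to: str
    true_titv: str
    true_rs: str
    region: str

    def __post_init__(self) -> None:
        if self.base_from == self.base_to:
            raise ValueError("planted mutation must change the base")
        if not 1 <= self.within_codon_pos <= 3:
            raise ValueError("within_codon_pos must be 1..3")

    @property
    def nt_position(self) -> int:
        return (self.codon_index - 1) * 3 + self.within_codon_pos


#: Per-region substitution rates (expected substitutions per codon) shaped
#: like the observed VH panel: mutations concentrate in CDR2, with the
#: flanking FR1/FR3 frameworks next and CDR1/FR2 nearly untouched.
DEFAULT_PER_REGION_RATE = {
    "FR1": 0.015,
    "CDR1": 0.005,
    "FR2": 0.005,
    "CDR2": 0.10,
    "FR3": 0.03,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the clone simulator.

    ``titv_ratio`` is the ratio of transition to transversion *proposals*;
    0.5 makes all three alternative bases equally likely, under which
    transversions predominate 2:1 as observed in the panel.
    """

    seed: int = 0
    n_clones: int = 4
    per_region_rate: dict = field(default_factory=lambda: dict(DEFAULT_PER_REGION_RATE))
    titv_ratio: float = 0.5
    allow_multi_hit_codons: bool = True
    stop_codon_policy: str = "allow"  # or "forbid"

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.per_region_rate.values()):
            raise ValueError("per-region rates must be >= 0")
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be > 0")
        if self.stop_codon_policy not in ("allow", "forbid"):
            raise ValueError(f"unknown stop_codon_policy {self.stop_codon_policy!r}")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")


def generate_germline(seed: int, n_codons: int, region_map: RegionMap) -> AnnotatedSequence:
    """Random open reading frame annotated with ``region_map``.

    Codons are drawn uniformly from the 61 sense codons, so the sequence
    never contains an internal stop.  Deterministic for a fixed seed.
    """
    if region_map.last_codon > n_codons:
        raise RegionMapError(
            f"region map needs {region_map.last_codon} codons but n_codons={n_codons}"
        )
    rng = np.random.default_rng(seed)
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    seq = "".join(_SENSE_CODONS[i] for i in codons)
    return AnnotatedSequence(id=f"germline_seed{seed}", nucleotides=seq, regions=region_map)


def _mutate_base(base: str, titv_ratio: float, rng: np.random.Generator) -> str:
    if rng.random() < titv_ratio / (titv_ratio + 1.0):
        return _TRANSITION_OF[base]
    return _TRANSVERSIONS_OF[base][rng.integers(2)]


def mutate_clone(
    germline: AnnotatedSequence,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, list[PlantedMutation]]:
    """Plant substitutions into a copy of the germline.

    Each codon site mutates independently with probability rate/3 where
    rate is the expected substitutions per codon of its region (codons
    outside any region use the ``JUNCTION`` key, default 0).  Labels are
    computed from the realized codon change: Ti/Tv per site, R/S at codon
    level (multi-hit codons share one verdict).  Under
    ``stop_codon_policy='forbid'`` a codon's hits are redrawn until no
    stop arises.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    codons = germline.codons()
    out_codons = list(codons)
    mutations: list[PlantedMutation] = []
    for ci, codon in enumerate(codons, start=1):
        region = germline.regions.region_of(ci)
        rate = cfg.per_region_rate.get(region, 0.0)
        p_site = min(rate / 3.0, 1.0)
        if p_site == 0.0:
            continue
        for _attempt in range(100):
            hit_sites = [i for i in range(3) if rng.random() < p_site]
            if not cfg.allow_multi_hit_codons and len(hit_sites) > 1:
                hit_sites = [hit_sites[rng.integers(len(hit_sites))]]
            if not hit_sites:
                new_codon = codon
                break
            new = list(codon)
            for i in hit_sites:
                new[i] = _mutate_base(codon[i], cfg.titv_ratio, rng)
            new_codon = "".join(new)
            if cfg.stop_codon_policy == "allow" or translate_codon(new_codon) != "*":
                break
        else:  # could not avoid a stop; leave the codon untouched
            new_codon, hit_sites = codon, []
        if new_codon == codon:
            continue
        out_codons[ci - 1] = new_codon
        verdict = classify_codon_effect(codon, new_codon)
        for i in hit_sites:
            if new_codon[i] == codon[i]:
                continue
            mutations.append(
                PlantedMutation(
                    codon_index=ci,
                    within_codon_pos=i + 1,
                    base_from=codon[i],
                    base_to=new_codon[i],
                    true_titv=classify_substitution(codon[i], new_codon[i]),
                    true_rs=verdict,
                    region=region,
                )
            )
    return "".join(out_codons), mutations


def simulate_clones(
    germline: AnnotatedSequence, cfg: SimulationConfig
) -> list[tuple[AnnotatedSequence, list[PlantedMutation]]]:
    """Generate ``cfg.n_clones`` labelled clones from one seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for k in range(1, cfg.n_clones + 1):
        seq, muts = mutate_clone(germline, cfg, rng)
        clone = AnnotatedSequence(id=f"clone_{k:02d}", nucleotides=seq, regions=germline.regions)
        out.append((clone, muts))
    return out


TRUTH_COLUMNS = [
    "clone_id", "codon_index", "pos_in_codon", "nt_position",
    "base_from", "base_to", "titv", "rs", "region",
]


def truth_to_frame(
    clones: Sequence[tuple[AnnotatedSequence, Sequence[PlantedMutation]]]
) -> pd.DataFrame:
    rows = [
        (c.id, m.codon_index, m.within_codon_pos, m.nt_position,
         m.base_from, m.base_to, m.true_titv, m.true_rs, m.region)
        for c, muts in clones
        for m in muts
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_fasta(path: Union[str, Path], sequences: Sequence[AnnotatedSequence]) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.nucleotides), 60):
                fh.write(s.nucleotides[i : i + 60] + "\n")


# ---- toy structures ----------------------------------------------------


@dataclass(frozen=True)
class GeometrySpec:
    """Placement constraints for the toy receptor/ligand pair.

    ``box_size`` is the edge of the cube holding each random cloud;
    ``separation`` translates the ligand along +x so the closest
    inter-group pair is at least that far apart; ``pinned`` entries
    ``(receptor_index, ligand_index, distance)`` move the named ligand
    atom to exactly ``distance`` Angstrom from the named receptor atom.
    """

    box_size: float = 15.0
    separation: Optional[float] = None
    pinned: tuple[tuple[int, int, float], ...] = ()


_ELEMENTS = ("C", "N", "O")


def _cloud(
    rng: np.random.Generator,
    n_atoms: int,
    chain: str,
    resname: str,
    serial_start: int,
    box_size: float,
    charge_sd: float,
) -> list[Atom]:
    coords = rng.uniform(0.0, box_size, size=(n_atoms, 3))
    atoms = []
    for i in range(n_atoms):
        element = _ELEMENTS[rng.integers(len(_ELEMENTS))]
        atoms.append(
            Atom(
                serial=serial_start + i,
                name=f"{element}{i + 1}",
                element=element,
                residue_name=resname,
                residue_seq=i // 3 + 1,
                chain=chain,
                xyz=coords[i],
                partial_charge=float(rng.normal(0.0, charge_sd)) if charge_sd else 0.0,
            )
        )
    return atoms


def generate_toy_complex(
    seed: int,
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    geometry_spec: Optional[GeometrySpec] = None,
    charge_sd: float = 0.1,
) -> tuple[StructureModel, StructureModel]:
    """Random receptor/ligand atom clouds honouring ``geometry_spec``.

    Atoms carry elements, residue/chain labels and small random partial
    charges, so every structure operator can run on the output.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("need at least one atom on each side")
    spec = geometry_spec or GeometrySpec()
    rng = np.random.default_rng(seed)
    receptor = _cloud(rng, n_receptor_atoms, "A", "ALA", 1, spec.box_size, charge_sd)
    ligand = _cloud(
        rng, n_ligand_atoms, "L", "LIG", n_receptor_atoms + 1, spec.box_size, charge_sd
    )
    if spec.separation is not None:
        rec_max = max(a.xyz[0] for a in receptor)
        lig_min = min(a.xyz[0] for a in ligand)
        shift = rec_max - lig_min + spec.separation
        for a in ligand:
            a.xyz = a.xyz + np.array([shift, 0.0, 0.0])
    for ri, li, dist in spec.pinned:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        ligand[li].xyz = receptor[ri].xyz + dist * direction
    return StructureModel(receptor), StructureModel(ligand)


def generate_toy_trajectory(
    model: StructureModel, n_frames: int, noise_sd: float, seed: int
) -> Trajectory:
    """Gaussian-jitter trajectory: frame 0 is the model itself, frames
    1..F-1 add isotropic displacement of scale ``noise_sd`` per coordinate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = model.coords
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if n_frames > 1 and noise_sd > 0:
        frames[1:] += rng.normal(0.0, noise_sd, size=frames[1:].shape)
    return Trajectory(model, frames)


def two_charge_fixture(distance: float = 3.32064, charge: float = 1.0) -> tuple[StructureModel, StructureModel]:
    """Canonical Coulomb fixture: +q and -q point charges ``distance`` apart.

    At the default spacing of 3.32064 A and unit charges the electrostatic
    interaction is -100.0 kcal/mol (Coulomb constant 332.0637).
    """
    a = Atom(1, "C1", "C", "LIG", 1, "A", np.zeros(3), partial_charge=charge)
    b = Atom(2, "C1", "C", "LIG", 1, "B", np.array([distance, 0.0, 0.0]),
             partial_charge=-charge)
    return StructureModel([a]), StructureModel([b])
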