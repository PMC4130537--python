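"""Geometric interface and flexibility metrics.

Covers the coordinate-level operators used to characterise an
antibody-ligand interface and the dynamics of a complex:

* Van der Waals contacts — inter-selection heavy-atom pairs within a
  distance cutoff (default 4.0 A, inclusive);
* intermolecular hydrogen bonds — donor/acceptor heavy-atom pairs within
  3.5 A whose D-H...A angle is at least 120 degrees when explicit
  hydrogens are present (distance-only mode, flagged, otherwise);
* RMSD after optimal least-squares (Kabsch) superposition;
* RMSF of each atom about its position in the iteratively superposed
  trajectory-average structure;
* phi/psi backbone dihedrals and a configurable Ramachandran-quadrant
  letter code, used to describe the take-off conformation at the base of
  CDR-H3 (a 'bab' code at the three residues before the loop apex marks a
  kinked-plus-bulge, K+, candidate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .model import Atom, StructureModel, Trajectory

# donor/acceptor heavy atoms by residue; protein side chains plus the
# sugar residues of Lewis-type glycans (hydroxyl oxygens are both)
_PROTEIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_PROTEIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_SUGAR_RESIDUES = {"FUC", "GAL", "GLA", "NAG", "NDG", "BGC", "GLC", "MAN", "FUL"}
_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _is_donor(atom: Atom) -> bool:
    res, name = atom.residue_name.upper(), atom.name.upper()
    if res in _AMINO_ACIDS:
        if name == "N" and res != "PRO":  # backbone amide
            return True
        return name in _PROTEIN_DONORS.get(res, ())
    if res in _SUGAR_RESIDUES:
        # hydroxyl/amide groups: every oxygen except the ring O5, plus N2 of GlcNAc
        return (atom.element == "O" and name != "O5") or name == "N2"
    return False


def _is_acceptor(atom: Atom) -> bool:
    res, name = atom.residue_name.upper(), atom.name.upper()
    if res in _AMINO_ACIDS:
        if name == "O" or name == "OXT":  # backbone carbonyl
            return True
        return name in _PROTEIN_ACCEPTORS.get(res, ())
    if res in _SUGAR_RESIDUES:
        return atom.element == "O"
    return False


@dataclass(frozen=True)
class ContactRecord:
    atom_a: Atom
    atom_b: Atom
    distance: float


@dataclass(frozen=True)
class HBondRecord:
    donor: Atom
    acceptor: Atom
    distance: float
    hydrogen: Optional[Atom] = None
    angle: Optional[float] = None  # D-H...A, degrees
    distance_only: bool = False


def _require_atoms(sel: StructureModel, which: str) -> None:
    if len(sel) == 0:
        raise ValueError(f"empty selection for {which}")


def vdw_contacts(
    sel_a: StructureModel,
    sel_b: StructureModel,
    cutoff: float = 4.0,
    include_hydrogens: bool = False,
) -> list[ContactRecord]:
    """All inter-selection atom pairs with distance <= cutoff (inclusive).

    Hydrogens are excluded by default, matching the convention of counting
    heavy-atom contacts only.
    """
    _require_atoms(sel_a, "vdw_contacts")
    _require_atoms(sel_b, "vdw_contacts")
    if not include_hydrogens:
        sel_a, sel_b = sel_a.heavy_atoms(), sel_b.heavy_atoms()
        if len(sel_a) == 0 or len(sel_b) == 0:  # nothing but hydrogens
            return []
    d = cdist(sel_a.coords, sel_b.coords)
    out = [
        ContactRecord(sel_a.atoms[i], sel_b.atoms[j], float(d[i, j]))
        for i, j in zip(*np.nonzero(d <= cutoff))
    ]
    out.sort(key=lambda r: r.distance)
    return out


def _bonded_hydrogens(sel: StructureModel, max_bond: float = 1.25) -> dict[int, list[Atom]]:
    """Map heavy-atom index -> covalently attached hydrogens (by distance)."""
    heavy = [(i, a) for i, a in enumerate(sel.atoms) if not a.is_hydrogen]
    hydrogens = [a for a in sel.atoms if a.is_hydrogen]
    attached: dict[int, list[Atom]] = {}
    if not hydrogens:
        return attached
    hxyz = np.array([h.xyz for h in hydrogens])
    for i, a in heavy:
        d = np.linalg.norm(hxyz - a.xyz, axis=1)
        for k in np.nonzero(d <= max_bond)[0]:
            attached.setdefault(i, []).append(hydrogens[k])
    return attached


def _angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p0 - p1, p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hydrogen_bonds(
    sel_a: StructureModel,
    sel_b: StructureModel,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBondRecord]:
    """Intermolecular hydrogen bonds between two selections.

    A candidate pairs a donor heavy atom of one selection with an acceptor
    of the other at donor-acceptor distance <= ``d_max``.  When the donor
    carries explicit hydrogens the best D-H...A angle must reach
    ``angle_min``; donors without hydrogens are accepted on distance alone
    and the record is flagged ``distance_only``.  Atoms whose residue/name
    is not in the donor/acceptor dictionary are silently neither.
    """
    _require_atoms(sel_a, "hydrogen_bonds")
    _require_atoms(sel_b, "hydrogen_bonds")
    records: list[HBondRecord] = []
    for donors_sel, acceptors_sel in ((sel_a, sel_b), (sel_b, sel_a)):
        attached = _bonded_hydrogens(donors_sel)
        donors = [
            (i, a) for i, a in enumerate(donors_sel.atoms)
            if not a.is_hydrogen and _is_donor(a)
        ]
        acceptors = [a for a in acceptors_sel.atoms if not a.is_hydrogen and _is_acceptor(a)]
        for i, d_atom in donors:
            for a_atom in acceptors:
                dist = float(np.linalg.norm(d_atom.xyz - a_atom.xyz))
                if dist > d_max:
                    continue
                hyds = attached.get(i, [])
                if hyds:
                    best = max(
                        hyds, key=lambda h: _angle_deg(d_atom.xyz, h.xyz, a_atom.xyz)
                    )
                    ang = _angle_deg(d_atom.xyz, best.xyz, a_atom.xyz)
                    if ang >= angle_min:
                        records.append(HBondRecord(d_atom, a_atom, dist, best, ang))
                else:
                    records.append(
                        HBondRecord(d_atom, a_atom, dist, distance_only=True)
                    )
    records.sort(key=lambda r: r.distance)
    return records


# ---- superposition and deviation metrics -------------------------------


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |mobile@R + t - ref|.

    Classic SVD solution with the determinant sign fix to exclude
    reflections.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    t = qc - pc @ R
    return R, t


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Superpose ``mobile`` onto ``reference``, fitting on ``fit_indices``."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    R, t = kabsch(mobile[idx], reference[idx])
    return mobile @ R + t


def rmsd(
    coords_ref: np.ndarray,
    coords_alt: np.ndarray,
    superpose_first: bool = True,
) -> float:
    """Root-mean-square deviation, after Kabsch superposition by default."""
    ref = np.asarray(coords_ref, float)
    alt = np.asarray(coords_alt, float)
    if ref.shape != alt.shape:
        raise ValueError("coordinate sets must be congruent")
    if superpose_first:
        alt = superpose(alt, ref)
    return float(np.sqrt(np.mean(np.sum((ref - alt) ** 2, axis=1))))


def rmsf(
    traj: Trajectory,
    selection: Union[str, None] = None,
    fit_selection: Union[str, None] = ":*:backbone",
    max_iter: int = 10,
    tol: float = 1e-8,
) -> np.ndarray:
    """Per-atom RMS fluctuation about the trajectory-average structure.

    Each frame is superposed (on ``fit_selection``, backbone by default)
    onto the running average structure; the average is recomputed and the
    procedure iterated to convergence.  Returns fluctuations for the atoms
    of ``selection`` in topology order.
    """
    frames = traj.frames.copy()
    if traj.n_frames < 2:
        warnings.warn("RMSF of a single-frame trajectory is identically zero",
                      stacklevel=2)
        idx = traj.atom_indices(selection)
        return np.zeros(len(idx))
    fit_idx = traj.atom_indices(fit_selection)
    if len(fit_idx) < 3:  # not enough backbone atoms: fit on everything
        fit_idx = np.arange(frames.shape[1])
    mean = frames[0]
    for _ in range(max_iter):
        frames = np.array([superpose(f, mean, fit_idx) for f in frames])
        new_mean = frames.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if shift < tol:
            break
    idx = traj.atom_indices(selection)
    dev = frames[:, idx, :] - mean[idx]
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


# ---- backbone dihedrals and Ramachandran coding ------------------------


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


@dataclass(frozen=True)
class PhiPsi:
    residue_seq: int
    residue_name: str
    phi: float  # NaN at the N-terminus
    psi: float  # NaN at the C-terminus

    @property
    def complete(self) -> bool:
        return not (math.isnan(self.phi) or math.isnan(self.psi))


def phi_psi(model: StructureModel, chain: str) -> list[PhiPsi]:
    """Backbone phi/psi per residue of a chain; termini get NaN angles.

    Residues missing any of N, CA, C are skipped (and break the dihedral
    chain for their neighbours).
    """
    residues = []
    for rid, atoms in model.select(f"{chain}::").residues():
        bb = {a.name.upper(): a for a in atoms}
        if {"N", "CA", "C"} <= bb.keys():
            residues.append((rid, bb))
    out: list[PhiPsi] = []
    for k, (rid, bb) in enumerate(residues):
        prev_bb = residues[k - 1][1] if k > 0 else None
        next_bb = residues[k + 1][1] if k + 1 < len(residues) else None
        consecutive_prev = prev_bb is not None and residues[k - 1][0][1] == rid[1] - 1
        consecutive_next = next_bb is not None and residues[k + 1][0][1] == rid[1] + 1
        phi = (
            dihedral(prev_bb["C"].xyz, bb["N"].xyz, bb["CA"].xyz, bb["C"].xyz)
            if consecutive_prev
            else math.nan
        )
        psi = (
            dihedral(bb["N"].xyz, bb["CA"].xyz, bb["C"].xyz, next_bb["N"].xyz)
            if consecutive_next
            else math.nan
        )
        out.append(PhiPsi(rid[1], rid[3], phi, psi))
    return out


@dataclass(frozen=True)
class RamachandranPartition:
    """Quadrant boundaries for the letter coding of (phi, psi).

    Negative-phi space splits into the alpha region ('a',
    ``psi_alpha_lo < psi <= psi_alpha_hi``) and the beta region ('b');
    positive-phi space is left-handed 'l' unless psi falls in the extended
    band (|psi| beyond ``psi_epsilon``), coded 'e'.
    """

    psi_alpha_lo: float = -120.0
    psi_alpha_hi: float = 50.0
    psi_epsilon: float = 120.0

    def code(self, phi: float, psi: float) -> str:
        if math.isnan(phi) or math.isnan(psi):
            raise ValueError("phi/psi undefined (chain terminus?)")
        if phi > 0:
            return "e" if (psi > self.psi_epsilon or psi <= -self.psi_epsilon) else "l"
        return "a" if self.psi_alpha_lo < psi <= self.psi_alpha_hi else "b"


DEFAULT_PARTITION = RamachandranPartition()


def ramachandran_code(
    phi: float, psi: float, partition: RamachandranPartition = DEFAULT_PARTITION
) -> str:
    """Single-letter Ramachandran quadrant code ('a', 'b', 'l' or 'e')."""
    return partition.code(phi, psi)


def takeoff_codes(
    model: StructureModel,
    chain: str,
    residue_seqs: Sequence[int],
    partition: RamachandranPartition = DEFAULT_PARTITION,
) -> tuple[str, bool]:
    """Ramachandran code string for chosen residues of a chain.

    Intended for the residues at the base of CDR-H3; returns the code
    string and a heuristic flag marking the kinked-plus-bulge (K+)
    candidate pattern 'bab'.  Residues with undefined angles contribute
    '-' and never form part of a candidate pattern.
    """
    angles = {pp.residue_seq: pp for pp in phi_psi(model, chain)}
    codes = []
    for seq in residue_seqs:
        pp = angles.get(seq)
        if pp is None or not pp.complete:
            codes.append("-")
        else:
            codes.append(partition.code(pp.phi, pp.psi))
    code_str = "".join(codes)
    return code_str, "bab" in code_str
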