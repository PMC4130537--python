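"""Nonbonded interaction-energy decomposition between two selections.

The model is a plain pairwise nonbonded sum in vacuo over inter-selection
atom pairs within a spherical cutoff (default 14 A, hard truncation):

    E_elec = sum 332.0637 q_i q_j / (eps * r_ij)     [kcal/mol, e, A]
    E_vdw  = sum e_ij [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]

with Lorentz-Berthelot-style combination e_ij = sqrt(e_i e_j),
rmin_ij = rmin/2_i + rmin/2_j, and the dielectric constant eps = 1 by
default (vacuum).  Per-atom parameters come from explicit atom overlays
(``Atom.partial_charge`` / ``Atom.lj_params``) or, failing that, from a
small element-keyed parameter table bundled as an editable TSV.  Missing
charges or LJ parameters are a hard error listing the offending atoms —
never silent zeros.

The decomposition is generic: absolute magnitudes depend entirely on the
charge/parameter assignment, so cross-structure comparisons are only
meaningful under one consistent parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import StructureModel

#: Coulomb conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0637

#: Pairs closer than this are treated as a geometry error (the r^-12 term
#: would dominate everything and hide the mistake).
MIN_PAIR_DISTANCE = 0.1


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyDecomposition:
    """Interaction energy split into its two nonbonded components."""

    vdw: float
    electrostatic: float

    @property
    def total(self) -> float:
        return self.vdw + self.electrostatic

    def __add__(self, other: "EnergyDecomposition") -> "EnergyDecomposition":
        return EnergyDecomposition(
            self.vdw + other.vdw, self.electrostatic + other.electrostatic
        )


class NonbondedParameters:
    """Element/atom-class keyed LJ parameters and default charges (TSV)."""

    def __init__(self, table: pd.DataFrame):
        required = {"atom_class", "epsilon", "rmin_half", "default_charge"}
        missing = required - set(table.columns)
        if missing:
            raise ParameterError(f"parameter table missing columns {sorted(missing)}")
        self._by_class = {
            str(r.atom_class).upper(): (
                float(r.epsilon),
                float(r.rmin_half),
                None if pd.isna(r.default_charge) else float(r.default_charge),
            )
            for r in table.itertuples()
        }

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "NonbondedParameters":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def default(cls) -> "NonbondedParameters":
        with resources.files("abmut.data").joinpath("nonbonded_params.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t", comment="#"))

    def lookup(self, atom_class: str):
        return self._by_class.get(atom_class.upper())


def _resolve(
    sel: StructureModel, params: NonbondedParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Charges, epsilons and rmin/2 for every atom; hard error when missing."""
    q = np.empty(len(sel))
    eps = np.empty(len(sel))
    rmh = np.empty(len(sel))
    missing_q, missing_lj = [], []
    for i, a in enumerate(sel.atoms):
        entry = params.lookup(a.element)
        if a.lj_params is not None:
            eps[i], rmh[i] = a.lj_params
        elif entry is not None:
            eps[i], rmh[i] = entry[0], entry[1]
        else:
            missing_lj.append(a)
        if a.partial_charge is not None:
            q[i] = a.partial_charge
        elif entry is not None and entry[2] is not None:
            q[i] = entry[2]
        else:
            missing_q.append(a)
    msgs = []
    if missing_q:
        names = ", ".join(f"{a.chain}/{a.residue_seq}/{a.name}" for a in missing_q[:10])
        msgs.append(f"{len(missing_q)} atom(s) without partial charge: {names}")
    if missing_lj:
        names = ", ".join(f"{a.chain}/{a.residue_seq}/{a.name}" for a in missing_lj[:10])
        msgs.append(f"{len(missing_lj)} atom(s) without LJ parameters: {names}")
    if msgs:
        raise ParameterError("; ".join(msgs))
    return q, eps, rmh


def _pair_energies(
    sel_a: StructureModel,
    sel_b: StructureModel,
    cutoff: float,
    dielectric: float,
    params: NonbondedParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (n_a, n_b) electrostatic and VdW energy matrices."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection for interaction energy")
    if cutoff <= 0 or dielectric <= 0:
        raise ValueError("cutoff and dielectric must be positive")
    qa, ea, ra = _resolve(sel_a, params)
    qb, eb, rb = _resolve(sel_b, params)
    r = cdist(sel_a.coords, sel_b.coords)
    if np.any(r < MIN_PAIR_DISTANCE):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(
            f"atoms closer than {MIN_PAIR_DISTANCE} A "
            f"({sel_a.atoms[i].name} / {sel_b.atoms[j].name} at {r[i, j]:.3g} A)"
        )
    within = r <= cutoff
    with np.errstate(divide="ignore", invalid="ignore"):
        elec = np.where(within, COULOMB_CONSTANT * np.outer(qa, qb) / (dielectric * r), 0.0)
        eps_ij = np.sqrt(np.outer(ea, eb))
        rmin_ij = ra[:, None] + rb[None, :]
        frac6 = (rmin_ij / r) ** 6
        vdw = np.where(within, eps_ij * (frac6**2 - 2.0 * frac6), 0.0)
    return elec, vdw


def interaction_energy(
    sel_a: StructureModel,
    sel_b: StructureModel,
    cutoff: float = 14.0,
    dielectric: float = 1.0,
    params: Optional[NonbondedParameters] = None,
) -> EnergyDecomposition:
    """Total inter-selection nonbonded energy, decomposed (kcal/mol)."""
    params = params or NonbondedParameters.default()
    elec, vdw = _pair_energies(sel_a, sel_b, cutoff, dielectric, params)
    return EnergyDecomposition(vdw=float(vdw.sum()), electrostatic=float(elec.sum()))


def per_residue_energy(
    sel_a: StructureModel,
    sel_b: StructureModel,
    cutoff: float = 14.0,
    dielectric: float = 1.0,
    params: Optional[NonbondedParameters] = None,
) -> dict[tuple, EnergyDecomposition]:
    """Partition of the interaction energy by residue of ``sel_a``.

    The values sum exactly to :func:`interaction_energy` of the same
    selections (same pair list, just grouped).
    """
    params = params or NonbondedParameters.default()
    elec, vdw = _pair_energies(sel_a, sel_b, cutoff, dielectric, params)
    out: dict[tuple, EnergyDecomposition] = {}
    for i, atom in enumerate(sel_a.atoms):
        contrib = EnergyDecomposition(float(vdw[i].sum()), float(elec[i].sum()))
        key = atom.residue_id
        out[key] = out[key] + contrib if key in out else contrib
    return out
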