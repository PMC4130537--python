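"""Atomic structure containers and PDB input/output.

Parsing goes through gemmi; the resulting models are flattened into a
lightweight atom list carrying the fields the analysis operators need
(element, residue, chain, coordinates, optional partial charge and
Lennard-Jones parameters).  Alternate conformations are resolved by
keeping the highest-occupancy altloc of each atom.  Writing uses an
in-package canonical fixed-width formatter so that write(read(x)) is
byte-stable for files produced by this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureParseError(ValueError):
    pass


@dataclass
class Atom:
    """One atom record; charges and LJ parameters are optional overlays."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    xyz: np.ndarray
    icode: str = ""
    partial_charge: Optional[float] = None
    lj_params: Optional[tuple[float, float]] = None  # (epsilon kcal/mol, rmin/2 A)
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureParseError(
                f"atom {self.serial} {self.name}: coordinates must be 3 finite numbers"
            )
        if not self.element:
            raise StructureParseError(f"atom {self.serial} {self.name}: empty element")
        self.element = self.element.upper()

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        return (self.chain, self.residue_seq, self.icode, self.residue_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class StructureModel:
    """Ordered atom list with unique serials and a selection mini-language."""

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureParseError("duplicate atom serials within one model")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape ({len(self.atoms)}, 3)")
        for atom, xyz in zip(self.atoms, coords):
            atom.xyz = xyz.copy()

    def residues(self) -> list[tuple[tuple, list[Atom]]]:
        """Atoms grouped by (chain, residue_seq, icode, residue_name), in order."""
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_id, []).append(a)
        return list(groups.items())

    # ---- selections ----------------------------------------------------

    def select(self, expr: Union[str, Callable[[Atom], bool]]) -> "StructureModel":
        """Subset of atoms matching ``expr``; atom objects are shared.

        The string mini-language is ``chain:residues:atom_names`` where each
        field may be '*' (or empty) for a wildcard, residues is a
        comma-separated list of numbers or ``lo-hi`` ranges, and atom names
        may include the shorthand ``backbone`` (N, CA, C, O).  Trailing
        wildcard fields can be omitted, e.g. ``"H"`` or ``"H:95-102"``.
        """
        pred = expr if callable(expr) else _parse_selection(expr)
        return StructureModel(a for a in self.atoms if pred(a))

    def heavy_atoms(self) -> "StructureModel":
        return self.select(lambda a: not a.is_hydrogen)


def _parse_selection(expr: str) -> Callable[[Atom], bool]:
    parts = (expr.strip().split(":") + ["*", "*", "*"])[:3]
    chain_f, res_f, name_f = (p.strip() or "*" for p in parts)

    chains = None if chain_f == "*" else {c.strip() for c in chain_f.split(",")}

    res_ranges: Optional[list[tuple[int, int]]] = None
    if res_f != "*":
        res_ranges = []
        for tok in res_f.split(","):
            tok = tok.strip()
            if "-" in tok[1:]:  # allow negative residue numbers
                cut = tok.index("-", 1)
                res_ranges.append((int(tok[:cut]), int(tok[cut + 1 :])))
            else:
                res_ranges.append((int(tok), int(tok)))

    names: Optional[set[str]] = None
    if name_f != "*":
        names = set()
        for tok in name_f.split(","):
            tok = tok.strip().upper()
            if tok == "BACKBONE":
                names.update(BACKBONE_ATOMS)
            else:
                names.add(tok)

    def pred(a: Atom) -> bool:
        if chains is not None and a.chain not in chains:
            return False
        if res_ranges is not None and not any(
            lo <= a.residue_seq <= hi for lo, hi in res_ranges
        ):
            return False
        if names is not None and a.name.upper() not in names:
            return False
        return True

    return pred


class Trajectory:
    """Frame series congruent with a topology model."""

    def __init__(self, topology: StructureModel, frames: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise StructureParseError(
                f"frames must have shape (F, {len(topology)}, 3), got {frames.shape}"
            )
        self.topology = topology
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        m = StructureModel([replace(a, xyz=a.xyz.copy()) for a in self.topology])
        m.set_coords(self.frames[i])
        return m

    def atom_indices(self, selection: Union[str, Callable[[Atom], bool], None]) -> np.ndarray:
        if selection is None:
            return np.arange(len(self.topology))
        pred = selection if callable(selection) else _parse_selection(selection)
        return np.array(
            [i for i, a in enumerate(self.topology) if pred(a)], dtype=int
        )


# ---- reading -----------------------------------------------------------


def _read_text(source: Union[str, Path, io.IOBase]) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    return Path(source).read_text()


def _gemmi_structure(text: str) -> gemmi.Structure:
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise StructureParseError(f"PDB parse error: {exc}") from exc
    st.setup_entities()
    return st


def _model_atoms(model: gemmi.Model) -> list[Atom]:
    # resolve altlocs: keep the highest-occupancy conformation of each atom
    best: dict[tuple, gemmi.Atom] = {}
    order: list[tuple] = []
    meta: dict[tuple, tuple] = {}
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), res.name, at.name)
                if key not in best:
                    best[key] = at
                    order.append(key)
                    meta[key] = (chain.name, res)
                elif at.occ > best[key].occ:
                    best[key] = at
    atoms = []
    for key in order:
        at = best[key]
        chain_name, res = meta[key]
        element = at.element.name.strip() or at.name[0]
        atoms.append(
            Atom(
                serial=at.serial,
                name=at.name,
                element=element,
                residue_name=res.name,
                residue_seq=res.seqid.num,
                icode=res.seqid.icode.strip(),
                chain=chain_name,
                xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                occupancy=at.occ,
                b_factor=at.b_iso,
            )
        )
    return atoms


def read_structure(source: Union[str, Path, io.IOBase]) -> StructureModel:
    """Read a single-model PDB (first MODEL of a multi-model file)."""
    st = _gemmi_structure(_read_text(source))
    if len(st) == 0:
        raise StructureParseError("no models in PDB input")
    return StructureModel(_model_atoms(st[0]))


def read_trajectory(source: Union[str, Path, io.IOBase]) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (frame order = MODEL order)."""
    st = _gemmi_structure(_read_text(source))
    if len(st) == 0:
        raise StructureParseError("no models in PDB input")
    topology = StructureModel(_model_atoms(st[0]))
    frames = []
    for model in st:
        atoms = _model_atoms(model)
        if len(atoms) != len(topology):
            raise StructureParseError(
                f"model {model.name!r} has {len(atoms)} atoms, expected {len(topology)}"
            )
        frames.append([a.xyz for a in atoms])
    return Trajectory(topology, np.array(frames))


# ---- writing -----------------------------------------------------------


def _format_atom_name(name: str) -> str:
    # one/two-letter element names start in column 14 by PDB convention
    if len(name) >= 4 or (name and name[0].isdigit()):
        return f"{name:<4.4s}"
    return f" {name:<3.3s}"


def _atom_line(a: Atom) -> str:
    x, y, z = a.xyz
    return (
        f"ATOM  {a.serial:>5d} {_format_atom_name(a.name)} "
        f"{a.residue_name:>3.3s} {a.chain:1.1s}{a.residue_seq:>4d}{a.icode or ' ':1.1s}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2.2s}"
    )


def structure_to_pdb_string(model: StructureModel) -> str:
    lines = [_atom_line(a) for a in model]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(model: StructureModel, path: Union[str, Path]) -> None:
    Path(path).write_text(structure_to_pdb_string(model))


def trajectory_to_pdb_string(traj: Trajectory) -> str:
    lines = []
    for i in range(traj.n_frames):
        lines.append(f"MODEL     {i + 1:>4d}")
        for a, xyz in zip(traj.topology, traj.frames[i]):
            lines.append(_atom_line(replace(a, xyz=xyz)))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    Path(path).write_text(trajectory_to_pdb_string(traj))
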