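"""Reading, writing and editing molecular structures.

Supported formats: plain XYZ, PDB (ATOM/HETATM/MODEL/ENDMDL/TER/CONECT),
MDL MOL/SDF V2000, and a minimal internal "csm" dialect that carries both
coordinates and connectivity.  Concatenated multi-model files and
directories of files are accepted.  Atom order is preserved exactly as
read; permutations elsewhere in the package are reported against it.

Connectivity can be read from the file (mol/sdf bond block, PDB CONECT,
csm adjacency lines), supplied as an external plain-text adjacency file
(1-based: each line ``i j k ...`` bonds atom i to j, k, ...), or inferred
from a covalent-radius criterion.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .symmetry_core import CSMError

__all__ = [
    "Atom", "BondSet", "Molecule", "FormatError", "SelectionError",
    "ConnectivityError", "read_structures", "infer_bonds",
    "parse_connectivity_file", "apply_selection", "write_structure",
]


class FormatError(CSMError):
    """Unparseable molecular file."""


class SelectionError(CSMError):
    """Invalid model/atom/chain selection."""


class ConnectivityError(CSMError):
    """Invalid connectivity listing."""


_FALLBACK_RADIUS = 0.77  # Å, generic single-bond covalent radius


def _periodic_table():
    from rdkit import Chem
    return Chem.GetPeriodicTable()


def recognized_element(symbol: str) -> str:
    """Normalize an element symbol; unknown symbols become "X"."""
    s = symbol.strip()
    if not s:
        return "X"
    s = s[0].upper() + s[1:].lower()
    try:
        if _periodic_table().GetAtomicNumber(s) > 0:
            return s
    except Exception:
        pass
    return "X"


def covalent_radius(element: str) -> float:
    try:
        r = _periodic_table().GetRcovalent(element)
        if r > 0:
            return float(r)
    except Exception:
        pass
    warnings.warn(f"no covalent radius for element {element!r}; "
                  f"using {_FALLBACK_RADIUS} Å")
    return _FALLBACK_RADIUS


# --------------------------------------------------------------------------
# domain types

@dataclass
class Atom:
    index: int
    element: str
    position: np.ndarray
    chain_id: Optional[str] = None
    residue_name: Optional[str] = None
    residue_seq: Optional[int] = None
    atom_name: Optional[str] = None
    het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class BondSet:
    """Unordered, loop-free set of atom-index pairs."""

    def __init__(self, edges: Iterable[Sequence[int]] = ()):
        self.edges: set[tuple[int, int]] = set()
        for i, j in edges:
            self.add(i, j)

    def add(self, i: int, j: int) -> None:
        if i == j:
            raise ConnectivityError(f"self-bond on atom {i + 1}")
        self.edges.add((min(i, j), max(i, j)))

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, BondSet) and self.edges == other.edges

    def induced(self, index_map: dict[int, int]) -> "BondSet":
        """Bonds among surviving atoms, re-indexed through ``index_map``."""
        out = BondSet()
        for i, j in self.edges:
            if i in index_map and j in index_map:
                out.add(index_map[i], index_map[j])
        return out

    def neighbors(self, n_atoms: int) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(n_atoms)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class Molecule:
    atoms: list[Atom]
    bonds: BondSet = field(default_factory=BondSet)
    source_format: str = "xyz"
    model_index: int = 1
    title: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


def atomic_masses(mol: Molecule) -> np.ndarray:
    pt = _periodic_table()
    out = []
    for a in mol.atoms:
        try:
            m = pt.GetAtomicWeight(a.element)
        except Exception:
            m = 12.0
        out.append(m if m > 0 else 12.0)
    return np.array(out)


# --------------------------------------------------------------------------
# reading

_EXT_FORMAT = {".xyz": "xyz", ".pdb": "pdb", ".ent": "pdb",
               ".mol": "mol", ".sdf": "sdf", ".sd": "sdf", ".csm": "csm"}


def _deduce_format(path: Path, hint: Optional[str]) -> str:
    if hint:
        f = hint.lower()
        if f not in ("xyz", "pdb", "mol", "sdf", "csm"):
            raise FormatError(f"unsupported format {hint!r}")
        return f
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"cannot deduce format from extension of {path}")
    return fmt


def read_structures(path, format: Optional[str] = None,
                    selected_models: Optional[Sequence[int]] = None) -> list[Molecule]:
    """Read one Molecule per model from a file (or every file of a directory).

    ``selected_models`` filters by 1-based model index; the reported
    ``model_index`` keeps the original numbering.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.is_dir():
        mols: list[Molecule] = []
        for child in sorted(p.iterdir()):
            if child.suffix.lower() in _EXT_FORMAT:
                mols.extend(read_structures(child, format=format))
        for k, m in enumerate(mols, start=1):
            m.model_index = k
    else:
        fmt = _deduce_format(p, format)
        reader = {"xyz": _read_xyz, "pdb": _read_pdb,
                  "mol": _read_mdl, "sdf": _read_mdl, "csm": _read_csm}[fmt]
        mols = reader(p)
        for m in mols:
            m.source_format = fmt
    if not mols:
        raise FormatError(f"no molecular models found in {p}")
    if selected_models is not None:
        chosen = []
        for k in selected_models:
            if not 1 <= k <= len(mols):
                raise SelectionError(
                    f"model index {k} out of range 1..{len(mols)}")
            chosen.append(mols[k - 1])
        mols = chosen
    return mols


def _read_xyz(path: Path) -> list[Molecule]:
    lines = path.read_text().splitlines()
    mols = []
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: expected an atom count")
        if i + n + 2 > len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated model of {n} atoms")
        title = lines[i + 1].strip() if i + 1 < len(lines) else ""
        atoms = []
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln + 1}: expected 'element x y z'")
            try:
                pos = np.array([float(x) for x in parts[1:4]])
            except ValueError:
                raise FormatError(f"{path}:{ln + 1}: bad coordinates")
            atoms.append(Atom(index=k, element=recognized_element(parts[0]),
                              position=pos))
        model += 1
        mols.append(Molecule(atoms=atoms, bonds=BondSet(), source_format="xyz",
                             model_index=model, title=title))
        i += 2 + n
    return mols


def _read_csm(path: Path) -> list[Molecule]:
    lines = [ln for ln in path.read_text().splitlines()]
    mols = []
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: expected an atom count")
        if i + 2 * n + 1 > len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated csm model")
        atoms = []
        for k in range(n):
            parts = lines[i + 1 + k].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{i + 2 + k}: expected 'element x y z'")
            atoms.append(Atom(index=k, element=recognized_element(parts[0]),
                              position=np.array([float(x) for x in parts[1:4]])))
        adj_text = "\n".join(lines[i + 1 + n: i + 1 + 2 * n])
        bonds = parse_connectivity_file(adj_text, n, allow_empty=True)
        model += 1
        mols.append(Molecule(atoms=atoms, bonds=bonds, source_format="csm",
                             model_index=model))
        i += 1 + 2 * n
    return mols


def _read_mdl(path: Path) -> list[Molecule]:
    from rdkit import Chem
    text = path.read_text()
    blocks = [b for b in text.split("$$$$") if b.strip()]
    mols = []
    for mi, block in enumerate(blocks, start=1):
        rd = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if rd is None:
            raise FormatError(f"{path}: model {mi}: unparseable MDL block")
        conf = rd.GetConformer()
        atoms = []
        for k, a in enumerate(rd.GetAtoms()):
            pos = conf.GetAtomPosition(k)
            atoms.append(Atom(index=k, element=recognized_element(a.GetSymbol()),
                              position=np.array([pos.x, pos.y, pos.z])))
        bonds = BondSet((b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                        for b in rd.GetBonds())
        title = block.lstrip("\n").splitlines()[0].strip() if block.strip() else ""
        mols.append(Molecule(atoms=atoms, bonds=bonds, source_format="sdf",
                             model_index=mi, title=title))
    return mols


def _read_pdb(path: Path) -> list[Molecule]:
    import gemmi
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    mols = []
    for mi, model in enumerate(st, start=1):
        atoms = []
        serial_to_index = {}
        for chain in model:
            for res in chain:
                for at in res:
                    if at.altloc not in ("", "\x00", " ", "A"):
                        raise FormatError(
                            f"{path}: atom {at.serial} has altloc "
                            f"{at.altloc!r}; pre-clean the file to a single "
                            f"conformation before the symmetry analysis")
                    k = len(atoms)
                    serial_to_index[at.serial] = k
                    atoms.append(Atom(
                        index=k,
                        element=recognized_element(at.element.name),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        atom_name=at.name,
                        het=(res.het_flag == "H"),
                    ))
        bonds = BondSet()
        for serial, partners in st.conect_map.items():
            for s2 in partners:
                if serial in serial_to_index and s2 in serial_to_index:
                    i, j = serial_to_index[serial], serial_to_index[s2]
                    if i != j:
                        bonds.add(i, j)
        if atoms:
            mols.append(Molecule(atoms=atoms, bonds=bonds, source_format="pdb",
                                 model_index=mi))
    return mols


# --------------------------------------------------------------------------
# connectivity

def infer_bonds(mol: Molecule, tolerance_factor: float = 1.15) -> BondSet:
    """Distance-based bond perception: (i, j) bonded iff
    ``d(i,j) <= tolerance_factor * (r_cov(i) + r_cov(j))``."""
    if tolerance_factor <= 0:
        raise ValueError("tolerance_factor must be positive")
    P = mol.coords
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite coordinates")
    radii = np.array([covalent_radius(a.element) for a in mol.atoms])
    diff = P[:, None, :] - P[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    cutoff = tolerance_factor * (radii[:, None] + radii[None, :])
    bonds = BondSet()
    n = len(mol)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff[i, j]:
                bonds.add(i, j)
    return bonds


def parse_connectivity_file(text: str, n_atoms: int,
                            allow_empty: bool = False) -> BondSet:
    """Parse a plain-text adjacency listing.

    Each non-empty line ``i j k ...`` (1-based) declares bonds (i,j), (i,k),
    ...; reciprocal declarations are merged.
    """
    bonds = BondSet()
    any_line = False
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        any_line = True
        try:
            nums = [int(x) for x in line.split()]
        except ValueError:
            raise ConnectivityError(f"line {ln}: non-integer entry")
        for x in nums:
            if not 1 <= x <= n_atoms:
                raise ConnectivityError(
                    f"line {ln}: atom index {x} out of range 1..{n_atoms}")
        head = nums[0]
        for other in nums[1:]:
            if other != head:
                bonds.add(head - 1, other - 1)
    if not any_line and not allow_empty:
        warnings.warn("empty connectivity listing; no bonds declared")
    return bonds


# --------------------------------------------------------------------------
# selection

def apply_selection(mol: Molecule, select_atoms: Optional[Sequence[int]] = None,
                    remove_hy: bool = False):
    """Restrict to a fragment and/or drop hydrogens.

    ``select_atoms`` is 1-based (file convention); selection is applied
    before hydrogen removal.  Returns the re-indexed Molecule and the
    old-index -> new-index map.  Bonds are induced on the surviving set, so
    a connectivity file should always describe the complete structure.
    """
    keep = list(range(len(mol)))
    if select_atoms is not None:
        for k in select_atoms:
            if not 1 <= k <= len(mol):
                raise SelectionError(
                    f"atom index {k} out of range 1..{len(mol)}")
        keep = [k - 1 for k in select_atoms]
    if remove_hy:
        keep = [i for i in keep if not mol.atoms[i].is_hydrogen]
    if not keep:
        raise SelectionError("selection leaves no atoms")
    index_map = {old: new for new, old in enumerate(keep)}
    atoms = []
    for new, old in enumerate(keep):
        atoms.append(replace(mol.atoms[old], index=new,
                             position=mol.atoms[old].position.copy()))
    sub = Molecule(atoms=atoms, bonds=mol.bonds.induced(index_map),
                   source_format=mol.source_format,
                   model_index=mol.model_index, title=mol.title)
    return sub, index_map


# --------------------------------------------------------------------------
# writing

def write_structure(mol: Molecule, format: str, destination) -> None:
    """Write a molecule; the written file re-reads to the same element
    sequence and bonds (coordinate precision is format-limited: full double
    for xyz/csm, 4 decimals for mol/sdf, 3 for pdb)."""
    fmt = format.lower()
    writer = {"xyz": _write_xyz, "pdb": _write_pdb, "mol": _write_mdl,
              "sdf": _write_mdl, "csm": _write_csm}.get(fmt)
    if writer is None:
        raise FormatError(f"unsupported output format {format!r}")
    text = writer(mol)
    Path(destination).write_text(text)


def _write_xyz(mol: Molecule) -> str:
    lines = [str(len(mol)), mol.title]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"


def _write_csm(mol: Molecule) -> str:
    lines = [str(len(mol))]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    adj = mol.bonds.neighbors(len(mol))
    for i in range(len(mol)):
        lines.append(" ".join(str(k + 1) for k in [i] + sorted(adj[i])))
    return "\n".join(lines) + "\n"


def _write_mdl(mol: Molecule) -> str:
    from rdkit import Chem
    from rdkit.Geometry import Point3D
    rd = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element if a.element != "X" else "*")
        at.SetNoImplicit(True)
        rd.AddAtom(at)
    for i, j in sorted(mol.bonds.edges):
        rd.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(mol))
    for k, a in enumerate(mol.atoms):
        conf.SetAtomPosition(k, Point3D(*map(float, a.position)))
    rd.AddConformer(conf)
    m = rd.GetMol()
    m.SetProp("_Name", mol.title or "")
    return Chem.MolToMolBlock(m, kekulize=False) + "$$$$\n"


def _write_pdb(mol: Molecule) -> str:
    lines = []
    for k, a in enumerate(mol.atoms, start=1):
        name = a.atom_name or a.element
        if len(name) < 4:
            name = " " + name.ljust(3)
        record = "HETATM" if a.het else "ATOM  "
        chain = (a.chain_id or "A")[:1]
        resname = (a.residue_name or "UNK")[:3]
        resseq = a.residue_seq if a.residue_seq is not None else 1
        x, y, z = a.position
        lines.append(f"{record}{k:5d} {name:<4s} {resname:>3s} {chain}"
                     f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                     f"  1.00  0.00          {a.element:>2s}")
    adj = mol.bonds.neighbors(len(mol))
    for i in range(len(mol)):
        if adj[i]:
            partners = "".join(f"{j + 1:5d}" for j in sorted(adj[i])[:4])
            lines.append(f"CONECT{i + 1:5d}{partners}")
    lines.append("END")
    return "\n".join(lines) + "\n"
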