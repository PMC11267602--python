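"""Deterministic generators of test geometries.

Exactly symmetric structures are built by closing seeded random orbits
under the group generator; controlled Gaussian perturbations and synthetic
protein homomers (one seeded chain replicated by the group rotation) make
every algorithm in the package testable without any external structure
file.  All randomness is seed-parameterized so fixtures are bit-reproducible.
These geometries are synthetic and make no claim of force-field realism.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .molio import Atom, BondSet, Molecule
from .symmetry_core import PointGroup, generator_operation

__all__ = ["make_symmetric", "orbit_permutation", "perturb", "make_homomer",
           "random_molecule"]

_DEFAULT_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "B"]


def make_symmetric(group: PointGroup, n_orbits: int = 2,
                   elements: Optional[Sequence[str]] = None,
                   seed: int = 0,
                   axis: Sequence[float] = (0.0, 0.0, 1.0)) -> Molecule:
    """Exactly ``group``-symmetric molecule: ``n_orbits`` seeded random
    points, each closed into an orbit of size h under the generator about
    ``axis``.  Atoms of one orbit share an element, so the true symmetry
    permutation respects the element classes."""
    if n_orbits < 1:
        raise ValueError("n_orbits must be >= 1")
    rng = np.random.default_rng(seed)
    op = generator_operation(group, np.asarray(axis, float))
    h = group.group_order_h
    if elements is None:
        elements = [_DEFAULT_ELEMENTS[k % len(_DEFAULT_ELEMENTS)]
                    for k in range(n_orbits)]
    atoms = []
    for orbit in range(n_orbits):
        p = rng.uniform(-2.0, 2.0, 3)
        while np.linalg.norm(p) < 0.5:  # keep away from the origin
            p = rng.uniform(-2.0, 2.0, 3)
        q = p.copy()
        for _ in range(h):
            atoms.append(Atom(index=len(atoms), element=elements[orbit],
                              position=q.copy()))
            q = op.matrix @ q
    return Molecule(atoms=atoms, bonds=BondSet(), source_format="xyz",
                    title=f"{group.label} fixture seed={seed}")


def orbit_permutation(group: PointGroup, n_orbits: int) -> np.ndarray:
    """The symmetry permutation of a :func:`make_symmetric` molecule: each
    orbit is one h-cycle in construction order (atom k of an orbit was
    produced by the k-th power of the generator, so the operation advances
    it to atom k+1)."""
    h = group.group_order_h
    perm = np.empty(n_orbits * h, dtype=int)
    for orbit in range(n_orbits):
        base = orbit * h
        for k in range(h):
            perm[base + k] = base + (k + 1) % h
    return perm


def perturb(mol: Molecule, sigma: float, seed: int = 0) -> Molecule:
    """Add seeded i.i.d. Gaussian displacement of std ``sigma`` per
    coordinate; ``sigma = 0`` returns identical coordinates."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, (len(mol.atoms), 3)) if sigma > 0 else 0.0
    atoms = [replace(a, position=a.position + (noise[k] if sigma > 0 else 0.0))
             for k, a in enumerate(mol.atoms)]
    return Molecule(atoms=atoms, bonds=BondSet(set(mol.bonds.edges)),
                    source_format=mol.source_format,
                    model_index=mol.model_index, title=mol.title)


def random_molecule(n_atoms: int, seed: int = 0,
                    elements: Sequence[str] = ("C", "N", "O")) -> Molecule:
    """Generic seeded random molecule (no constructed symmetry); element
    assignment cycles deterministically so classes are reproducible."""
    rng = np.random.default_rng(seed)
    P = rng.uniform(-2.0, 2.0, (n_atoms, 3))
    atoms = [Atom(index=k, element=elements[int(rng.integers(len(elements)))],
                  position=P[k]) for k in range(n_atoms)]
    return Molecule(atoms=atoms, bonds=BondSet(), source_format="xyz",
                    title=f"random seed={seed}")


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")


def make_homomer(n_chains: int, n_residues: int,
                 group: Optional[PointGroup] = None,
                 sigma: float = 0.0, seed: int = 0) -> Molecule:
    """Synthetic homo-oligomer: one seeded random chain of ``n_residues``
    alanine-like residues (atoms N, CA, C, O, CB), replicated into
    ``n_chains`` chains by the group rotation about z (chain ids A, B, ...),
    then perturbed by ``sigma``.

    ``group`` defaults to Cn with n = n_chains; for exact closure
    ``n_chains`` must equal the group order.
    """
    if group is None:
        group = PointGroup.parse(f"c{n_chains}")
    if n_chains != group.group_order_h:
        raise ValueError("n_chains must equal the group order for closure")
    rng = np.random.default_rng(seed)
    op = generator_operation(group, (0.0, 0.0, 1.0))

    # a loose helical backbone, displaced off the symmetry axis
    base = []
    for r in range(n_residues):
        center = np.array([6.0 + 0.3 * np.cos(0.8 * r),
                           0.3 * np.sin(0.8 * r),
                           1.5 * r])
        for k in range(len(_RESIDUE_ATOMS)):
            base.append(center + rng.normal(0.0, 0.6, 3))
    base = np.array(base)

    atoms = []
    coords = base.copy()
    for c in range(n_chains):
        for r in range(n_residues):
            for k, name in enumerate(_RESIDUE_ATOMS):
                pos = coords[r * len(_RESIDUE_ATOMS) + k]
                atoms.append(Atom(
                    index=len(atoms),
                    element="N" if name == "N" else ("O" if name == "O" else "C"),
                    position=pos.copy(),
                    chain_id=_CHAIN_IDS[c],
                    residue_name="ALA",
                    residue_seq=r + 1,
                    atom_name=name))
        coords = coords @ op.matrix.T
    mol = Molecule(atoms=atoms, bonds=BondSet(), source_format="pdb",
                   title=f"homomer {group.label} seed={seed}")
    if sigma > 0:
        mol = perturb(mol, sigma, seed=seed + 1)
    return mol
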