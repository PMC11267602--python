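"""Symmetry measures for protein homo-oligomers.

A homomer is an assembly of chemically identical chains whose ideal
symmetry is cyclic (a Cn rotation about the oligomer axis, or an improper
group for special arrangements).  The permutation space is structured:
chains permute among themselves (chain cycles must divide the group
order), and within a chain pair atoms correspond through the shared
residue sequence.  This module prepares a cleaned, equal-length-chain view
of a PDB-derived molecule, derives the sequence-based atom equivalence,
and searches chain permutations exhaustively (small multiplicities) with
per-chain-pair atom matching.

HETATM records (waters, ligands, glycans) are dropped during preparation;
input files are expected to be pre-cleaned of alternate locations and
sequence gaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .molio import Molecule, SelectionError
from .symmetry_core import (
    CSMError, CSMResult, EquivalencePartition, PointGroup,
    center_and_normalize, csm_for_permutation, generator_operation,
    optimal_axis, permutation_cycles, validate_permutation,
)

__all__ = ["Homomer", "PreparationError", "prepare_homomer",
           "sequence_equivalence", "chain_permutation_search",
           "trivial_protein_csm"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PreparationError(CSMError):
    """Chains are unequal or their sequences mismatch."""


@dataclass
class Homomer:
    """An equal-chain view of a homo-oligomer.

    ``chain_atoms[c]`` lists the atom indices (into ``molecule``) of chain
    ``chains[c]`` in file order; all chains have ``per_chain_length`` atoms
    with identical (residue ordinal, residue name, atom name, element)
    signatures.
    """

    molecule: Molecule
    chains: list[str]
    chain_atoms: list[list[int]]

    @property
    def per_chain_length(self) -> int:
        return len(self.chain_atoms[0])

    @property
    def n_chains(self) -> int:
        return len(self.chains)


def _chain_signature(mol: Molecule, atom_ids: Sequence[int]):
    """Per-atom signature used to verify that chains are equivalent:
    residue ordinal within the chain, residue name, atom name, element."""
    sig = []
    ordinal = -1
    last_seq = None
    for i in atom_ids:
        a = mol.atoms[i]
        if a.residue_seq != last_seq:
            ordinal += 1
            last_seq = a.residue_seq
        sig.append((ordinal, a.residue_name, a.atom_name, a.element))
    return sig


def prepare_homomer(mol: Molecule,
                    select_chains: Optional[Sequence[str]] = None,
                    select_res: Optional[Sequence[int]] = None,
                    use_backbone: bool = False) -> Homomer:
    """Build an equal-chain Homomer view of a PDB-derived molecule.

    Order of operations: drop HETATM records, keep ``select_chains``, keep
    the residue serials in ``select_res`` (the same set in every chain),
    then restrict to backbone atoms (N, CA, C, O) if ``use_backbone``.
    Raises :class:`PreparationError` naming the first mismatching residue
    if the surviving chains are not equivalent.
    """
    chain_ids: list[str] = []
    per_chain: dict[str, list[int]] = {}
    for i, a in enumerate(mol.atoms):
        if a.het:
            continue
        if a.chain_id is None or a.residue_seq is None or a.atom_name is None:
            raise PreparationError(
                f"atom {i + 1} lacks chain/residue metadata; protein mode "
                "requires a pdb-derived structure")
        if a.chain_id not in per_chain:
            per_chain[a.chain_id] = []
            chain_ids.append(a.chain_id)
        per_chain[a.chain_id].append(i)

    if select_chains is not None:
        for c in select_chains:
            if c not in per_chain:
                raise SelectionError(f"unknown chain id {c!r}")
        chain_ids = [c for c in chain_ids if c in set(select_chains)]
    if len(chain_ids) < 2:
        raise PreparationError("a homomer needs at least two chains")

    if select_res is not None:
        wanted = set(select_res)
        for c in chain_ids:
            per_chain[c] = [i for i in per_chain[c]
                            if mol.atoms[i].residue_seq in wanted]
    if use_backbone:
        for c in chain_ids:
            per_chain[c] = [i for i in per_chain[c]
                            if mol.atoms[i].atom_name in BACKBONE_ATOMS]

    for c in chain_ids:
        if not per_chain[c]:
            raise PreparationError(f"chain {c} has no atoms after selection")

    ref = _chain_signature(mol, per_chain[chain_ids[0]])
    for c in chain_ids[1:]:
        sig = _chain_signature(mol, per_chain[c])
        if sig != ref:
            for k, (x, y) in enumerate(zip(sig, ref)):
                if x != y:
                    raise PreparationError(
                        f"chain {c} differs from chain {chain_ids[0]} at "
                        f"residue ordinal {x[0]} ({x[1]} {x[2]} vs {y[1]} {y[2]})")
            raise PreparationError(
                f"chain {c} has {len(sig)} atoms but chain "
                f"{chain_ids[0]} has {len(ref)}")

    return Homomer(molecule=mol, chains=list(chain_ids),
                   chain_atoms=[per_chain[c] for c in chain_ids])


def sequence_equivalence(h: Homomer) -> EquivalencePartition:
    """Atoms are equivalent iff they share residue ordinal, residue type,
    atom name and element across chains: each class holds exactly one atom
    per chain.  Indices refer to the homomer's flat atom order (chain by
    chain)."""
    classes = [[c * h.per_chain_length + k for c in range(h.n_chains)]
               for k in range(h.per_chain_length)]
    return EquivalencePartition(classes, "sequence_based")


def homomer_molecule(h: Homomer) -> Molecule:
    """Flat, chain-ordered Molecule for the prepared selection."""
    from dataclasses import replace
    atoms = []
    for ids in h.chain_atoms:
        for i in ids:
            atoms.append(h.molecule.atoms[i])
    flat = [replace(a, index=k, position=a.position.copy())
            for k, a in enumerate(atoms)]
    return Molecule(atoms=flat, source_format=h.molecule.source_format,
                    model_index=h.molecule.model_index)


def _chain_perms(n_chains: int, group_h: int):
    """Chain permutations whose cycle lengths divide the group order."""
    for p in itertools.permutations(range(n_chains)):
        perm = np.array(p, dtype=int)
        if all(group_h % len(c) == 0 for c in permutation_cycles(perm)):
            yield perm


def _atom_perm_sequence(h: Homomer, chain_perm: np.ndarray) -> np.ndarray:
    """Atom permutation dictated by the sequence: the k-th atom of chain c
    maps to the k-th atom of chain chain_perm[c]."""
    L = h.per_chain_length
    perm = np.empty(h.n_chains * L, dtype=int)
    for c in range(h.n_chains):
        perm[c * L: (c + 1) * L] = chain_perm[c] * L + np.arange(L)
    return perm


def _atom_perm_assignment(h: Homomer, chain_perm: np.ndarray,
                          P: np.ndarray, op) -> np.ndarray:
    """Per-chain-pair Hungarian matching on rotated coordinates within
    (residue name, atom name, element) key groups.  Falls back to the
    sequence-dictated mapping if the result has an inadmissible cycle
    structure (can happen when a repeated residue type swaps)."""
    L = h.per_chain_length
    keys = [(a[1], a[2], a[3]) for a in
            _chain_signature(h.molecule, h.chain_atoms[0])]
    groups: dict[tuple, list[int]] = {}
    for k, key in enumerate(keys):
        groups.setdefault(key, []).append(k)
    rotated = P @ op.matrix.T
    perm = np.empty(h.n_chains * L, dtype=int)
    for c in range(h.n_chains):
        t = int(chain_perm[c])
        for members in groups.values():
            src = np.asarray([c * L + k for k in members])
            dst = np.asarray([t * L + k for k in members])
            diff = rotated[src][:, None, :] - P[dst][None, :, :]
            cost = np.sum(diff * diff, axis=-1)
            rows, cols = linear_sum_assignment(cost)
            perm[src[rows]] = dst[cols]
    return perm


def chain_permutation_search(h: Homomer, group: PointGroup,
                             atom_mode: str = "assignment",
                             weights: str = "uniform") -> CSMResult:
    """Search chain permutations (exhaustively for <= 8 chains; Hungarian
    on chain centroids above) together with the atom permutation, refining
    the axis analytically for each candidate; returns the best result."""
    mol = homomer_molecule(h)
    geom = center_and_normalize(mol, weights=weights)
    gh = group.group_order_h

    if h.n_chains <= 8:
        chain_perms = list(_chain_perms(h.n_chains, gh))
    else:
        chain_perms = [_centroid_chain_perm(h, geom, group)]
    if not chain_perms:
        raise CSMError(
            f"no chain permutation of {h.n_chains} chains has cycle "
            f"lengths dividing the group order {gh}")

    best = None
    best_chain = None
    for cp in chain_perms:
        perm = _atom_perm_sequence(h, cp)
        op, value = optimal_axis(geom, perm, group)
        if atom_mode == "assignment":
            for _ in range(3):
                cand = _atom_perm_assignment(h, cp, geom.coords, op)
                if not all(gh % len(c) == 0 for c in permutation_cycles(cand)):
                    break
                op2, v2 = optimal_axis(geom, cand, group)
                if v2 < value - 1e-12:
                    perm, op, value = cand, op2, v2
                else:
                    break
        elif atom_mode != "sequence_dictated":
            raise ValueError(f"unknown atom_mode {atom_mode!r}")
        if best is None or value < best[0] - 1e-13:
            best = (value, perm)
            best_chain = cp
    res = csm_for_permutation(geom, best[1], group,
                              algorithm=f"chain-search({atom_mode})")
    res.stats["chain_permutation"] = best_chain.tolist()
    res.stats["chains"] = h.chains
    res.stats["n_chain_perms"] = len(chain_perms)
    return res


def _centroid_chain_perm(h: Homomer, geom, group: PointGroup) -> np.ndarray:
    """Hungarian match of rotated chain centroids (large multiplicities)."""
    L = h.per_chain_length
    cents = np.stack([geom.coords[c * L:(c + 1) * L].mean(axis=0)
                      for c in range(h.n_chains)])
    # use the best axis of the sequence-dictated identity chain order
    op, _ = optimal_axis(geom, _atom_perm_sequence(
        h, np.arange(h.n_chains)), group)
    rot = cents @ op.matrix.T
    diff = rot[:, None, :] - cents[None, :, :]
    rows, cols = linear_sum_assignment(np.sum(diff * diff, axis=-1))
    perm = np.empty(h.n_chains, dtype=int)
    perm[rows] = cols
    gh = group.group_order_h
    if not all(gh % len(c) == 0 for c in permutation_cycles(perm)):
        return np.arange(h.n_chains)
    return perm


def trivial_protein_csm(h: Homomer, group: PointGroup,
                        use_chains: bool = False,
                        weights: str = "uniform") -> CSMResult:
    """Identity-permutation CSM of the prepared homomer; with
    ``use_chains`` the chain permutation is searched but the atom
    permutation stays sequence-dictated."""
    if use_chains:
        return chain_permutation_search(h, group,
                                        atom_mode="sequence_dictated",
                                        weights=weights)
    mol = homomer_molecule(h)
    geom = center_and_normalize(mol, weights=weights)
    perm = np.arange(len(mol.atoms))
    res = csm_for_permutation(geom, perm, group, algorithm="trivial")
    res.stats["chains"] = h.chains
    return res
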