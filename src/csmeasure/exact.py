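"""Exact CSM by enumeration of admissible atom permutations.

Permutations are built class-by-class as products of cycles whose lengths
divide the group order h, in a fixed deterministic order (classes ascending
by their smallest atom index; within a class, cycle lengths ascending and
cycle members chosen lexicographically), so ties between equal-valued
permutations always resolve the same way.  Under ``keep_structure`` a
partial cycle is abandoned as soon as any already-assigned bonded pair
maps to a non-bonded pair (or vice versa) — the pruning that makes the
connectivity-preserving search tractable for larger molecules.
"""

from __future__ import annotations

import time
from typing import Iterator, Optional, Sequence

import numpy as np

from .symmetry_core import (
    CSMError, CSMResult, EquivalencePartition, InvalidPermutationError,
    PointGroup, center_and_normalize, csm_for_permutation, optimal_axis,
    partition_all_equivalent, partition_by_element,
    partition_by_element_and_connectivity, validate_permutation,
)

__all__ = ["enumerate_valid_permutations", "exact_csm", "SearchTimeoutError"]


class SearchTimeoutError(CSMError):
    """The permutation scan exceeded its time budget."""

    def __init__(self, timeout: float, examined: int):
        self.timeout = timeout
        self.examined = examined
        super().__init__(
            f"permutation search abandoned after {timeout:g} s "
            f"({examined} permutations examined); use keep-structure, "
            f"remove-hy or the approximate approach")


def enumerate_valid_permutations(partition: EquivalencePartition,
                                 group: PointGroup,
                                 bonds=None,
                                 keep_structure: bool = False) -> Iterator[np.ndarray]:
    """Yield every admissible permutation exactly once (see module docs)."""
    if keep_structure and bonds is None:
        raise ValueError("keep_structure requires a bond set")
    h = group.group_order_h
    n = sum(len(c) for c in partition.classes)
    divisors = [L for L in range(1, h + 1) if h % L == 0]
    classes = sorted((sorted(c) for c in partition.classes), key=lambda c: c[0])

    adj = None
    if keep_structure:
        adj = np.zeros((n, n), dtype=bool)
        for i, j in bonds.edges:
            adj[i, j] = adj[j, i] = True

    perm = np.full(n, -1, dtype=int)
    assigned: list[int] = []  # atoms whose image is set, in assignment order

    def can_assign(i: int, j: int) -> bool:
        if adj is None:
            return True
        for a in assigned:
            if adj[i, a] != adj[j, perm[a]]:
                return False
        return True

    def assign(i: int, j: int) -> bool:
        if not can_assign(i, j):
            return False
        perm[i] = j
        assigned.append(i)
        return True

    def unassign():
        perm[assigned.pop()] = -1

    def gen_class(ci: int, remaining: list[int]) -> Iterator[np.ndarray]:
        if not remaining:
            nxt = ci + 1
            if nxt == len(classes):
                yield perm.copy()
            else:
                yield from gen_class(nxt, classes[nxt])
            return
        i0 = remaining[0]
        rest = remaining[1:]
        for L in divisors:
            if L - 1 > len(rest):
                break
            if L == 1:
                if assign(i0, i0):
                    yield from gen_class(ci, rest)
                    unassign()
            else:
                yield from grow_cycle(ci, i0, i0, [], L, rest)

    def grow_cycle(ci: int, start: int, current: int, members: list[int],
                   L: int, rest: list[int]) -> Iterator[np.ndarray]:
        # members: cycle atoms chosen after start, in order
        if len(members) == L - 1:
            if assign(current, start):
                left = [a for a in rest if a not in members]
                yield from gen_class(ci, left)
                unassign()
            return
        for j in rest:
            if j in members:
                continue
            if assign(current, j):
                yield from grow_cycle(ci, start, j, members + [j], L, rest)
                unassign()

    if n == 0:
        return
    yield from gen_class(0, classes[0])


def count_valid_permutations(partition, group, bonds=None,
                             keep_structure: bool = False) -> int:
    return sum(1 for _ in enumerate_valid_permutations(
        partition, group, bonds, keep_structure))


def exact_csm(mol, group: PointGroup,
              keep_structure: bool = False,
              ignore_sym: bool = False,
              use_perm: Optional[Sequence[int]] = None,
              timeout: float = 300.0,
              weights: str = "uniform") -> CSMResult:
    """Minimal CSM over all admissible permutations (or a supplied one).

    ``use_perm`` bypasses the scan with a specific 0-based permutation
    (validated first).  ``ignore_sym`` treats all atoms as equivalent,
    turning the measure into a pure shape descriptor.  ``keep_structure``
    restricts the scan to bond-graph automorphisms and requires the
    molecule to carry bonds.
    """
    geom = center_and_normalize(mol, weights=weights)
    n = len(mol.atoms)
    partition = partition_all_equivalent(n) if ignore_sym \
        else partition_by_element(mol)
    bonds = mol.bonds

    tag = "exact"
    if keep_structure:
        if bonds is None or len(bonds) == 0:
            raise CSMError("keep-structure requires connectivity data "
                           "(file bonds, a connectivity file, or inference)")
        tag += "+keep-structure"
    if ignore_sym:
        tag += "+ignore-sym"

    if use_perm is not None:
        p = np.asarray(use_perm, dtype=int)
        if sorted(p.tolist()) != list(range(n)):
            raise InvalidPermutationError("supplied permutation is not a "
                                          f"bijection on 1..{n}")
        if not validate_permutation(p, group, partition):
            raise InvalidPermutationError(
                "supplied permutation has a cycle length that does not "
                f"divide the group order {group.group_order_h}, or mixes "
                "non-equivalent atoms")
        if keep_structure and not validate_permutation(
                p, group, partition, bonds, keep_structure=True):
            raise InvalidPermutationError(
                "supplied permutation breaks the molecular connectivity")
        res = csm_for_permutation(geom, p, group, algorithm=tag + "+use-perm")
        res.stats["permutations_examined"] = 1
        return res

    enum_partition = partition
    if keep_structure and not ignore_sym:
        # refinement never excludes a bond-preserving permutation
        enum_partition = partition_by_element_and_connectivity(mol, bonds)

    deadline = time.monotonic() + timeout
    best_value = np.inf
    best_perm = None
    examined = 0
    for p in enumerate_valid_permutations(enum_partition, group, bonds,
                                          keep_structure):
        examined += 1
        _, value = optimal_axis(geom, p, group)
        if value < best_value - 1e-13:
            best_value = value
            best_perm = p
        if examined % 64 == 0 and time.monotonic() > deadline:
            raise SearchTimeoutError(timeout, examined)
    if best_perm is None:
        raise CSMError(f"no admissible permutation exists for {group.label}")
    res = csm_for_permutation(geom, best_perm, group, algorithm=tag)
    res.stats["permutations_examined"] = examined
    return res
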