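"""Approximate CSM for large molecules: the direction-permutation loop.

Candidate symmetry-axis directions seed an alternating refinement: for the
current axis, an atom permutation is built by assignment of each atom to
its image under the generator operation (Hungarian, greedy, or a
bond-aware greedy), then the axis is re-optimized analytically for that
permutation.  The best (value, permutation, axis) over all starts is
returned.  The result is an upper bound on the exact minimum, since every
candidate permutation is admissible and scored with the same functional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .symmetry_core import (
    CSMResult, EquivalencePartition, GroupKind, PointGroup,
    center_and_normalize, csm_for_permutation, generator_operation,
    optimal_axis, partition_all_equivalent, partition_by_element,
    permutation_cycles,
)

__all__ = ["DirectionSet", "fibonacci_sphere", "cartesian_directions",
           "assignment_for_direction", "refine", "approx_csm"]


@dataclass
class DirectionSet:
    """Unit start directions for the axis search."""

    vectors: list
    source: str

    def __post_init__(self):
        self.vectors = [np.asarray(v, float) / np.linalg.norm(v)
                        for v in self.vectors]

    def __len__(self):
        return len(self.vectors)

    def union(self, other: "DirectionSet") -> "DirectionSet":
        return DirectionSet(list(self.vectors) + list(other.vectors),
                            f"{self.source}+{other.source}")


def cartesian_directions() -> DirectionSet:
    return DirectionSet([np.array([1.0, 0.0, 0.0]),
                         np.array([0.0, 1.0, 0.0]),
                         np.array([0.0, 0.0, 1.0])], "cartesian3")


def fibonacci_sphere(n: int) -> DirectionSet:
    """n deterministic near-uniform unit vectors on the golden-angle
    spiral lattice."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    vecs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return DirectionSet(list(vecs), f"fibonacci({n})")


def _repair_cycles(perm: np.ndarray, h: int) -> np.ndarray:
    """Collapse cycles whose length does not divide h into fixed points
    (the conservative repair: the result is always admissible)."""
    out = perm.copy()
    for cyc in permutation_cycles(perm):
        if h % len(cyc):
            for a in cyc:
                out[a] = a
    return out


def assignment_for_direction(geom, op, partition: EquivalencePartition,
                             algorithm: str = "hungarian",
                             bonds=None) -> np.ndarray:
    """Build a permutation matching each rotated atom op·P_i to an atom
    P_j of the same equivalence class, then repair it to a valid cycle
    structure.

    hungarian: minimum-total-squared-distance assignment per class.
    greedy: repeatedly commit the closest unmatched (i, j) pair.
    structure_priority: greedy by distance, but a pairing that breaks bond
    preservation against already-committed pairs is rejected (leftovers
    are matched by plain distance).
    """
    P = geom.coords
    rotated = P @ op.matrix.T  # row i = op · P_i
    n = len(P)
    perm = np.full(n, -1, dtype=int)

    if algorithm == "hungarian":
        for cls in partition.classes:
            idx = np.asarray(cls, dtype=int)
            diff = rotated[idx][:, None, :] - P[idx][None, :, :]
            cost = np.sum(diff * diff, axis=-1)
            rows, cols = linear_sum_assignment(cost)
            perm[idx[rows]] = idx[cols]
    elif algorithm in ("greedy", "structure_priority"):
        pairs = []
        for ci, cls in enumerate(partition.classes):
            idx = np.asarray(cls, dtype=int)
            diff = rotated[idx][:, None, :] - P[idx][None, :, :]
            cost = np.sum(diff * diff, axis=-1)
            for a in range(len(idx)):
                for b in range(len(idx)):
                    pairs.append((cost[a, b], int(idx[a]), int(idx[b])))
        pairs.sort()
        adj = None
        if algorithm == "structure_priority":
            if bonds is None:
                raise ValueError("structure_priority requires a bond set")
            adj = np.zeros((n, n), dtype=bool)
            for i, j in bonds.edges:
                adj[i, j] = adj[j, i] = True
        src_free = np.ones(n, dtype=bool)
        dst_free = np.ones(n, dtype=bool)
        committed: list[int] = []

        def bond_ok(i, j):
            return all(adj[i, a] == adj[j, perm[a]] for a in committed)

        for rounds in range(2):
            for c, i, j in pairs:
                if not (src_free[i] and dst_free[j]):
                    continue
                if adj is not None and rounds == 0 and not bond_ok(i, j):
                    continue
                perm[i] = j
                src_free[i] = dst_free[j] = False
                committed.append(i)
            if src_free.sum() == 0 or adj is None:
                break
    else:
        raise ValueError(f"unknown assignment algorithm {algorithm!r}")

    return _repair_cycles(perm, op_order(op))


def op_order(op) -> int:
    """Group order h of the cyclic group generated by ``op``."""
    n = max(1, int(round(2 * np.pi / op.angle)))
    if op.improper and n % 2:
        return 2 * n  # S1 (mirror), generally odd rotoreflections close at 2n
    return n


def refine(geom, group: PointGroup, start_axis, algorithm: str = "hungarian",
           tol: float = 1e-10, max_iter: int = 50,
           partition: Optional[EquivalencePartition] = None,
           bonds=None) -> CSMResult:
    """Alternate assignment and analytic axis optimization from one start
    direction; returns the best state visited (its value trace, recorded in
    ``stats['trace']``, is non-increasing)."""
    if partition is None:
        raise ValueError("refine requires an equivalence partition")
    axis = np.asarray(start_axis, float)
    axis = axis / np.linalg.norm(axis)
    best_value = np.inf
    best_perm = None
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        op = generator_operation(group, axis)
        perm = assignment_for_direction(geom, op, partition, algorithm, bonds)
        op_new, value = optimal_axis(geom, perm, group)
        if value < best_value - tol:
            best_value = value
            best_perm = perm
            trace.append(value)
            axis = op_new.axis
        else:
            converged = True
            break
    res = csm_for_permutation(geom, best_perm, group,
                              algorithm=f"approx({algorithm})")
    res.converged = converged
    res.stats["trace"] = trace
    return res


def approx_csm(mol, group: PointGroup,
               algorithm: str = "hungarian",
               directions: Optional[DirectionSet] = None,
               tol: float = 1e-10, max_iter: int = 50,
               ignore_sym: bool = False,
               weights: str = "uniform") -> CSMResult:
    """Best direction-permutation result over a set of start directions.

    For proper rotations of order > 2 both axis orientations are tried
    (the generator and its inverse).  Deterministic for fixed options.
    """
    geom = center_and_normalize(mol, weights=weights)
    partition = partition_all_equivalent(len(mol.atoms)) if ignore_sym \
        else partition_by_element(mol)
    if directions is None or len(directions) == 0:
        directions = cartesian_directions()
    starts = list(directions.vectors)
    if group.kind is GroupKind.CN and group.order_n > 2:
        starts = starts + [-v for v in directions.vectors]
    best = None
    for v in starts:
        res = refine(geom, group, v, algorithm=algorithm, tol=tol,
                     max_iter=max_iter, partition=partition, bonds=mol.bonds)
        if best is None or res.value < best.value - 1e-13:
            best = res
    best.stats["n_starts"] = len(starts)
    best.stats["directions"] = directions.source
    return best
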