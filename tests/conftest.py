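"""Shared fixtures and independent oracles.

The oracle helpers below deliberately re-derive everything from first
principles (Rodrigues rotation, explicit group averaging, grid + simplex
axis search, full N! permutation scans) so that they share no code path
with the package's analytic axis optimization or pruned enumeration.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from csmeasure import PointGroup, partition_by_element, validate_permutation

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, max_examples=25,
                              derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


# --------------------------------------------------------------------------
# independent oracle

def oracle_rotation(axis, theta):
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return (np.eye(3) * np.cos(theta) + np.sin(theta) * K
            + (1 - np.cos(theta)) * np.outer(a, a))


def oracle_generator(group, axis):
    M = oracle_rotation(axis, 2 * np.pi / group.order_n)
    if group.improper:
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        M = M @ (np.eye(3) - 2 * np.outer(a, a))
    return M


def oracle_nearest(P, perm, group, axis):
    """Group-average by explicit matrix inversion and index chasing."""
    h = group.group_order_h
    M = oracle_generator(group, axis)
    Minv = np.linalg.inv(M)
    Q = np.zeros_like(P)
    cur = np.eye(3)
    idx = np.arange(len(P))
    for _ in range(h):
        Q += (cur @ P[idx].T).T
        idx = np.asarray(perm)[idx]
        cur = cur @ Minv
    return Q / h


def oracle_value(P, perm, group, axis):
    Q = oracle_nearest(P, perm, group, axis)
    return 100.0 * np.sum((P - Q) ** 2) / np.sum(P * P)


def _fib_axes(n):
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z * z)
    phi = np.pi * (3 - np.sqrt(5)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], 1)


_GRID = _fib_axes(600)


def oracle_axis_min(P, perm, group, grid=None):
    """Dense direction grid followed by a Nelder-Mead polish in spherical
    angles; returns the minimal value over all axes."""
    grid = _GRID if grid is None else grid
    vals = [oracle_value(P, perm, group, ax) for ax in grid]
    best_ax = grid[int(np.argmin(vals))]

    def f(ang):
        th, ph = ang
        ax = np.array([np.sin(th) * np.cos(ph),
                       np.sin(th) * np.sin(ph), np.cos(th)])
        return oracle_value(P, perm, group, ax)

    th0 = np.arccos(np.clip(best_ax[2], -1, 1))
    ph0 = np.arctan2(best_ax[1], best_ax[0])
    r = minimize(f, [th0, ph0], method="Nelder-Mead",
                 options=dict(xatol=1e-10, fatol=1e-14, maxiter=400))
    return min(float(r.fun), float(min(vals)))


def brute_force_csm(mol, group, partition=None, bonds=None,
                    keep_structure=False):
    """Minimum over every admissible permutation of the full N! scan,
    with grid+polish axis optimization per permutation."""
    P = mol.coords - mol.coords.mean(axis=0)
    part = partition_by_element(mol) if partition is None else partition
    best = np.inf
    for p in itertools.permutations(range(len(mol.atoms))):
        pa = np.array(p)
        if not validate_permutation(pa, group, part, bonds=bonds,
                                    keep_structure=keep_structure):
            continue
        best = min(best, oracle_axis_min(P, pa, group))
    return best


@pytest.fixture(scope="session")
def small_groups():
    return [PointGroup.parse(s) for s in
            ("cs", "ci", "c2", "c3", "c4", "s4", "s6", "c6")]
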