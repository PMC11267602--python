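"""Core machinery for continuous symmetry measures of cyclic point groups.

A continuous symmetry measure (CSM) quantifies how far a structure is from
the nearest structure possessing a given point-group symmetry G, on a scale
from 0 (exactly G-symmetric) to 100.  For centered coordinates ``P`` and the
nearest G-symmetric coordinates ``Q``::

    S(G) = 100 * sum_i ||P_i - Q_i||^2 / sum_i ||P_i||^2

Only cyclic groups are treated: Cn (proper n-fold rotation), Sn
(n-fold rotoreflection, n even), Cs (mirror, handled as S1) and Ci
(inversion, handled as S2).  The continuous chirality measure (CCM) is the
minimum of S over the achiral groups S1, S2, S4, S6, ... up to ``sn_max``.

Given a fixed atom permutation sigma whose cycle lengths divide the group
order h, the nearest symmetric structure is the group average

    Q_i = (1/h) * sum_{k=0}^{h-1} G^{-k} P_{sigma^k(i)}

which is the orthogonal projection of P (as a vector in R^{3N}) onto the
fixed subspace of the operator P -> G^{-1} P_sigma.  Projection gives
S/100 = 1 - f(axis) / (h * |P|^2) with the overlap

    f(m) = sum_k sum_i  < P_i, G(m)^{-k} P_{sigma^k(i)} >

which is a (quadratic + linear) form in the unit axis m; its maximum over
the sphere is found analytically from the eigen-decomposition of the
quadratic part (a trust-region-style secular equation).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# errors

class CSMError(Exception):
    """Base class for errors raised by this package."""


class DegenerateGeometryError(CSMError):
    """All atoms coincide; the measure is undefined."""


class InvalidPermutationError(CSMError):
    """A permutation violates the group / partition / connectivity rules."""


class PointGroupError(CSMError):
    """Unrecognized or unsupported point-group label."""


# --------------------------------------------------------------------------
# point groups

class GroupKind(enum.Enum):
    CS = "CS"
    CI = "CI"
    CN = "CN"
    SN = "SN"
    CH = "CH"


@dataclass(frozen=True)
class PointGroup:
    """A cyclic target point group.

    ``order_n`` is the n of Cn/Sn (1 for Cs = S1, 2 for Ci = S2) and
    ``group_order_h`` the number of group elements generated: n for Cn and
    even Sn, 2 for Cs and Ci.  ``CH`` is the chirality meta-group; it must
    be expanded (see :meth:`expand_achiral`) before any computation.
    """

    kind: GroupKind
    order_n: int

    def __post_init__(self):
        if self.kind is GroupKind.CN and self.order_n < 2:
            raise PointGroupError("Cn requires n >= 2")
        if self.kind is GroupKind.SN and (self.order_n < 4 or self.order_n % 2):
            raise PointGroupError("Sn requires even n >= 4")

    @property
    def group_order_h(self) -> int:
        if self.kind in (GroupKind.CS, GroupKind.CI):
            return 2
        if self.kind is GroupKind.CH:
            raise PointGroupError("Ch must be expanded into Sn subgroups first")
        return self.order_n

    @property
    def improper(self) -> bool:
        return self.kind in (GroupKind.CS, GroupKind.CI, GroupKind.SN)

    @property
    def label(self) -> str:
        return {
            GroupKind.CS: "Cs",
            GroupKind.CI: "Ci",
            GroupKind.CN: f"C{self.order_n}",
            GroupKind.SN: f"S{self.order_n}",
            GroupKind.CH: "Ch",
        }[self.kind]

    @classmethod
    def parse(cls, label: str) -> "PointGroup":
        """Parse a case-insensitive group label: cs, ci, c2, c3, ..., s4, s6, ..., ch."""
        s = label.strip().lower()
        if s == "cs":
            return cls(GroupKind.CS, 1)
        if s == "ci":
            return cls(GroupKind.CI, 2)
        if s == "ch":
            return cls(GroupKind.CH, 0)
        m = re.fullmatch(r"([cs])(\d+)", s)
        if not m:
            raise PointGroupError(f"unrecognized point-group label: {label!r}")
        n = int(m.group(2))
        if m.group(1) == "c":
            if n == 1:
                raise PointGroupError("C1 is trivial; every structure has it")
            return cls(GroupKind.CN, n)
        if n == 1:
            return cls(GroupKind.CS, 1)
        if n == 2:
            return cls(GroupKind.CI, 2)
        return cls(GroupKind.SN, n)

    def expand_achiral(self, sn_max: int) -> list["PointGroup"]:
        """The achiral subgroups S1, S2, S4, S6, ... up to sn_max (CCM menu)."""
        if sn_max < 2:
            raise PointGroupError("sn_max must be >= 2")
        groups = [PointGroup(GroupKind.CS, 1), PointGroup(GroupKind.CI, 2)]
        groups += [PointGroup(GroupKind.SN, n) for n in range(4, sn_max + 1, 2)]
        return groups


# --------------------------------------------------------------------------
# symmetry operations

@dataclass(frozen=True)
class SymmetryOperation:
    """Generator operation of a cyclic group: rotation (or rotoreflection)
    by ``angle`` about the unit vector ``axis``."""

    axis: np.ndarray
    angle: float
    improper: bool
    matrix: np.ndarray


def generator_operation(group: PointGroup, axis: Sequence[float]) -> SymmetryOperation:
    """Generator of ``group`` about ``axis`` (normalized internally).

    Cn: proper rotation by 2*pi/n.  Sn: rotation by 2*pi/n composed with
    reflection through the plane normal to the axis.  Cs: pure reflection
    (S1).  Ci: inversion (S2; the axis is immaterial).
    """
    if group.kind is GroupKind.CH:
        raise PointGroupError("Ch must be expanded into Sn subgroups first")
    m = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(m)
    if nrm == 0:
        raise ValueError("axis must be a nonzero vector")
    m = m / nrm
    angle = 2 * np.pi / group.order_n
    R = Rotation.from_rotvec(angle * m).as_matrix()
    if group.improper:
        M = R @ (np.eye(3) - 2.0 * np.outer(m, m))
    else:
        M = R
    return SymmetryOperation(axis=m, angle=angle, improper=group.improper, matrix=M)


# --------------------------------------------------------------------------
# geometry

@dataclass
class CenteredGeometry:
    """Coordinates referred to the structure's centroid.

    ``norm_sq`` is the squared Frobenius norm sum_i ||P_i||^2 that
    normalizes the measure.  Produced by :func:`center_and_normalize`;
    the dataclass itself does not recenter, so a caller may evaluate the
    functional in an externally chosen frame.
    """

    coords: np.ndarray
    norm_sq: float
    centering_weights: str = "uniform"


def geometry_from_coords(coords: np.ndarray, recenter: bool = True,
                         weights: Optional[np.ndarray] = None) -> CenteredGeometry:
    P = np.array(coords, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coords must be an N x 3 array")
    kind = "uniform"
    if recenter:
        if weights is None:
            centroid = P.mean(axis=0)
        else:
            w = np.asarray(weights, float)
            centroid = (w[:, None] * P).sum(axis=0) / w.sum()
            kind = "mass"
        P = P - centroid
    norm_sq = float(np.sum(P * P))
    if norm_sq <= 1e-20:
        raise DegenerateGeometryError("all atoms coincide at a single point")
    return CenteredGeometry(coords=P, norm_sq=norm_sq, centering_weights=kind)


def center_and_normalize(mol, weights: str = "uniform") -> CenteredGeometry:
    """Translate the (uniform or mass-weighted) centroid to the origin.

    ``mol`` may be a Molecule (from :mod:`csmeasure.molio`) or an N x 3
    array.  Uniform weighting is the default: the measure is a pure-geometry
    descriptor; mass weighting is available for compatibility with the
    center-of-mass convention.
    """
    coords = getattr(mol, "coords", None)
    if coords is None:
        coords = np.asarray(mol, dtype=float)
    if weights == "uniform":
        return geometry_from_coords(coords, recenter=True)
    if weights == "mass":
        from .molio import atomic_masses
        return geometry_from_coords(coords, recenter=True, weights=atomic_masses(mol))
    raise ValueError(f"unknown weighting {weights!r}")


# --------------------------------------------------------------------------
# equivalence partitions

@dataclass
class EquivalencePartition:
    """Disjoint atom classes within which permutation is allowed."""

    classes: list[list[int]]
    basis: str  # element_only | all_equivalent | element_and_connectivity | sequence_based

    def class_of(self) -> np.ndarray:
        n = sum(len(c) for c in self.classes)
        out = np.full(n, -1, dtype=int)
        for ci, cls in enumerate(self.classes):
            for i in cls:
                out[i] = ci
        return out


def _sorted_classes(groups: dict) -> list[list[int]]:
    classes = [sorted(v) for v in groups.values()]
    classes.sort(key=lambda c: c[0])
    return classes


def partition_by_element(mol) -> EquivalencePartition:
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(mol.atoms):
        groups.setdefault(a.element, []).append(i)
    return EquivalencePartition(_sorted_classes(groups), "element_only")


def partition_all_equivalent(n_atoms: int) -> EquivalencePartition:
    return EquivalencePartition([list(range(n_atoms))], "all_equivalent")


def partition_by_element_and_connectivity(mol, bonds) -> EquivalencePartition:
    """Element classes refined by iterative neighbour-colour propagation.

    Two atoms can only be exchanged by a bond-graph automorphism if they
    have the same stable colour, so this refinement shrinks the search
    space without excluding any connectivity-preserving permutation.
    """
    n = len(mol.atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds.edges:
        adj[i].append(j)
        adj[j].append(i)
    colour = {i: mol.atoms[i].element for i in range(n)}
    for _ in range(n):
        new = {}
        for i in range(n):
            new[i] = (colour[i], tuple(sorted(colour[j] for j in adj[i])))
        # compress
        codes = {c: k for k, c in enumerate(sorted(set(new.values()), key=repr))}
        new = {i: codes[new[i]] for i in range(n)}
        if len(set(new.values())) == len(set(colour.values())):
            break
        colour = new
    groups: dict = {}
    for i in range(n):
        groups.setdefault(colour[i], []).append(i)
    return EquivalencePartition(_sorted_classes(groups), "element_and_connectivity")


# --------------------------------------------------------------------------
# permutation validity

def permutation_cycles(perm: np.ndarray) -> list[list[int]]:
    perm = np.asarray(perm, dtype=int)
    seen = np.zeros(len(perm), dtype=bool)
    cycles = []
    for i in range(len(perm)):
        if seen[i]:
            continue
        cyc = [i]
        seen[i] = True
        j = perm[i]
        while j != i:
            cyc.append(int(j))
            seen[j] = True
            j = perm[j]
        cycles.append(cyc)
    return cycles


def validate_permutation(perm, group: PointGroup, partition: EquivalencePartition,
                         bonds=None, keep_structure: bool = False) -> bool:
    """True iff ``perm`` is admissible for ``group``:

    (a) every cycle length divides the group order h;
    (b) each partition class maps into itself;
    (c) with ``keep_structure``, bonded pairs map to bonded pairs and
        non-bonded to non-bonded (a bond-graph automorphism).
    """
    perm = np.asarray(perm, dtype=int)
    h = group.group_order_h
    for cyc in permutation_cycles(perm):
        if h % len(cyc):
            return False
    class_of = partition.class_of()
    if np.any(class_of[perm] != class_of):
        return False
    if keep_structure:
        if bonds is None:
            raise ValueError("keep_structure requires a bond set")
        edges = {tuple(sorted(e)) for e in bonds.edges}
        mapped = {tuple(sorted((int(perm[i]), int(perm[j])))) for i, j in edges}
        if mapped != edges:
            return False
    return True


# --------------------------------------------------------------------------
# symmetrization and the functional

def symmetrize(geom: CenteredGeometry, perm, op: SymmetryOperation, h: int) -> np.ndarray:
    """Group-average the coordinates into the nearest (op, perm)-symmetric
    structure:  Q_i = (1/h) sum_k  op^{-k} P_{perm^k(i)}."""
    perm = np.asarray(perm, dtype=int)
    P = geom.coords
    Q = np.zeros_like(P)
    Mk = np.eye(3)  # op.matrix ** k
    sigma_k = np.arange(len(P))
    for _ in range(h):
        # row form of M^{-k} p  is  p @ (M^{-k}).T = p @ M^k  (orthogonal M)
        Q += P[sigma_k] @ Mk
        sigma_k = perm[sigma_k]
        Mk = Mk @ op.matrix
    return Q / h


def csm_functional(geom: CenteredGeometry, Q: np.ndarray) -> float:
    """100 * sum ||P_i - Q_i||^2 / sum ||P_i||^2."""
    d = geom.coords - Q
    return 100.0 * float(np.sum(d * d)) / geom.norm_sq


# --------------------------------------------------------------------------
# analytic axis optimization

def _overlap_quadratic(P: np.ndarray, perm: np.ndarray, group: PointGroup):
    """Coefficients (const, B, C) of the overlap f(m) = const + B.m + m'Cm.

    f(m) = sum_k sum_i <P_i, G(m)^{-k} P_{sigma^k(i)}> where G(m)^{-k} is a
    rotation by -2*pi*k/n about m, composed with the mirror through the
    plane normal to m when the group is improper and k is odd.  Using
    R(theta,m) = cos t I + sin t [m]x + (1-cos t) mm' and
    R(theta,m)(I-2mm') = cos t I + sin t [m]x - (1+cos t) mm'.
    """
    h = group.group_order_h
    alpha = 2 * np.pi / group.order_n
    const = 0.0
    B = np.zeros(3)
    C = np.zeros((3, 3))
    sigma_k = np.arange(len(P))
    for k in range(h):
        theta = -k * alpha
        c, s = np.cos(theta), np.sin(theta)
        odd_improper = group.improper and (k % 2 == 1)
        t = -(1.0 + c) if odd_improper else (1.0 - c)
        Pk = P[sigma_k]
        const += c * float(np.sum(P * Pk))
        # <a, [m]x b> = m . (b x a)
        B += s * np.cross(Pk, P).sum(axis=0)
        X = P.T @ Pk
        C += t * 0.5 * (X + X.T)
        sigma_k = perm[sigma_k]
    return const, B, C


def _max_quadratic_on_sphere(B: np.ndarray, C: np.ndarray):
    """Maximize m'Cm + B.m over unit vectors m (3x3 symmetric C).

    Solved from the stationary condition 2Cm + B = 2*lambda*m with
    lambda >= lambda_max(C) (the global maximum), via the secular equation
    in the eigenbasis of C; the degenerate "hard case" (B orthogonal to the
    top eigenspace) is handled explicitly.
    """
    evals, evecs = eigh(C)
    lmax = evals[-1]
    scale = max(1.0, float(np.abs(evals).max()), float(np.linalg.norm(B)))
    b = evecs.T @ B
    normb = np.linalg.norm(b)
    if normb <= 1e-13 * scale:
        m = evecs[:, -1]
        return m, float(lmax)

    top = np.isclose(evals, lmax, rtol=0.0, atol=1e-11 * scale)
    btop = float(np.linalg.norm(b[top]))

    def mvec(lam):
        return b / (2.0 * (lam - evals))

    def phi(lam):
        return float(np.sum(mvec(lam) ** 2))

    if btop > 1e-9 * normb:
        lo = lmax + 0.5 * btop
        hi = lmax + 0.5 * normb
        if hi <= lo or phi(lo) <= 1.0:
            lam = lo
        else:
            lam = brentq(lambda x: phi(x) - 1.0, lo, hi,
                         xtol=1e-15 * scale, rtol=8.9e-16)
        y = mvec(lam)
    else:
        # hard case: solve in the non-degenerate subspace at lambda = lmax
        y = np.where(top, 0.0, b / (2.0 * (lmax - np.where(top, 1.0, evals))))
        r = 1.0 - float(np.sum(y * y))
        if r >= 0.0:
            itop = np.argmax(top)
            y[itop] = np.sqrt(r)
        else:
            lo = lmax + 1e-14 * scale
            hi = lmax + 0.5 * normb + 1e-14 * scale
            lam = brentq(lambda x: phi(x) - 1.0, lo, hi,
                         xtol=1e-15 * scale, rtol=8.9e-16)
            y = mvec(lam)
    y = y / np.linalg.norm(y)
    m = evecs @ y
    val = float(y @ (evals * y) + b @ y)
    return m, val


def optimal_axis(geom: CenteredGeometry, perm, group: PointGroup):
    """Best symmetry-element direction for a fixed permutation.

    Returns ``(operation, value)`` where ``value`` is the CSM attained by
    the optimal axis.  For Ci the axis is immaterial; z is reported.
    """
    perm = np.asarray(perm, dtype=int)
    h = group.group_order_h
    const, B, C = _overlap_quadratic(geom.coords, perm, group)
    scale = max(1.0, geom.norm_sq)
    if np.linalg.norm(B) <= 1e-13 * scale and np.abs(C).max() <= 1e-13 * scale:
        # no axis dependence (e.g. inversion)
        m = np.array([0.0, 0.0, 1.0])
        f = const
    else:
        m, q = _max_quadratic_on_sphere(B, C)
        f = const + q
    value = 100.0 * (1.0 - f / (h * geom.norm_sq))
    value = max(value, 0.0)
    return generator_operation(group, m), value


# --------------------------------------------------------------------------
# results

@dataclass
class CSMResult:
    """Outcome of a CSM computation: the measure, the permutation attaining
    it, the symmetry-element direction, and the nearest symmetric structure."""

    value: float
    permutation: np.ndarray
    operation: SymmetryOperation
    nearest_structure: np.ndarray
    group: PointGroup
    algorithm: str
    subgroup_reported: Optional[PointGroup] = None
    converged: bool = True
    stats: dict = field(default_factory=dict)


def invert_permutation(perm: np.ndarray) -> np.ndarray:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv


def _canonical_axis_perm(axis: np.ndarray, perm: np.ndarray, group: PointGroup):
    """Normalize the axis sign (first non-negligible component positive).

    For n > 2 flipping the axis replaces the generator by its inverse, which
    pairs with the inverse permutation; (sigma, -m) and (sigma^-1, m) give
    identical overlap and nearest structure, so both are adjusted together.
    """
    nz = np.flatnonzero(np.abs(axis) > 1e-8)
    if len(nz) and axis[nz[0]] < 0:
        axis = -axis
        if group.order_n > 2:
            perm = invert_permutation(perm)
    return axis, perm


def csm_for_permutation(geom: CenteredGeometry, perm, group: PointGroup,
                        algorithm: str = "fixed-permutation") -> CSMResult:
    """CSM for a fixed permutation with analytic axis optimization."""
    perm = np.asarray(perm, dtype=int)
    op, _ = optimal_axis(geom, perm, group)
    axis, perm_c = _canonical_axis_perm(op.axis, perm, group)
    op = generator_operation(group, axis)
    h = group.group_order_h
    Q = symmetrize(geom, perm_c, op, h)
    value = csm_functional(geom, Q)
    return CSMResult(value=value, permutation=perm_c, operation=op,
                     nearest_structure=Q, group=group, algorithm=algorithm)


# --------------------------------------------------------------------------
# chirality

def ccm(mol, sn_max: int = 8,
        solver: Optional[Callable] = None, **solver_kwargs) -> CSMResult:
    """Continuous chirality measure: minimal CSM over the achiral groups
    S1 (= Cs), S2 (= Ci), S4, S6, ... up to ``sn_max``.

    ``solver(mol, group, **solver_kwargs) -> CSMResult`` defaults to the
    exact permutation search.  The returned result carries the winning
    subgroup in ``subgroup_reported``.
    """
    if solver is None:
        from .exact import exact_csm
        solver = exact_csm
    groups = PointGroup(GroupKind.CH, 0).expand_achiral(sn_max)
    best = None
    per_subgroup: dict[str, float] = {}
    errors = []
    for g in groups:
        try:
            res = solver(mol, g, **solver_kwargs)
        except CSMError as exc:  # keep going; aggregate if nothing works
            errors.append((g.label, exc))
            continue
        per_subgroup[g.label] = res.value
        if best is None or res.value < best.value:
            best = replace(res, subgroup_reported=g)
    if best is None:
        raise CSMError(f"all achiral subgroups failed: {errors}")
    best.algorithm += "+ccm"
    best.stats["per_subgroup"] = per_subgroup
    return best
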