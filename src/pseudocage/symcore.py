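"""Icosahedral rotation group and its symmetry axes.

Every placement and expansion step in the package is driven by the 60 proper
rotations of the icosahedron.  The frame convention is the crystallographic
"I" setting: the three two-fold axes lie along the Cartesian axes and one
five-fold axis lies in the xz-plane, tilted from +z by arctan(1/phi) where
phi is the golden ratio.  Icosahedron vertices sit at the cyclic permutations
of (0, +/-1, +/-phi), normalized to the unit sphere.

Tolerances: 1e-9 for construction-time orthogonality/determinant checks,
1e-6 for membership/equality tests (double-precision products accumulate
error well below 1e-12 per composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

PHI = (1.0 + np.sqrt(5.0)) / 2.0

_CONSTRUCT_TOL = 1e-9
_MEMBER_TOL = 1e-6


@dataclass(frozen=True)
class RotationOperator:
    """A proper rotation, stored as a 3x3 orthogonal matrix with det +1.

    ``order`` is the smallest positive integer n with matrix**n == identity.
    """

    matrix: np.ndarray
    order: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if abs(np.linalg.det(m) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1")
        if np.max(np.abs(m @ m.T - np.eye(3))) > 1e-6:
            raise ValueError("rotation matrix must be orthogonal")

    def compose(self, other: "RotationOperator") -> "RotationOperator":
        m = self.matrix @ other.matrix
        return RotationOperator(m, _matrix_order(m))

    def inverse(self) -> "RotationOperator":
        return RotationOperator(self.matrix.T, self.order)

    @property
    def angle_deg(self) -> float:
        """Rotation angle in [0, 180] degrees, from the trace formula."""
        c = (np.trace(self.matrix) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def axis(self) -> np.ndarray | None:
        """Canonical-sign rotation axis, or None for the identity."""
        if self.order == 1:
            return None
        return _rotation_axis(self.matrix)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.matrix.T


@dataclass(frozen=True)
class Axis:
    """Undirected symmetry axis with canonical sign.

    The first non-zero component of ``direction`` is positive, so that the
    set of axes of each order has a unique, reproducible representation.
    """

    direction: np.ndarray
    order: int

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > _CONSTRUCT_TOL:
            d = d / n
        object.__setattr__(self, "direction", _canonical_sign(d))
        if self.order not in (2, 3, 5):
            raise ValueError(f"unsupported axis order {self.order}")


@dataclass(frozen=True)
class SymmetryGroup:
    """The icosahedral rotation group I (order 60)."""

    operators: tuple[RotationOperator, ...]
    frame: str = (
        "two-fold axes along x, y, z; one five-fold axis in the xz-plane "
        "tilted from +z by arctan(1/phi); vertices at cyclic permutations "
        "of (0, +/-1, +/-phi) / |(0, 1, phi)|"
    )

    def __len__(self) -> int:
        return len(self.operators)

    def matrices(self) -> np.ndarray:
        return np.stack([op.matrix for op in self.operators])


def _canonical_sign(d: np.ndarray) -> np.ndarray:
    for x in d:
        if abs(x) > 1e-8:
            return d if x > 0 else -d
    raise ValueError("zero vector has no canonical sign")


def _matrix_order(m: np.ndarray, max_order: int = 10) -> int:
    p = np.eye(3)
    for n in range(1, max_order + 1):
        p = p @ m
        if np.max(np.abs(p - np.eye(3))) < _MEMBER_TOL:
            return n
    raise ValueError("matrix is not a low-order rotation")


def _rotation_axis(m: np.ndarray) -> np.ndarray:
    """Axis of a non-identity rotation, canonical sign."""
    angle = np.arccos(np.clip((np.trace(m) - 1.0) / 2.0, -1.0, 1.0))
    if abs(angle - np.pi) > 1e-6:
        a = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
        a = a / (2.0 * np.sin(angle))
    else:
        # 180 degrees: m = 2 a a^T - I
        aat = (m + np.eye(3)) / 2.0
        k = int(np.argmax(np.diag(aat)))
        a = aat[:, k] / np.sqrt(aat[k, k])
    return _canonical_sign(a / np.linalg.norm(a))


def icosahedron_vertices() -> np.ndarray:
    """The 12 unit vertices in the declared frame, deterministically ordered."""
    raw = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            raw.append((0.0, s1, s2 * PHI))
            raw.append((s1, s2 * PHI, 0.0))
            raw.append((s2 * PHI, 0.0, s1))
    v = np.array(sorted(raw))
    return v / np.linalg.norm(v[0])


def _axis_rotation(direction: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``direction`` by ``angle`` radians (Rodrigues)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    k = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def icosahedral_rotations() -> SymmetryGroup:
    """The 60 proper rotations of the icosahedron.

    Generated by closure from a five-fold and a two-fold rotation, then
    ordered deterministically: identity first, remainder sorted by
    (axis class, lexicographic canonical axis direction, rotation angle).
    """
    v = icosahedron_vertices()
    # a vertex (five-fold pole) and the two-fold along +z
    g5 = _axis_rotation(v[np.argmax(v[:, 2])], 2 * np.pi / 5)
    g2 = np.diag([-1.0, -1.0, 1.0])

    elements: list[np.ndarray] = [np.eye(3)]

    def known(m: np.ndarray) -> bool:
        return any(np.max(np.abs(m - e)) < _MEMBER_TOL for e in elements)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (g5, g2):
                p = g @ m
                if not known(p):
                    elements.append(p)
                    nxt.append(p)
        frontier = nxt
    if len(elements) != 60:
        raise RuntimeError(f"closure produced {len(elements)} elements, expected 60")

    ops = [RotationOperator(m, _matrix_order(m)) for m in elements]

    def sort_key(op: RotationOperator):
        if op.order == 1:
            return (0, (), 0.0)
        ax = op.axis()
        # axis class = cyclic order of the axis (2, 3 or 5)
        angle = op.angle_deg
        # measure the angle as a signed rotation about the canonical axis so
        # that e.g. 72 and 288 degree rotations about one pole sort apart
        signed = _signed_angle_about(op.matrix, ax)
        return (op.order, tuple(np.round(ax, 9)), signed)

    ops.sort(key=sort_key)
    return SymmetryGroup(tuple(ops))


def _signed_angle_about(m: np.ndarray, axis: np.ndarray) -> float:
    """Angle in [0, 360) of rotation m about the given (canonical) axis."""
    # build any unit vector orthogonal to axis
    t = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(t, axis)) > 0.9:
        t = np.array([0.0, 1.0, 0.0])
    u = t - np.dot(t, axis) * axis
    u = u / np.linalg.norm(u)
    w = m @ u
    ang = np.degrees(np.arctan2(np.dot(np.cross(u, w), axis), np.dot(u, w)))
    return float(ang % 360.0)


def symmetry_axes(group: SymmetryGroup, order: int) -> list[Axis]:
    """The undirected symmetry axes of the given order.

    6 five-fold, 10 three-fold and 15 two-fold axes (12, 20 and 30 directed
    poles respectively).
    """
    if order not in (2, 3, 5):
        raise ValueError(f"icosahedral axes have order 2, 3 or 5, not {order}")
    dirs: dict[tuple, np.ndarray] = {}
    for op in group.operators:
        if op.order == order:
            ax = op.axis()
            dirs[tuple(np.round(ax, 6))] = ax
    return [Axis(dirs[k], order) for k in sorted(dirs)]


def directed_poles(group: SymmetryGroup, order: int) -> np.ndarray:
    """Both poles of every axis of the given order, sorted lexicographically."""
    axes = symmetry_axes(group, order)
    poles = [a.direction for a in axes] + [-a.direction for a in axes]
    return np.array(sorted(map(tuple, np.round(poles, 12))))


def stabilizer(group: SymmetryGroup, axis: Axis) -> list[RotationOperator]:
    """The cyclic subgroup fixing ``axis`` (size == axis.order)."""
    d = axis.direction
    ops = [
        op
        for op in group.operators
        if np.max(np.abs(op.matrix @ d - d)) < _MEMBER_TOL
    ]
    if len(ops) != axis.order:
        raise ValueError(
            f"direction {d} is not an order-{axis.order} symmetry axis "
            f"(stabilizer size {len(ops)})"
        )
    return ops


def to_biomt(group: SymmetryGroup) -> str:
    """Operators as a PDB REMARK 350 BIOMT text block (zero translations)."""
    lines = []
    for n, op in enumerate(group.operators, start=1):
        for row in range(3):
            r = op.matrix[row]
            lines.append(
                f"REMARK 350   BIOMT{row + 1} {n:3d}"
                f"{r[0]:10.6f}{r[1]:10.6f}{r[2]:10.6f}{0.0:15.5f}"
            )
    return "\n".join(lines) + "\n"


def to_pdbx_oper_list(group: SymmetryGroup) -> str:
    """Operators as mmCIF ``_pdbx_struct_oper_list``-style loop text."""
    lines = [
        "loop_",
        "_pdbx_struct_oper_list.id",
        "_pdbx_struct_oper_list.type",
    ]
    for i in range(3):
        for j in range(3):
            lines.append(f"_pdbx_struct_oper_list.matrix[{i + 1}][{j + 1}]")
        lines.append(f"_pdbx_struct_oper_list.vector[{i + 1}]")
    for n, op in enumerate(group.operators, start=1):
        fields = [str(n), "'point symmetry operation'"]
        for i in range(3):
            fields.extend(f"{op.matrix[i, j]:.9f}" for j in range(3))
            fields.append("0.0")
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def rotation_matrix_about(direction: Iterable[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis by an arbitrary angle."""
    return _axis_rotation(
        np.asarray(list(direction), dtype=float), np.radians(angle_deg)
    )


def frame_from_z_x(z_dir: np.ndarray, x_hint: np.ndarray) -> np.ndarray:
    """Right-handed rotation matrix whose columns are (x', y', z').

    z' is the unit ``z_dir``; x' is ``x_hint`` orthogonalized against z'.
    Maps local +z to ``z_dir`` and local +x into the plane toward ``x_hint``.
    """
    z = np.asarray(z_dir, dtype=float)
    z = z / np.linalg.norm(z)
    x = np.asarray(x_hint, dtype=float)
    x = x - np.dot(x, z) * z
    n = np.linalg.norm(x)
    if n < 1e-9:
        raise ValueError("x_hint is parallel to z_dir")
    x = x / n
    y = np.cross(z, x)
    return np.column_stack([x, y, z])
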