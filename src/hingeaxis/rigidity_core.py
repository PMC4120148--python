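"""Rigidity matrices and infinitesimal motion spaces.

The rigidity matrix encodes the first-order behavior of the constraints;
its null space is the (infinitesimal) motion space. For body-bar-hinge
frameworks each body contributes six columns ordered
``(ω_x, ω_y, ω_z, v_x, v_y, v_z)`` — a twist per body — and

* a bar contributes one row equating the projections of its two endpoint
  velocities onto the bar direction,
* a hinge contributes five rows forcing the relative twist of its two
  bodies into the line spanned by ``(d, a×d)`` (rotation about the hinge
  axis through point ``a`` with direction ``d``),
* pinning a body contributes six rows zeroing that body's twist.

Degrees of freedom = dimension of the null space after pinning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .frameworks import BarJointFramework, BBHFramework

logger = logging.getLogger(__name__)

__all__ = [
    "RigidityMatrix",
    "MotionSpace",
    "bar_joint_matrix",
    "bbh_matrix",
    "pin",
    "null_space",
    "hinge_twist",
    "SV_TOLERANCE",
]

#: Relative singular-value threshold separating numerical zeros from rank.
SV_TOLERANCE = 1e-8


@dataclass
class RigidityMatrix:
    """Constraint rows over per-body twist (or per-joint velocity) columns."""

    array: np.ndarray  # (n_rows, n_cols)
    n_bodies: int  # bodies (BBH) or joints (bar-joint)
    cols_per_body: int  # 6 for BBH, `dimension` for bar-joint
    row_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.array = np.atleast_2d(np.asarray(self.array, dtype=float))
        expected = self.n_bodies * self.cols_per_body
        if self.array.shape[1] != expected:
            raise ValueError(
                f"matrix has {self.array.shape[1]} columns, expected {expected}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape

    def rank(self, tol: float = SV_TOLERANCE) -> int:
        if self.array.size == 0 or not self.array.any():
            return 0
        s = scipy.linalg.svdvals(self.array)
        return int(np.sum(s > tol * s[0]))


@dataclass
class MotionSpace:
    """Orthonormal basis of the rigidity matrix's null space.

    ``d`` is the number of degrees of freedom; ``basis`` has shape
    ``(d, n_cols)``, one motion (all bodies' twists concatenated) per row.
    """

    d: int
    basis: np.ndarray
    n_bodies: int
    cols_per_body: int = 6

    def body_twist(self, vector: np.ndarray, body: int) -> np.ndarray:
        """Slice the 6-block (or dim-block) of one body out of a motion vector."""
        c = self.cols_per_body
        return np.asarray(vector)[body * c : (body + 1) * c]


def bar_joint_matrix(
    framework: BarJointFramework,
    pin_joints: set[int] | frozenset[int] | None = None,
    pin_bar: int | None = None,
) -> RigidityMatrix:
    """Rigidity matrix of a bar-joint framework.

    One row per bar with coefficients ``(p - q)`` on joint p's velocity
    columns and ``(q - p)`` on joint q's. Pinning fixes all velocity
    components of the given joints (``pin_bar`` pins both endpoints of
    that bar, grounding it and removing the trivial motions).
    """
    dim = framework.dimension
    n = framework.n_joints
    pins: set[int] = set(pin_joints or ())
    if pin_bar is not None:
        i, j = framework.bars[pin_bar]
        pins |= {i, j}

    rows = []
    labels = []
    for k, (i, j) in enumerate(framework.bars):
        p, q = framework.joints[i], framework.joints[j]
        u = p - q
        if np.linalg.norm(u) < 1e-12:
            raise ValueError(f"zero-length bar between joints {i} and {j}")
        row = np.zeros(n * dim)
        row[i * dim : (i + 1) * dim] = u
        row[j * dim : (j + 1) * dim] = -u
        rows.append(row)
        labels.append(f"bar{k}({i},{j})")
    for j in sorted(pins):
        for c in range(dim):
            row = np.zeros(n * dim)
            row[j * dim + c] = 1.0
            rows.append(row)
            labels.append(f"pin(joint{j},{'xyz'[c]})")
    return RigidityMatrix(np.array(rows), n_bodies=n, cols_per_body=dim, row_labels=labels)


def hinge_twist(axis_point, axis_direction) -> np.ndarray:
    """The twist ``(d, a×d)`` of a unit rotation about the hinge line."""
    a = np.asarray(axis_point, float)
    d = np.asarray(axis_direction, float)
    return np.concatenate([d, np.cross(a, d)])


def _bar_row_blocks(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient 6-blocks of a bar row for body a (at p) and body b (at q)."""
    u = p - q
    return np.concatenate([np.cross(p, u), u]), np.concatenate([-np.cross(q, u), -u])


def _hinge_rows(h_twist: np.ndarray) -> np.ndarray:
    """Five orthonormal rows spanning the orthogonal complement of a twist line."""
    t = h_twist / np.linalg.norm(h_twist)
    # complete t to an orthonormal basis of R^6; rows 2..6 are the complement
    basis = scipy.linalg.null_space(t[None, :])  # (6, 5), orthonormal columns
    return basis.T


def bbh_matrix(framework: BBHFramework) -> RigidityMatrix:
    """Rigidity matrix of a body-bar-hinge framework (no pinning rows)."""
    n = framework.n
    rows = []
    labels = []
    for k, bar in enumerate(framework.bars):
        p = np.asarray(bar.point_a, float)
        q = np.asarray(bar.point_b, float)
        if np.linalg.norm(p - q) < 1e-12:
            raise ValueError(f"bar {k} has coincident endpoints")
        block_a, block_b = _bar_row_blocks(p, q)
        row = np.zeros(6 * n)
        row[6 * bar.body_a : 6 * bar.body_a + 6] = block_a
        row[6 * bar.body_b : 6 * bar.body_b + 6] = block_b
        rows.append(row)
        labels.append(f"bar{k}({bar.body_a},{bar.body_b})")
    for k, h in enumerate(framework.hinges):
        t = hinge_twist(h.axis_point, h.axis_direction)
        if np.linalg.norm(t[:3]) < 1e-12:
            raise ValueError(f"hinge {k} has a degenerate axis direction")
        for r, prow in enumerate(_hinge_rows(t)):
            row = np.zeros(6 * n)
            # relative twist t_b - t_a must lie in span{t}: P (t_b - t_a) = 0
            row[6 * h.body_b : 6 * h.body_b + 6] = prow
            row[6 * h.body_a : 6 * h.body_a + 6] = -prow
            rows.append(row)
            labels.append(f"hinge{k}({h.body_a},{h.body_b})[{r}]")
    if not rows:
        rows = [np.zeros(6 * n)]
        labels = ["empty"]
    return RigidityMatrix(np.array(rows), n_bodies=n, cols_per_body=6, row_labels=labels)


def pin(matrix: RigidityMatrix, body: int) -> RigidityMatrix:
    """Append six identity rows zeroing the twist of one body."""
    if not (0 <= body < matrix.n_bodies):
        raise ValueError(f"body id {body} out of range")
    if matrix.cols_per_body != 6:
        raise ValueError("pin() applies to body frameworks (6 columns per body)")
    extra = np.zeros((6, matrix.shape[1]))
    for c in range(6):
        extra[c, 6 * body + c] = 1.0
    return RigidityMatrix(
        np.vstack([matrix.array, extra]),
        n_bodies=matrix.n_bodies,
        cols_per_body=matrix.cols_per_body,
        row_labels=matrix.row_labels + [f"pin(body{body},{i})" for i in range(6)],
    )


def null_space(matrix: RigidityMatrix, tol: float = SV_TOLERANCE) -> MotionSpace:
    """Orthonormal null-space basis via SVD.

    The degrees of freedom ``d`` count singular values below
    ``tol * max_singular_value`` plus any column deficit. The basis is
    deterministic: right singular vectors in SVD order, each scaled so its
    first entry of largest magnitude is positive.
    """
    a = matrix.array
    m, ncols = a.shape
    if a.size == 0 or not a.any():
        basis = np.eye(ncols)
    else:
        _, s, vh = scipy.linalg.svd(a, full_matrices=True)
        rank = int(np.sum(s > tol * s[0]))
        basis = vh[rank:]
    # deterministic sign: largest-|entry| component made positive
    fixed = []
    for b in basis:
        k = int(np.argmax(np.abs(b)))
        fixed.append(b if b[k] >= 0 else -b)
    basis = np.array(fixed) if fixed else np.zeros((0, ncols))
    return MotionSpace(
        d=len(basis),
        basis=basis,
        n_bodies=matrix.n_bodies,
        cols_per_body=matrix.cols_per_body,
    )


def dof_rank(framework: BBHFramework, pinned: int | None = None) -> int:
    """Degrees of freedom from the matrix rank (the algebraic oracle).

    Without pinning, the six trivial rigid-body motions are subtracted:
    ``6n - 6 - rank``. With a pinned body the result is the pinned
    null-space dimension.
    """
    m = bbh_matrix(framework)
    if pinned is not None:
        return null_space(pin(m, pinned)).d
    return 6 * framework.n - 6 - m.rank()
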