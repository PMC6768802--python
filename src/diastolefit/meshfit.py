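"""Least-squares propagation of tensor-product cubic-Hermite meshes.

A cubic-Hermite (CH) mesh stores, per node and per field component, a value
degree of freedom plus derivative DOFs with respect to the unit local
coordinates — 2 per node in 1D, 4 in 2D, 8 in 3D. Shared nodes give C1
continuity across element faces by construction.

Given material points with fixed embedded local coordinates and tracked
Lagrangian displacements z between frames, the mesh at a new frame is the
standard linear least-squares solve

    U_i = (H^T H)^-1 H^T (H U_j + z),

where H is the sparse shape matrix of CH basis values at the embedded
coordinates. The solve is per field component; an optional per-point weight
vector and optional Tikhonov regularization are supported.

Derivative DOFs are parameterized with respect to the unit local coordinate
(no arc-length scaling), so the solve needs no per-element scale
bookkeeping; local coordinates live in [0, 1]^d.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import IllPosedFitError, ValidationError

__all__ = [
    "HermiteMesh",
    "TrackedPoints",
    "ShapeMatrix",
    "ResidualStats",
    "hermite_basis_1d",
    "shape_matrix",
    "propagate_mesh",
    "fit_residual",
]

logger = logging.getLogger(__name__)


def hermite_basis_1d(t: np.ndarray) -> np.ndarray:
    """The four cubic Hermite functions on [0, 1].

    Returns shape ``t.shape + (2, 2)`` indexed by [node (0=left, 1=right),
    dof kind (0=value, 1=derivative)].
    """
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape + (2, 2))
    t2, t3 = t * t, t * t * t
    out[..., 0, 0] = 2.0 * t3 - 3.0 * t2 + 1.0
    out[..., 0, 1] = t3 - 2.0 * t2 + t
    out[..., 1, 0] = -2.0 * t3 + 3.0 * t2
    out[..., 1, 1] = t3 - t2
    return out


def _hermite_basis_deriv_1d(t: np.ndarray) -> np.ndarray:
    """First derivatives of the four Hermite cubics w.r.t. t."""
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape + (2, 2))
    t2 = t * t
    out[..., 0, 0] = 6.0 * t2 - 6.0 * t
    out[..., 0, 1] = 3.0 * t2 - 4.0 * t + 1.0
    out[..., 1, 0] = -6.0 * t2 + 6.0 * t
    out[..., 1, 1] = 3.0 * t2 - 2.0 * t
    return out


@dataclass
class HermiteMesh:
    """Tensor-product cubic-Hermite mesh.

    Parameters
    ----------
    dim : spatial dimension of the element local coordinates (1, 2 or 3).
    n_nodes : node count M.
    elements : (n_el, 2**dim) integer node connectivity; corners ordered
        lexicographically over the local axes (np.ndindex order).
    dofs : (n_fields, n_nodes * 2**dim) DOF matrix, node-major; within a
        node the 2**dim derivative-flag combinations are in np.ndindex
        order ((0,..,0) = value DOF first).
    """

    dim: int
    n_nodes: int
    elements: np.ndarray
    dofs: np.ndarray

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=int)
        self.dofs = np.atleast_2d(np.asarray(self.dofs, dtype=float))
        if self.dim not in (1, 2, 3):
            raise ValidationError("dim must be 1, 2 or 3")
        if self.elements.ndim != 2 or self.elements.shape[1] != 2**self.dim:
            raise ValidationError(
                f"elements must be (n_el, {2**self.dim}) for dim={self.dim}"
            )
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValidationError("element connectivity references invalid nodes")
        if self.dofs.shape[1] != self.n_dof:
            raise ValidationError(
                f"dofs must have {self.n_dof} columns, got {self.dofs.shape[1]}"
            )

    @property
    def dof_per_node(self) -> int:
        return 2**self.dim

    @property
    def n_dof(self) -> int:
        """Scalar-field DOF count (per field component)."""
        return self.n_nodes * self.dof_per_node

    @property
    def n_fields(self) -> int:
        return self.dofs.shape[0]

    def with_dofs(self, dofs: np.ndarray) -> "HermiteMesh":
        return HermiteMesh(self.dim, self.n_nodes, self.elements, dofs)


@dataclass
class TrackedPoints:
    """Material points embedded in a mesh with tracked displacements.

    ``element_id`` (N,), ``xi`` (N, dim) in [0, 1]^dim, and optional
    Lagrangian displacements ``displacements`` (N, n_fields) in mm.
    """

    element_id: np.ndarray
    xi: np.ndarray
    displacements: np.ndarray | None = None

    def __post_init__(self):
        self.element_id = np.asarray(self.element_id, dtype=int)
        self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        if self.xi.shape[0] != len(self.element_id):
            raise ValidationError("element_id / xi length mismatch")
        if np.any(self.xi < 0.0) or np.any(self.xi > 1.0):
            raise ValidationError("local coordinates must lie in [0, 1]^d")
        if self.displacements is not None:
            self.displacements = np.atleast_2d(
                np.asarray(self.displacements, dtype=float)
            )
            if self.displacements.shape[0] != len(self.element_id):
                raise ValidationError("displacements length mismatch")

    def __len__(self) -> int:
        return len(self.element_id)

    def dof_ratio(self, mesh: HermiteMesh) -> float:
        """Data-to-DOF ratio d*N / (2**d * M); the fit regime wants >> 1."""
        return self.xi.shape[1] * len(self) / mesh.n_dof


@dataclass
class ShapeMatrix:
    """Sparse matrix of CH basis values: rows = points, cols = scalar DOFs.

    The same matrix applies to every field component; the rows of the
    value-DOF columns sum to 1 (partition of unity).
    """

    matrix: sp.csr_matrix
    mesh: HermiteMesh

    @property
    def shape(self):
        return self.matrix.shape

    def evaluate(self, dofs: np.ndarray) -> np.ndarray:
        """Interpolant values at every embedded point, (N, n_fields)."""
        return (self.matrix @ np.atleast_2d(dofs).T)


def _deriv_flags(dim: int):
    return list(itertools.product((0, 1), repeat=dim))


def shape_matrix(
    mesh: HermiteMesh, pts: TrackedPoints, deriv_axis: int | None = None
) -> ShapeMatrix:
    """Assemble the sparse shape matrix at the embedded local coordinates.

    With ``deriv_axis`` set, basis functions are differentiated once along
    that local axis (used to verify C1 continuity).
    """
    d = mesh.dim
    if pts.xi.shape[1] != d:
        raise ValidationError(f"points have dim {pts.xi.shape[1]}, mesh has {d}")
    bad = (pts.element_id < 0) | (pts.element_id >= len(mesh.elements))
    if np.any(bad):
        raise ValidationError("point embedded in nonexistent element")

    n = len(pts)
    corners = _deriv_flags(d)  # corner multi-indices, same enumeration
    flags = _deriv_flags(d)
    basis = [
        hermite_basis_1d(pts.xi[:, k]) if deriv_axis != k else _hermite_basis_deriv_1d(pts.xi[:, k])
        for k in range(d)
    ]

    dpn = mesh.dof_per_node
    point_rows = np.arange(n)
    rows, cols, vals = [], [], []
    for ci, corner in enumerate(corners):
        node = mesh.elements[pts.element_id, ci]
        for fi, flag in enumerate(flags):
            v = np.ones(n)
            for k in range(d):
                v = v * basis[k][:, corner[k], flag[k]]
            rows.append(point_rows)
            cols.append(node * dpn + fi)
            vals.append(v)
    m = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, mesh.n_dof),
    )
    return ShapeMatrix(matrix=m, mesh=mesh)


def propagate_mesh(
    mesh_j: HermiteMesh,
    displacements: np.ndarray,
    h: ShapeMatrix,
    weights: np.ndarray | None = None,
    regularization: float = 0.0,
) -> HermiteMesh:
    """Least-squares DOF solve for the mesh at a new frame.

    Solves, per field component, ``U_i = (H^T W H + lam I)^-1 H^T W z`` with
    ``z = H U_j + displacements``. Default is unweighted (W = I); a diagonal
    per-point weight vector may be supplied. Rank deficiency with zero
    regularization raises :class:`IllPosedFitError`.
    """
    H = h.matrix
    n, n_dof = H.shape
    z = np.atleast_2d(np.asarray(displacements, dtype=float))
    if z.shape != (n, mesh_j.n_fields):
        raise ValidationError(
            f"displacements must be ({n}, {mesh_j.n_fields}), got {z.shape}"
        )
    targets = h.evaluate(mesh_j.dofs) + z

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValidationError("weights must be a nonnegative length-N vector")
        Hw = H.multiply(w[:, None]).tocsr()
    else:
        Hw = H
    hth = (Hw.T @ H).toarray()
    if regularization > 0.0:
        hth = hth + regularization * np.eye(n_dof)
        logger.info("propagate_mesh: Tikhonov regularization lambda=%g", regularization)
    else:
        if n < n_dof or np.linalg.matrix_rank(hth) < n_dof:
            raise IllPosedFitError(
                f"normal matrix is rank deficient ({n} points for {n_dof} DOFs); "
                "add tracked points or set regularization > 0"
            )
    rhs = Hw.T @ targets
    u_new = np.linalg.solve(hth, rhs)
    return mesh_j.with_dofs(u_new.T)


@dataclass
class ResidualStats:
    """Fit residual statistics (mm): componentwise mean and standard
    deviation, max point-residual norm, and the raw residual matrix."""

    mean: np.ndarray
    std: np.ndarray
    max: float
    residuals: np.ndarray
    orthogonality: float  # max |H^T r|, normal-equation check

    def __str__(self):  # pragma: no cover - cosmetic
        return (
            f"residual mean={np.array2string(self.mean, precision=4)} mm, "
            f"sd={np.array2string(self.std, precision=4)} mm, max={self.max:.4g} mm"
        )


def fit_residual(
    mesh_i: HermiteMesh, targets: np.ndarray, h: ShapeMatrix
) -> ResidualStats:
    """Residuals of a fitted mesh against observed point positions."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    pred = h.evaluate(mesh_i.dofs)
    if targets.shape != pred.shape:
        raise ValidationError(f"targets must be {pred.shape}, got {targets.shape}")
    r = targets - pred
    ortho = float(np.abs(h.matrix.T @ r).max()) if r.size else 0.0
    return ResidualStats(
        mean=r.mean(axis=0),
        std=r.std(axis=0, ddof=0),
        max=float(np.linalg.norm(r, axis=1).max()) if len(r) else 0.0,
        residuals=r,
        orthogonality=ortho,
    )
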