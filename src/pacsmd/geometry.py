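"""Coordinate algebra: centres of mass, Kabsch superposition, RMSD, PCA,
convex hulls.

These primitives back every selection feature and post-processing tool:
RMSD-type features superpose on one atom group and measure on another,
distance features compare group centres of mass, edge-expansion selection
and the standard-state volume correction both rely on convex hulls
(computed with Quickhull via :mod:`scipy.spatial`).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "AtomGroup", "DegenerateFitError", "DegeneracyError", "Hull",
    "center_of_mass", "com_distance", "convex_hull", "pca_project", "rmsd",
    "rmsd_after_fit", "superpose", "apply_transform",
]


class DegenerateFitError(ValueError):
    """Fit group has fewer than three non-collinear atoms."""


class DegeneracyError(ValueError):
    """Point set is degenerate (coplanar/collinear) for hull construction."""


@dataclasses.dataclass(frozen=True)
class AtomGroup:
    """An ordered set of atom indices with per-atom masses (g/mol)."""

    indices: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        m = np.asarray(self.masses, dtype=float)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("atom indices must be unique")
        if np.any(idx < 0):
            raise ValueError("atom indices must be non-negative")
        if m.shape != idx.shape:
            raise ValueError("masses must match indices")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "masses", m)

    @classmethod
    def from_indices(cls, indices: Sequence[int],
                     masses: Sequence[float] | None = None) -> "AtomGroup":
        idx = np.asarray(indices, dtype=int)
        if masses is None:
            masses = np.ones(len(idx))
        return cls(idx, np.asarray(masses, dtype=float))

    def __len__(self) -> int:
        return len(self.indices)


def _check_group(coords: np.ndarray, group: AtomGroup) -> None:
    if len(group) == 0:
        raise ValueError("atom group is empty")
    if group.indices.max() >= coords.shape[0]:
        raise IndexError("atom group index out of bounds for structure")


def center_of_mass(coords: np.ndarray, group: AtomGroup) -> np.ndarray:
    """Mass-weighted mean position of a group, in nm."""
    coords = np.asarray(coords, dtype=float)
    _check_group(coords, group)
    w = group.masses / group.masses.sum()
    return w @ coords[group.indices]


def com_distance(coords: np.ndarray, group1: AtomGroup,
                 group2: AtomGroup) -> float:
    """Distance between the centres of mass of two groups (d_com, nm)."""
    return float(np.linalg.norm(center_of_mass(coords, group1)
                                - center_of_mass(coords, group2)))


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, reference: np.ndarray,
            weights: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R with ``reference ~ mobile @ R.T`` for
    centred coordinate sets (Kabsch via SVD, reflection corrected)."""
    h = (mobile * weights[:, None]).T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # flip the smallest singular direction if the best orthogonal matrix
    # would be a reflection
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, reference: np.ndarray, fit_group: AtomGroup,
              ref_fit_group: AtomGroup | None = None,
              mass_weighted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition transform of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` minimises the (optionally
    mass-weighted) squared deviation over the fit group.  The rotation is
    always proper (det = +1), also for mirror-image inputs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ref_fit_group is None:
        ref_fit_group = fit_group
    _check_group(mobile, fit_group)
    _check_group(reference, ref_fit_group)
    if len(fit_group) != len(ref_fit_group):
        raise ValueError("fit groups differ in size between mobile and "
                         "reference")
    if len(fit_group) < 3:
        raise DegenerateFitError("fit group needs at least 3 atoms")

    w = group_weights(fit_group, mass_weighted)
    p = mobile[fit_group.indices]
    q = reference[ref_fit_group.indices]
    pc = p - w @ p
    qc = q - w @ q
    # collinear points leave the rotation about the line undetermined
    if np.linalg.matrix_rank(pc, tol=1e-10 * max(1.0, np.abs(pc).max())) < 2:
        raise DegenerateFitError("fit group atoms are collinear")
    rot = _kabsch(pc, qc, w)
    trans = w @ q - (w @ p) @ rot.T
    return rot, trans


def group_weights(group: AtomGroup, mass_weighted: bool) -> np.ndarray:
    if mass_weighted:
        return group.masses / group.masses.sum()
    return np.full(len(group), 1.0 / len(group))


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd(mobile: np.ndarray, reference: np.ndarray, group: AtomGroup,
         ref_group: AtomGroup | None = None,
         mass_weighted: bool = False) -> float:
    """Plain (no-fit) RMSD over a group, in nm."""
    if ref_group is None:
        ref_group = group
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    _check_group(mobile, group)
    _check_group(reference, ref_group)
    if len(group) != len(ref_group):
        raise ValueError("RMSD groups differ in size between mobile and "
                         "reference")
    w = group_weights(group, mass_weighted)
    diff = mobile[group.indices] - reference[ref_group.indices]
    return float(np.sqrt(np.sum(w * np.sum(diff ** 2, axis=1))))


def rmsd_after_fit(mobile: np.ndarray, reference: np.ndarray,
                   fit_group: AtomGroup, rmsd_group: AtomGroup | None = None,
                   ref_fit_group: AtomGroup | None = None,
                   ref_rmsd_group: AtomGroup | None = None,
                   mass_weighted: bool = False) -> float:
    """RMSD over ``rmsd_group`` after best-fitting on ``fit_group``.

    The two groups may differ (fit on a rigid scaffold, measure on a mobile
    part).  ``ref_*`` groups remap atom indices when the reference structure
    is numbered differently.  RMSD is unweighted over the selected atoms by
    default; set ``mass_weighted`` to weight by atomic mass.
    """
    if rmsd_group is None:
        rmsd_group = fit_group
    if ref_rmsd_group is None:
        ref_rmsd_group = rmsd_group
    rot, trans = superpose(mobile, reference, fit_group,
                           ref_fit_group=ref_fit_group,
                           mass_weighted=mass_weighted)
    fitted = apply_transform(mobile, rot, trans)
    return rmsd(fitted, reference, rmsd_group, ref_group=ref_rmsd_group,
                mass_weighted=mass_weighted)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_project(points: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component projection.

    Returns ``(scores, axes)`` with ``axes`` the orthonormal eigenvectors
    (rows) of the unbiased covariance of ``points`` sorted by descending
    variance, and ``scores`` the centred projections.  Points are centred,
    not whitened.
    """
    points = np.asarray(points, dtype=float)
    m, d = points.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(m - 1, d):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound "
            f"min(M-1, D)={min(m - 1, d)}")
    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    axes = vt[:n_components]
    # deterministic sign: largest-magnitude loading positive
    for i, axis in enumerate(axes):
        j = int(np.argmax(np.abs(axis)))
        if axis[j] < 0:
            axes[i] = -axis
    scores = centred @ axes.T
    return scores, axes


# ---------------------------------------------------------------------------
# Convex hulls
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Hull:
    """Convex hull of a 2-D or 3-D point set.

    ``volume`` is the d-dimensional content (area in 2-D, volume in 3-D);
    ``facets`` are the Qhull facet equations ``[normal | offset]`` with
    ``normal . x + offset <= 0`` inside.
    """

    vertex_indices: np.ndarray
    volume: float
    facets: np.ndarray

    def distance_inside(self, points: np.ndarray) -> np.ndarray:
        """Distance of each point to the nearest facet plane (positive
        inside the hull, negative outside)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        signed = points @ self.facets[:, :-1].T + self.facets[:, -1]
        return -signed.max(axis=1)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self.distance_inside(points) >= -tol


def convex_hull(points: np.ndarray) -> Hull:
    """Convex hull via Quickhull; dimension must be 2 or 3."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise ValueError("points must be an (M, 2) or (M, 3) array")
    if points.shape[0] < points.shape[1] + 1:
        raise DegeneracyError(
            f"need at least {points.shape[1] + 1} points for a "
            f"{points.shape[1]}-D hull")
    try:
        qh = ConvexHull(points)
    except QhullError as exc:
        raise DegeneracyError(f"degenerate point set: {exc}") from None
    return Hull(vertex_indices=np.array(qh.vertices),
                volume=float(qh.volume),
                facets=np.array(qh.equations))
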