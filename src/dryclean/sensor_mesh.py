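"""Triangulated sensor surface and FEM discretization of the
Laplace–Beltrami operator.

The electrode cap is an open surface (disk topology), so the mesh is built
by Delaunay triangulation of a 2D parameterization of the positions — an
azimuthal-equidistant projection for (approximately) spherical caps, or the
principal plane for flat layouts — and the triangles are mapped back to the
3D vertices.  Linear (P1) finite elements then give the standard cotangent
stiffness matrix and the consistent mass matrix:

    S_ij = -1/2 (cot α_ij + cot β_ij)   for an edge ij shared by triangles
           with opposite angles α_ij, β_ij; diagonal = -Σ_j S_ij,
    M_e  = (A/12) [[2,1,1],[1,2,1],[1,1,2]]  per triangle of area A.

Natural (Neumann) boundary conditions are used: nothing is added on the
open boundary, so constant fields remain in the null space of S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["SensorMesh", "triangulate", "assemble_fem"]


@dataclass
class SensorMesh:
    """Triangle mesh over sensor positions with optional FEM matrices.

    ``vertices`` rows are in the same order as the recording channels the
    mesh was built from.  ``stiffness``/``mass`` are dense symmetric
    ``(n, n)`` arrays once :func:`assemble_fem` has run.
    """

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int, consistently oriented
    channel_names: list[str] | None = None
    stiffness: np.ndarray | None = None
    mass: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) int array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [0, 2]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def vertex_neighbors(self, index: int) -> np.ndarray:
        """Indices of vertices sharing an edge with ``index``."""
        e = self.edges()
        nb = np.concatenate([e[e[:, 0] == index, 1], e[e[:, 1] == index, 0]])
        return np.unique(nb)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def euler_characteristic(self) -> int:
        """V - E + F (equals 1 for a mesh with disk topology)."""
        return self.n_vertices - len(self.edges()) + self.n_triangles


def _project_2d(positions: np.ndarray) -> np.ndarray:
    """Parameterize cap-like 3D positions in the plane.

    Near-planar layouts are projected onto their principal plane; otherwise
    the points are treated as directions from the best-fit sphere center and
    mapped with an azimuthal-equidistant projection about their mean
    direction (the cap apex), which preserves neighborhood structure for
    open electrode caps.
    """
    pos = np.asarray(positions, dtype=float)
    centered = pos - pos.mean(axis=0)
    # principal axes; smallest singular value ~ 0 means coplanar
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * s[0]:
        raise ValueError("positions are collinear; cannot triangulate")
    if s[2] <= 1e-9 * s[0]:
        return centered @ vt[:2].T

    # best-fit sphere: ||p - c||^2 = r^2 is linear in (c, r^2 - |c|^2)
    A = np.hstack([2 * pos, np.ones((len(pos), 1))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    u3 = pos - center
    norms = np.linalg.norm(u3, axis=1)
    u3 = u3 / norms[:, None]
    pole = u3.mean(axis=0)
    pole /= np.linalg.norm(pole)
    # tangent basis at the pole
    ref = np.array([1.0, 0.0, 0.0])
    if abs(pole @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ pole) * pole
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    cos_t = np.clip(u3 @ pole, -1.0, 1.0)
    theta = np.arccos(cos_t)
    phi = np.arctan2(u3 @ e2, u3 @ e1)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def triangulate(positions: np.ndarray, channel_names: list[str] | None = None) -> SensorMesh:
    """Build the sensor-surface mesh (geometry only).

    Parameters
    ----------
    positions : ndarray, shape (n, 3)
        Electrode positions; row order defines vertex order.
    channel_names : list of str, optional
        Used for error messages and carried on the mesh.

    Raises
    ------
    ValueError
        If ``n < 4``, positions are collinear, or two electrodes coincide
        (the offending channels are named).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    n = pos.shape[0]
    if n < 4:
        raise ValueError("need at least 4 positions to build a surface mesh")
    names = channel_names if channel_names is not None else [str(i) for i in range(n)]

    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    scale2 = max(d2.max(), 1.0)
    iu = np.triu_indices(n, k=1)
    dup = np.where(d2[iu] < 1e-16 * scale2)[0]
    if dup.size:
        pairs = [f"{names[iu[0][k]]}/{names[iu[1][k]]}" for k in dup]
        raise ValueError(f"duplicate electrode positions: {', '.join(pairs)}")

    pts2 = _project_2d(pos)
    tri = Delaunay(pts2)
    triangles = tri.simplices.astype(np.int64)

    # drop degenerate slivers produced by the projection
    mesh = SensorMesh(vertices=pos, triangles=triangles, channel_names=list(names))
    areas = mesh.triangle_areas()
    keep = areas > 1e-12 * np.median(areas[areas > 0])
    triangles = triangles[keep]

    # consistent orientation: outward normals for caps (away from centroid),
    # +normal of the principal plane for flat layouts
    centroid = pos.mean(axis=0)
    v = pos
    normals = np.cross(v[triangles[:, 1]] - v[triangles[:, 0]],
                       v[triangles[:, 2]] - v[triangles[:, 0]])
    tri_centers = v[triangles].mean(axis=1)
    ref_dot = (normals * (tri_centers - centroid)).sum(axis=1)
    norm_scale = np.linalg.norm(normals, axis=1)
    if np.all(np.abs(ref_dot) < 1e-9 * norm_scale * np.linalg.norm(pos - centroid, axis=1).max()):
        # planar layout: centroid lies in the surface, so orient all
        # normals along the dominant triangle normal instead
        ref = normals[np.argmax(norm_scale)]
        ref_dot = normals @ ref
    flip = ref_dot < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    mesh = SensorMesh(vertices=pos, triangles=triangles, channel_names=list(names))
    used = np.unique(triangles)
    if used.size != n:
        missing = sorted(set(range(n)) - set(used.tolist()))
        raise ValueError(
            f"vertices not part of any triangle: {[names[i] for i in missing]}"
        )
    return mesh


def assemble_fem(mesh: SensorMesh, clamp_obtuse: bool = False) -> SensorMesh:
    """Fill ``mesh.stiffness`` and ``mesh.mass`` with P1-FEM matrices.

    Cotangents of obtuse angles are kept signed by default, which is the
    faithful FEM assembly; ``clamp_obtuse=True`` clips them at zero for
    pathological montages with very poor triangle quality.  Raises
    ``ValueError`` on zero-area triangles.
    """
    n = mesh.n_vertices
    S = np.zeros((n, n))
    M = np.zeros((n, n))
    v = mesh.vertices
    for tri in mesh.triangles:
        p = v[tri]
        e0 = p[2] - p[1]  # edge opposite vertex 0
        e1 = p[0] - p[2]
        e2 = p[1] - p[0]
        area = 0.5 * np.linalg.norm(np.cross(e2, -e1))
        if area <= 0:
            raise ValueError(f"zero-area triangle {tri.tolist()}")
        # cot of the angle at vertex k = (e_i . e_j)/(2 A) with signs fixed
        cots = np.array(
            [
                np.dot(-e1, e2),   # at vertex 0: edges to v1 (e2) and v2 (-e1)
                np.dot(-e2, e0),   # at vertex 1
                np.dot(-e0, e1),   # at vertex 2
            ]
        ) / (2.0 * area)
        if clamp_obtuse:
            cots = np.maximum(cots, 0.0)
        for k in range(3):
            i, j = tri[(k + 1) % 3], tri[(k + 2) % 3]
            w = 0.5 * cots[k]
            S[i, j] -= w
            S[j, i] -= w
            S[i, i] += w
            S[j, j] += w
        me = (area / 12.0) * (np.ones((3, 3)) + np.eye(3))
        M[np.ix_(tri, tri)] += me
    mesh.stiffness = S
    mesh.mass = M
    return mesh
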