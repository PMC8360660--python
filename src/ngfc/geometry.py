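"""Compartment-labeled membrane surfaces.

The signaling simulator runs on a closed triangulated dendritic surface in
which every face is labeled ``shaft`` or ``spine``. The package ships a
synthetic stand-in (see :func:`ngfc.synthetic_data.synth_dendrite`); real
meshes can be imported from OBJ/PLY with face groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import GeometryError

__all__ = ["MembraneGeometry"]

COMPARTMENTS = ("shaft", "spine")


@dataclass
class MembraneGeometry:
    """Closed triangulated surface with per-face compartment labels.

    Attributes
    ----------
    mesh : trimesh.Trimesh
        The surface (may contain several watertight bodies).
    face_labels : ndarray of str
        ``"shaft"`` or ``"spine"`` per face.
    spine_ids : ndarray of int
        Spine membership per face (-1 for shaft faces); spine faces with
        the same id belong to one connected spine.
    """

    mesh: trimesh.Trimesh
    face_labels: np.ndarray
    spine_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.face_labels = np.asarray(self.face_labels, dtype=object)
        n_faces = len(self.mesh.faces)
        if self.face_labels.shape != (n_faces,):
            raise GeometryError("face_labels must have one entry per face")
        unknown = set(np.unique(self.face_labels)) - set(COMPARTMENTS)
        if unknown:
            raise GeometryError(f"unknown compartment labels: {sorted(unknown)}")
        if self.spine_ids is None:
            self.spine_ids = np.where(self.face_labels == "spine", 0, -1)
        self.spine_ids = np.asarray(self.spine_ids, dtype=int)

    @property
    def n_spines(self) -> int:
        ids = self.spine_ids[self.spine_ids >= 0]
        return int(np.unique(ids).size)

    def area(self, compartment: str | None = None) -> float:
        """Total surface area (µm²), optionally of one compartment."""
        areas = self.mesh.area_faces
        if compartment is None:
            return float(areas.sum())
        if compartment not in COMPARTMENTS:
            raise GeometryError(f"unknown compartment {compartment!r}")
        return float(areas[self.face_labels == compartment].sum())

    def sample_surface(self, n: int, compartment: str, rng) -> np.ndarray:
        """Area-weighted random points on one compartment's faces."""
        mask = self.face_labels == compartment
        faces = np.flatnonzero(mask)
        if faces.size == 0:
            raise GeometryError(f"no faces labeled {compartment!r}")
        w = self.mesh.area_faces[faces]
        chosen = rng.choice(faces, size=n, p=w / w.sum())
        tri = self.mesh.triangles[chosen]
        r1, r2 = rng.random(n), rng.random(n)
        swap = r1 + r2 > 1
        r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
        pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (tri[:, 2] - tri[:, 0])
        return pts

    def nearest_face(self, points: np.ndarray):
        """Project points to the surface; return (projected, face indices)."""
        return _closest_on_mesh(self.mesh.triangles, np.atleast_2d(points))

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Compartment label of the nearest face of each point."""
        _, face_idx = self.nearest_face(np.atleast_2d(points))
        return self.face_labels[face_idx]


def _closest_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    ``tri``: (F, 3, 3) triangle vertices; ``p``: (M, 3) points.
    Returns (M, F, 3) closest points (standard barycentric region test).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p[:, None, :] - a[None, :, :]                 # (M, F, 3)
    d1 = np.einsum("fj,mfj->mf", ab, ap)
    d2 = np.einsum("fj,mfj->mf", ac, ap)
    bp = p[:, None, :] - b[None, :, :]
    d3 = np.einsum("fj,mfj->mf", ab, bp)
    d4 = np.einsum("fj,mfj->mf", ac, bp)
    cp = p[:, None, :] - c[None, :, :]
    d5 = np.einsum("fj,mfj->mf", ab, cp)
    d6 = np.einsum("fj,mfj->mf", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc_den = (d4 - d3) + (d5 - d6)
        w_bc = np.where(w_bc_den != 0, (d4 - d3) / w_bc_den, 0.0)

    out = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
    # edge BC region
    edge_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    pt_bc = b[None] + np.clip(w_bc, 0, 1)[..., None] * (c - b)[None]
    # edge AC region
    edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    pt_ac = a[None] + np.clip(w_ac, 0, 1)[..., None] * ac[None]
    # edge AB region
    edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    pt_ab = a[None] + np.clip(v_ab, 0, 1)[..., None] * ab[None]
    # vertex regions
    vert_a = (d1 <= 0) & (d2 <= 0)
    vert_b = (d3 >= 0) & (d4 <= d3)
    vert_c = (d6 >= 0) & (d5 <= d6)

    out = np.where(edge_bc[..., None], pt_bc, out)
    out = np.where(edge_ac[..., None], pt_ac, out)
    out = np.where(edge_ab[..., None], pt_ab, out)
    out = np.where(vert_c[..., None], np.broadcast_to(c[None], out.shape), out)
    out = np.where(vert_b[..., None], np.broadcast_to(b[None], out.shape), out)
    out = np.where(vert_a[..., None], np.broadcast_to(a[None], out.shape), out)
    return out


def _closest_on_mesh(triangles: np.ndarray, points: np.ndarray, chunk: int = 256):
    """Nearest surface point and face index for each query point."""
    best_pts = np.empty_like(points)
    best_face = np.empty(points.shape[0], dtype=int)
    for i0 in range(0, points.shape[0], chunk):
        p = points[i0 : i0 + chunk]
        cand = _closest_on_triangles(triangles, p)      # (m, F, 3)
        d2 = np.einsum("mfj,mfj->mf", cand - p[:, None, :], cand - p[:, None, :])
        idx = d2.argmin(axis=1)
        best_face[i0 : i0 + chunk] = idx
        best_pts[i0 : i0 + chunk] = cand[np.arange(p.shape[0]), idx]
    return best_pts, best_face
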