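"""Morphological indices of an aneurysm sac.

Given the dome mesh and a neck plane, computes the nine standard shape
indices used in rupture studies:

* DA — dome area (m², neck cap excluded)
* V_aneu — sac volume enclosed by dome + planar neck cap (m³)
* NSI — nonsphericity index, 1 − (18π)^{1/3} V^{2/3} / DA
  (0 for a hemisphere with an equatorial neck, larger for irregular sacs)
* H — height, the longest perpendicular distance from the neck plane
* W — width, the largest cross-section diameter parallel to the neck plane
* D_neck — neck diameter (max Feret diameter of the neck loop)
* HWR = H/W, AR = H/D_neck, BF = W/D_neck

The neck plane is a required input; automatic neck detection is out of
scope.  All indices are invariant under rigid motion, and lengths/areas/
volumes scale as s, s², s³ under uniform scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from .exceptions import OrientationError, TopologyError
from .mesh import TriSurfaceMesh

__all__ = [
    "NeckPlane",
    "MorphologyRecord",
    "neck_plane_from_loop",
    "dome_area",
    "dome_volume",
    "nsi",
    "height",
    "width",
    "neck_diameter",
    "morphology_record",
]


@dataclass
class NeckPlane:
    """Plane separating the sac from the parent vessel.

    ``normal`` is unit length and oriented toward the dome; ``loop`` holds
    the ordered vertex indices of the neck boundary.
    """

    point: np.ndarray  # (3,) m
    normal: np.ndarray  # (3,) unit
    loop: np.ndarray  # (k,) vertex indices

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float)
        self.normal = np.asarray(self.normal, float)
        nrm = np.linalg.norm(self.normal)
        if nrm == 0:
            raise ValueError("neck normal must be nonzero")
        self.normal = self.normal / nrm
        self.loop = np.asarray(self.loop, dtype=np.int64)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.point) @ self.normal

    def save(self, path) -> None:
        """Plain-text neck definition (point, normal, loop indices)."""
        with open(path, "w") as fh:
            fh.write("point: " + " ".join(f"{x:.17g}" for x in self.point) + "\n")
            fh.write("normal: " + " ".join(f"{x:.17g}" for x in self.normal) + "\n")
            fh.write("loop: " + " ".join(str(i) for i in self.loop) + "\n")

    @classmethod
    def load(cls, path) -> "NeckPlane":
        fields = {}
        with open(path) as fh:
            for line in fh:
                if ":" in line:
                    key, val = line.split(":", 1)
                    fields[key.strip()] = val.split()
        return cls(
            point=np.array(fields["point"], float),
            normal=np.array(fields["normal"], float),
            loop=np.array(fields["loop"], int),
        )


@dataclass
class MorphologyRecord:
    """The nine shape indices of one aneurysm (SI units)."""

    DA: float  # m²
    V_aneu: float  # m³
    NSI: float
    H: float  # m
    W: float  # m
    D_neck: float  # m
    HWR: float
    AR: float
    BF: float

    def as_dict(self) -> dict[str, float]:
        return {
            "DA": self.DA,
            "V_aneu": self.V_aneu,
            "NSI": self.NSI,
            "H": self.H,
            "W": self.W,
            "D_neck": self.D_neck,
            "HWR": self.HWR,
            "AR": self.AR,
            "BF": self.BF,
        }


def neck_plane_from_loop(mesh: TriSurfaceMesh, loop: np.ndarray) -> NeckPlane:
    """Best-fit plane through a neck loop, normal oriented toward the dome."""
    loop = np.asarray(loop, int)
    pts = mesh.vertices[loop]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    dome_centroid = mesh.vertices[mesh.dome_vertices].mean(axis=0)
    if (dome_centroid - centroid) @ normal < 0:
        normal = -normal
    return NeckPlane(point=centroid, normal=normal, loop=loop)


def _dome_face_indices(mesh: TriSurfaceMesh) -> np.ndarray:
    idx = np.flatnonzero(mesh.dome_faces)
    if idx.size == 0:
        raise ValueError("mesh has no dome-labeled faces")
    return idx


def _check_dome_connected(mesh: TriSurfaceMesh, faces_idx: np.ndarray) -> None:
    faces = mesh.faces[faces_idx]
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    fid = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, fid = edges[order], fid[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    rows, cols = fid[:-1][same], fid[1:][same]
    n = len(faces)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"dome region has {ncomp} edge-connected components; indices are "
            "computed on their union",
            stacklevel=3,
        )


def dome_area(mesh: TriSurfaceMesh) -> float:
    """Total area of dome-labeled triangles (m²); neck cap excluded."""
    idx = _dome_face_indices(mesh)
    _check_dome_connected(mesh, idx)
    return float(mesh.face_areas[idx].sum())


def _boundary_vertices(mesh: TriSurfaceMesh, faces_idx: np.ndarray) -> np.ndarray:
    faces = mesh.faces[faces_idx]
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def dome_volume(mesh: TriSurfaceMesh, neck: NeckPlane) -> float:
    """Sac volume enclosed by the dome plus a triangulated planar neck cap.

    The cap fans from the loop centroid; the signed volume of the closed
    surface is computed by the divergence theorem and returned as a
    magnitude (orientation is auto-repaired).
    """
    idx = _dome_face_indices(mesh)
    boundary = set(_boundary_vertices(mesh, idx).tolist())
    if boundary != set(neck.loop.tolist()):
        raise TopologyError(
            "dome boundary does not match the neck loop "
            f"({len(boundary)} boundary vs {len(neck.loop)} loop vertices)"
        )
    v = mesh.vertices
    centroid = v[neck.loop].mean(axis=0)
    tris = [v[mesh.faces[idx]]]  # (n_f, 3, 3)
    loop = neck.loop
    nxt = np.roll(loop, -1)
    cap = np.stack(
        [v[loop], v[nxt], np.broadcast_to(centroid, (len(loop), 3))], axis=1
    )
    tris.append(cap)
    allt = np.concatenate(tris)
    signed = np.einsum(
        "ij,ij->i", allt[:, 0], np.cross(allt[:, 1], allt[:, 2])
    ).sum() / 6.0
    return float(abs(signed))


def nsi(v_aneu: float, da: float) -> float:
    """Nonsphericity index 1 − (18π)^{1/3} V^{2/3} / A.

    With A the cap-excluded dome area, a hemisphere scores exactly 0
    because (18π)^{1/3}(2π/3)^{2/3} = 2π.
    """
    if v_aneu <= 0 or da <= 0:
        raise ValueError("volume and area must be positive")
    return float(1.0 - (18.0 * np.pi) ** (1.0 / 3.0) * v_aneu ** (2.0 / 3.0) / da)


def height(mesh: TriSurfaceMesh, neck: NeckPlane) -> float:
    """H: longest perpendicular distance from the neck plane to the dome."""
    d = neck.signed_distance(mesh.vertices[mesh.dome_vertices])
    h = float(d.max())
    if h <= 0:
        raise OrientationError("dome lies entirely below the neck plane")
    if d.min() < -1e-6:
        warnings.warn(
            f"dome vertices extend {-d.min():.2e} m below the neck plane",
            stacklevel=2,
        )
    return h


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(normal, e1)


def _max_pairwise(points2d: np.ndarray) -> float:
    if len(points2d) < 2:
        return 0.0
    if len(points2d) > 40:
        # hull vertices suffice for the diameter
        try:
            from scipy.spatial import ConvexHull

            points2d = points2d[ConvexHull(points2d).vertices]
        except Exception:  # noqa: BLE001 - collinear slices fall back to brute force
            pass
    return float(pdist(points2d).max())


def width(mesh: TriSurfaceMesh, neck: NeckPlane, n_slices: int = 100) -> float:
    """W: largest cross-section diameter measured parallel to the neck plane.

    Dome vertices are binned into ``n_slices`` plane-parallel slabs; per
    slab the maximal pairwise distance of the in-plane projections is
    taken, and W is the maximum over slabs.
    """
    pts = mesh.vertices[mesh.dome_vertices]
    d = neck.signed_distance(pts)
    h = d.max()
    if h <= 0:
        raise OrientationError("dome lies entirely below the neck plane")
    e1, e2 = _plane_basis(neck.normal)
    uv = np.stack([(pts - neck.point) @ e1, (pts - neck.point) @ e2], axis=1)
    edges = np.linspace(0.0, h, n_slices + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_slices - 1)
    best = 0.0
    for s in range(n_slices):
        best = max(best, _max_pairwise(uv[which == s]))
    return float(best)


def neck_diameter(
    mesh: TriSurfaceMesh, neck: NeckPlane, definition: str = "feret"
) -> float:
    """D_neck: diameter of the neck loop projected onto the neck plane.

    ``definition="feret"`` (default) is the maximal pairwise distance;
    ``"equivalent_area"`` returns the diameter of the circle with the same
    enclosed area as the projected loop polygon.
    """
    pts = mesh.vertices[neck.loop]
    e1, e2 = _plane_basis(neck.normal)
    uv = np.stack([(pts - neck.point) @ e1, (pts - neck.point) @ e2], axis=1)
    if definition == "feret":
        return _max_pairwise(uv)
    if definition == "equivalent_area":
        x, y = uv[:, 0], uv[:, 1]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        return float(2.0 * np.sqrt(area / np.pi))
    raise ValueError(f"unknown neck-diameter definition {definition!r}")


def morphology_record(
    mesh: TriSurfaceMesh, neck: NeckPlane, n_slices: int = 100
) -> MorphologyRecord:
    """All nine shape indices of one aneurysm; ratio identities hold exactly."""
    da = dome_area(mesh)
    vol = dome_volume(mesh, neck)
    h = height(mesh, neck)
    w = width(mesh, neck, n_slices=n_slices)
    dn = neck_diameter(mesh, neck)
    return MorphologyRecord(
        DA=da,
        V_aneu=vol,
        NSI=nsi(vol, da),
        H=h,
        W=w,
        D_neck=dn,
        HWR=h / w,
        AR=h / dn,
        BF=w / dn,
    )
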