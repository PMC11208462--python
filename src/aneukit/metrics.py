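"""Wall-shear-stress field metrics on triangulated aneurysm surfaces.

Implements the five per-vertex WSS metrics used for rupture-status
analysis, their scalar summaries over the dome, and thresholded area
indices:

======  ============================================  ==========
metric  meaning                                       units
======  ============================================  ==========
TAWSS   cycle-averaged magnitude of τ                 Pa
OSI     directional oscillation, 0.5·(1 − ‖∮τ‖/∮‖τ‖)  —
WSSD    cycle-averaged surface divergence ∇_s·τ       Pa/m
WSSG    cycle-averaged ‖G(t)‖, G the WSS-gradient     Pa/m
GON     1 − ‖∮G dt‖/∮‖G(t)‖dt                         —
======  ============================================  ==========

The gradient vector ``G`` has components (∂τ_p/∂p, ∂τ_q/∂q) in the local
tangent frame aligned with the cycle-averaged WSS direction ``p`` (the
construction the gradient-oscillatory-number literature uses); a full
3×3 tangential-Jacobian Frobenius norm is available via
``gradient_def="frobenius"``.

Spatial derivatives use linear (P1) shape functions per triangle — exact
for fields linear over a planar patch — area-averaged onto vertices.
Time quadrature is the periodic trapezoidal rule: with uniform sampling
and the wrap-around sample identified with sample 0, every time integral
reduces to a plain mean over the stored samples times the period.

WSSD and WSSG are reported as cycle *averages* (1/T ∮ · dt) so their units
stay Pa/m independent of the period; pass ``cycle_average=False`` for the
raw ∮ · dt integral.  GON and OSI are scale-free either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .exceptions import DegenerateGeometryError, DimensionError
from .mesh import TimeVaryingVectorField, TriSurfaceMesh

__all__ = [
    "MetricMap",
    "MetricSummary",
    "AreaIndexResult",
    "tawss",
    "osi",
    "wssd",
    "wssg",
    "gon",
    "surface_divergence",
    "surface_gradient",
    "summarize",
    "area_index",
    "wss_summary_row",
    "SUMMARY_COLUMNS",
]

#: denominators below this are treated as zero flow (OSI/GON set to 0)
_EPS_FLOW = 1e-12

METRIC_UNITS = {
    "TAWSS": "Pa",
    "OSI": "1",
    "WSSD": "Pa/m",
    "WSSG": "Pa/m",
    "GON": "1",
}

#: the eleven scalar summaries reported per aneurysm, in cohort-table order
SUMMARY_COLUMNS = (
    "maxTAWSS",
    "minTAWSS",
    "SA-TAWSS",
    "maxOSI",
    "SA-OSI",
    "maxWSSG",
    "SA-WSSG",
    "minWSSD",
    "SA-WSSD",
    "maxGON",
    "SA-GON",
)


@dataclass
class MetricMap:
    """A per-vertex scalar metric field."""

    name: str
    values: np.ndarray  # (n_v,)
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.name}: non-finite metric value")


@dataclass
class MetricSummary:
    """max / min / space-averaged value of one metric over a region."""

    name: str
    max: float
    min: float
    space_average: float


@dataclass
class AreaIndexResult:
    """Dome-wall area (and fraction) beyond a metric threshold."""

    metric: str
    threshold: float
    direction: str  # "above" | "below"
    area: float  # m²
    ratio: float  # area / dome area


# ---------------------------------------------------------------------------
# discrete surface operators (P1 shape functions, cached per mesh)
# ---------------------------------------------------------------------------

class _SurfaceOperator:
    """Precomputed P1 gradient data for one mesh.

    ``grad_phi[f, i]`` is the (3,) gradient of the hat function of local
    vertex ``i`` on face ``f``; ``avg`` is the sparse (n_v, n_f) matrix of
    area-weighted face→vertex averaging.
    """

    def __init__(self, mesh: TriSurfaceMesh):
        self.mesh = mesh
        v, f = mesh.vertices, mesh.faces
        p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        cross = np.cross(p1 - p0, p2 - p0)
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        if np.any(areas <= 1e-18):
            idx = int(np.argmin(areas))
            raise DegenerateGeometryError(f"triangle {idx} is degenerate")
        normals = cross / (2.0 * areas)[:, None]
        # hat-function gradients: ∇φ_i = n × e_i / (2A), e_i the opposite edge
        edges = np.stack([p2 - p1, p0 - p2, p1 - p0], axis=1)  # (n_f, 3, 3)
        self.grad_phi = np.cross(normals[:, None, :], edges) / (
            2.0 * areas[:, None, None]
        )
        self.face_areas = areas
        self.face_normals = normals
        n_v, n_f = mesh.n_vertices, mesh.n_faces
        rows = f.ravel()
        cols = np.repeat(np.arange(n_f), 3)
        w = np.repeat(areas, 3)
        acc = sp.csr_matrix((w, (rows, cols)), shape=(n_v, n_f))
        inv_tot = 1.0 / np.asarray(acc.sum(axis=1)).ravel()
        self.avg = sp.diags(inv_tot) @ acc

    def face_gradient(self, scalars: np.ndarray) -> np.ndarray:
        """Per-face constant gradient of per-vertex scalars (..., n_v) → (..., n_f, 3)."""
        vals = scalars[..., self.mesh.faces]  # (..., n_f, 3)
        return np.einsum("fik,...fi->...fk", self.grad_phi, vals)

    def to_vertices(self, face_vals: np.ndarray) -> np.ndarray:
        """Area-weighted face→vertex average of (..., n_f[, k]) values."""
        if face_vals.ndim == 1:
            return self.avg @ face_vals
        lead = face_vals.shape[: face_vals.ndim - 1]
        flat = face_vals.reshape(-1, face_vals.shape[-1])
        if face_vals.shape[-1] == self.mesh.n_faces:
            return (self.avg @ flat.T).T.reshape(*lead, self.mesh.n_vertices)
        # trailing component axis: (..., n_f, k)
        *lead2, n_f, k = face_vals.shape
        flat = face_vals.reshape(-1, n_f, k)
        out = np.stack([(self.avg @ flat[j]) for j in range(flat.shape[0])])
        return out.reshape(*lead2, self.mesh.n_vertices, k)


_OP_CACHE: dict[int, _SurfaceOperator] = {}


def _operator(mesh: TriSurfaceMesh) -> _SurfaceOperator:
    op = _OP_CACHE.get(id(mesh))
    if op is None or op.mesh is not mesh:
        op = _SurfaceOperator(mesh)
        _OP_CACHE.clear()  # keep the cache tiny: one mesh at a time
        _OP_CACHE[id(mesh)] = op
    return op


def surface_gradient(mesh: TriSurfaceMesh, scalar: np.ndarray) -> np.ndarray:
    """Tangential surface gradient of a per-vertex scalar map, (n_v, 3).

    Per-face constant gradients from linear shape functions, area-averaged
    onto vertices (one-sided at boundary vertices).  Exact for fields linear
    over a planar patch.
    """
    scalar = np.asarray(scalar, float)
    if scalar.shape[-1] != mesh.n_vertices:
        raise DimensionError("scalar map length != vertex count")
    op = _operator(mesh)
    return op.to_vertices(op.face_gradient(scalar))


def surface_divergence(mesh: TriSurfaceMesh, vectors: np.ndarray) -> np.ndarray:
    """Discrete surface divergence of a tangential per-vertex field (Pa/m).

    Each face evaluates ∇·τ of the linear interpolant of its three vertex
    vectors expressed in the face plane; face values are area-averaged to
    vertices.  Accepts (n_v, 3) or a stacked (..., n_v, 3) series.
    """
    vectors = np.asarray(vectors, float)
    if vectors.shape[-2] != mesh.n_vertices or vectors.shape[-1] != 3:
        raise DimensionError("field must have shape (..., n_v, 3)")
    op = _operator(mesh)
    tau = vectors[..., mesh.faces, :]  # (..., n_f, 3corner, 3comp)
    normals = op.face_normals
    normal_comp = np.einsum("...fik,fk->...fi", tau, normals)
    tau_t = tau - normal_comp[..., None] * normals[:, None, :]
    div_face = np.einsum("fik,...fik->...f", op.grad_phi, tau_t)
    return op.to_vertices(div_face)


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def _time_mean(samples: np.ndarray) -> np.ndarray:
    # periodic trapezoid with the wrap-around sample == sample 0
    return samples.mean(axis=0)


def tawss(mesh: TriSurfaceMesh, fld: TimeVaryingVectorField) -> MetricMap:
    """Time-averaged WSS magnitude, (1/T)∮‖τ‖dt, in Pa."""
    mags = np.linalg.norm(fld.samples, axis=2)
    return MetricMap("TAWSS", _time_mean(mags), METRIC_UNITS["TAWSS"])


def osi(mesh: TriSurfaceMesh, fld: TimeVaryingVectorField) -> MetricMap:
    """Oscillatory shear index, 0.5·(1 − ‖∮τdt‖/∮‖τ‖dt) ∈ [0, 0.5].

    Vertices with ∮‖τ‖dt below 1e-12 Pa·s (no flow) get OSI = 0.
    """
    mean_vec = _time_mean(fld.samples)
    mean_mag = _time_mean(np.linalg.norm(fld.samples, axis=2))
    denom = mean_mag * fld.period
    out = np.zeros(fld.n_vertices)
    ok = denom > _EPS_FLOW
    out[ok] = 0.5 * (1.0 - np.linalg.norm(mean_vec[ok], axis=1) / mean_mag[ok])
    return MetricMap("OSI", np.clip(out, 0.0, 0.5), METRIC_UNITS["OSI"])


def wssd(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    cycle_average: bool = True,
) -> MetricMap:
    """WSS divergence: time integral of ∇_s·τ, cycle-averaged by default."""
    div = surface_divergence(mesh, fld.samples)  # (n_t, n_v)
    out = _time_mean(div)
    if not cycle_average:
        out = out * fld.period
    return MetricMap("WSSD", out, METRIC_UNITS["WSSD"])


def _tangent_frame(
    mesh: TriSurfaceMesh, fld: TimeVaryingVectorField
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p, q, flagged): tangent frame from the cycle-averaged WSS direction.

    Where the mean WSS magnitude is below the zero-flow threshold an
    arbitrary fixed tangent direction is used and the vertex is flagged.
    """
    normals = mesh.vertex_normals
    mean_vec = _time_mean(fld.samples)
    # keep p strictly tangential
    mean_vec = mean_vec - np.einsum("vk,vk->v", mean_vec, normals)[:, None] * normals
    mag = np.linalg.norm(mean_vec, axis=1)
    flagged = mag <= _EPS_FLOW
    p = np.zeros_like(mean_vec)
    p[~flagged] = mean_vec[~flagged] / mag[~flagged, None]
    if flagged.any():
        # fixed fallback: project x̂ (or ŷ where x̂ ∥ normal) to the tangent plane
        ref = np.tile(np.array([1.0, 0.0, 0.0]), (flagged.sum(), 1))
        n_f = normals[flagged]
        par = np.abs(np.einsum("vk,vk->v", ref, n_f)) > 0.9
        ref[par] = np.array([0.0, 1.0, 0.0])
        t = ref - np.einsum("vk,vk->v", ref, n_f)[:, None] * n_f
        p[flagged] = t / np.linalg.norm(t, axis=1, keepdims=True)
    q = np.cross(normals, p)
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    qn[qn == 0.0] = 1.0
    q = q / qn
    return p, q, flagged


def _gradient_series(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    gradient_def: str,
) -> np.ndarray:
    """Per-instant WSS-gradient vectors/tensors flattened to (n_t, n_v, k)."""
    op = _operator(mesh)
    if gradient_def == "pq":
        p, q, _ = _tangent_frame(mesh, fld)
        tau_p = np.einsum("tvk,vk->tv", fld.samples, p)
        tau_q = np.einsum("tvk,vk->tv", fld.samples, q)
        grads = op.to_vertices(op.face_gradient(np.stack([tau_p, tau_q])))
        # grads: (2, n_t, n_v, 3)
        g_pp = np.einsum("tvk,vk->tv", grads[0], p)
        g_qq = np.einsum("tvk,vk->tv", grads[1], q)
        return np.stack([g_pp, g_qq], axis=-1)  # (n_t, n_v, 2)
    if gradient_def == "frobenius":
        comps = np.moveaxis(fld.samples, 2, 0)  # (3, n_t, n_v)
        grads = op.to_vertices(op.face_gradient(comps))  # (3, n_t, n_v, 3)
        return np.moveaxis(grads, 0, 2).reshape(fld.n_t, fld.n_vertices, 9)
    raise ValueError(f"unknown gradient_def {gradient_def!r}")


def wssg(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    cycle_average: bool = True,
    gradient_def: str = "pq",
) -> MetricMap:
    """WSS gradient magnitude: (1/T)∮‖G(t)‖dt in Pa/m.

    ``G`` defaults to the two-component (∂τ_p/∂p, ∂τ_q/∂q) vector in the
    frame of the cycle-averaged WSS direction; ``gradient_def="frobenius"``
    uses the full tangential-Jacobian Frobenius norm instead.
    """
    g = _gradient_series(mesh, fld, gradient_def)
    out = _time_mean(np.linalg.norm(g, axis=2))
    if not cycle_average:
        out = out * fld.period
    return MetricMap("WSSG", out, METRIC_UNITS["WSSG"])


def gon(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    gradient_def: str = "pq",
) -> MetricMap:
    """Gradient oscillatory number, 1 − ‖∮G dt‖/∮‖G‖dt ∈ [0, 1].

    Shares the gradient-vector definition with :func:`wssg`.  Vertices with
    ∮‖G‖dt below threshold get GON = 0.
    """
    g = _gradient_series(mesh, fld, gradient_def)
    num = np.linalg.norm(_time_mean(g), axis=1)
    den = _time_mean(np.linalg.norm(g, axis=2))
    out = np.zeros(fld.n_vertices)
    ok = den * fld.period > _EPS_FLOW
    out[ok] = 1.0 - num[ok] / den[ok]
    return MetricMap("GON", np.clip(out, 0.0, 1.0), METRIC_UNITS["GON"])


# ---------------------------------------------------------------------------
# reductions over the dome
# ---------------------------------------------------------------------------

def _region_vertex_mask(mesh: TriSurfaceMesh, region: str) -> np.ndarray:
    if region == "all":
        return np.ones(mesh.n_vertices, dtype=bool)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    faces = mesh.faces[mesh.region == region]
    mask[np.unique(faces)] = True
    return mask


def summarize(
    mesh: TriSurfaceMesh, metric_map: MetricMap, region: str = "dome"
) -> MetricSummary:
    """max / min / area-weighted mean of a metric over a labeled region.

    The space average weights vertices by their barycentric lumped area so
    it approximates the surface integral ∫f dA / ∫dA.
    """
    mask = _region_vertex_mask(mesh, region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    vals = metric_map.values[mask]
    w = mesh.vertex_areas[mask]
    return MetricSummary(
        name=metric_map.name,
        max=float(vals.max()),
        min=float(vals.min()),
        space_average=float(np.average(vals, weights=w)),
    )


def area_index(
    mesh: TriSurfaceMesh,
    metric_map: MetricMap | np.ndarray,
    threshold: float,
    direction: str,
    region: str = "dome",
) -> AreaIndexResult:
    """Wall area whose metric passes a threshold, plus its dome fraction.

    A face counts when the *mean of its three vertex values* is strictly
    above (``direction="above"``) or strictly below (``"below"``) the
    threshold; its full area is then accumulated.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    values = metric_map.values if isinstance(metric_map, MetricMap) else np.asarray(metric_map, float)
    name = metric_map.name if isinstance(metric_map, MetricMap) else "metric"
    face_mask = mesh.region == region if region != "all" else np.ones(mesh.n_faces, bool)
    face_vals = values[mesh.faces[face_mask]].mean(axis=1)
    areas = mesh.face_areas[face_mask]
    total = areas.sum()
    passed = face_vals > threshold if direction == "above" else face_vals < threshold
    area = float(areas[passed].sum())
    return AreaIndexResult(
        metric=name,
        threshold=float(threshold),
        direction=direction,
        area=area,
        ratio=area / total if total > 0 else 0.0,
    )


def wss_summary_row(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    region: str = "dome",
    gradient_def: str = "pq",
) -> dict[str, float]:
    """The eleven standard hemodynamic summaries of one aneurysm.

    Returns a dict with keys :data:`SUMMARY_COLUMNS` (maxTAWSS … SA-GON),
    ready to append to a cohort table.
    """
    maps = {
        "TAWSS": tawss(mesh, fld),
        "OSI": osi(mesh, fld),
        "WSSG": wssg(mesh, fld, gradient_def=gradient_def),
        "WSSD": wssd(mesh, fld),
        "GON": gon(mesh, fld, gradient_def=gradient_def),
    }
    s = {name: summarize(mesh, m, region) for name, m in maps.items()}
    return {
        "maxTAWSS": s["TAWSS"].max,
        "minTAWSS": s["TAWSS"].min,
        "SA-TAWSS": s["TAWSS"].space_average,
        "maxOSI": s["OSI"].max,
        "SA-OSI": s["OSI"].space_average,
        "maxWSSG": s["WSSG"].max,
        "SA-WSSG": s["WSSG"].space_average,
        "minWSSD": s["WSSD"].min,
        "SA-WSSD": s["WSSD"].space_average,
        "maxGON": s["GON"].max,
        "SA-GON": s["GON"].space_average,
    }
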