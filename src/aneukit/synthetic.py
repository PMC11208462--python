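"""Synthetic inputs for the whole analysis pipeline.

The CTA-derived patient geometries and solver WSS fields behind the study
design this package supports are not publicly available, so every input is
emulated here with *analytically known* structure:

* parametric dome meshes (spherical caps with optional spherical-harmonic
  surface bumps) together with their neck plane;
* pulsatile tangential WSS series containing planted features — high-WSS
  spots, converging (negative-divergence) sinks, direction-oscillation
  patches and high-gradient rims — whose target metric values are known in
  closed form at the feature centre;
* spherical-harmonic oracle fields on the unit sphere with closed-form
  surface gradients/divergences (∇_s·∇_s Y_l^m = −l(l+1) Y_l^m), used to
  validate the discrete surface operators;
* two-group rupture cohorts whose per-group means/SDs default to the
  published 40-aneurysm comparison table and whose rank correlations can
  follow the published Spearman matrix (Gaussian copula).

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
import sympy as sym

from .exceptions import GenerationError, PlacementError
from .mesh import TimeVaryingVectorField, TriSurfaceMesh, project_tangential
from .morphology import NeckPlane

__all__ = [
    "DomeSpec",
    "FlowFeature",
    "CohortSpec",
    "make_dome_mesh",
    "make_wss_series",
    "make_analytic_sphere_field",
    "make_cohort",
    "pulse_shape",
    "TABLE_MEANS_SD",
    "SPEARMAN_MATRIX",
    "COHORT_COLUMNS",
]


# ---------------------------------------------------------------------------
# pulse waveform template
# ---------------------------------------------------------------------------

def pulse_shape(phase: np.ndarray | float) -> np.ndarray:
    """Two-harmonic cardiac pulse shape s(t/T), mean 1, systolic peak 1.8.

    Stands in for subject-specific inflow waveforms; strictly positive
    (minimum ≈ 0.58).
    """
    ph = 2.0 * np.pi * np.asarray(phase, float)
    return 1.0 + 0.6 * np.cos(ph) + 0.2 * np.cos(2.0 * ph)


# ---------------------------------------------------------------------------
# dome meshes
# ---------------------------------------------------------------------------

@dataclass
class DomeSpec:
    """Parametric aneurysm dome: a spherical cap with harmonic bumps.

    ``bumps`` is a list of ``(l, m, amplitude)`` with the amplitude given as
    a fraction of the cap radius (must stay < 0.3 for meshability).  Bumps
    are tapered to zero at the rim so the neck stays planar.
    """

    cap_radius: float = 2e-3  # m
    cap_angle: float = np.pi / 2  # rad; π/2 = hemisphere
    bumps: Sequence[tuple[int, int, float]] = field(default_factory=list)
    mesh_edge_length: float = 1.5e-4  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cap_angle < np.pi:
            raise ValueError("cap_angle must lie in (0, π)")
        for l, m, a in self.bumps:
            if abs(a) >= 0.3:
                raise GenerationError(
                    f"bump amplitude {a} too large to mesh without self-intersection"
                )
            if abs(m) > l:
                raise ValueError(f"invalid harmonic (l={l}, m={m})")


@lru_cache(maxsize=64)
def _real_sph_harm(l: int, m: int):
    """Lambdified real spherical harmonic Y_l^m(θ, φ) and its θ/φ derivatives."""
    th, ph = sym.symbols("theta phi", real=True)
    y = sym.Znm(l, m, th, ph).expand(func=True)
    y = sym.simplify(sym.re(sym.expand_complex(y)))
    dth = sym.diff(y, th)
    dph = sym.diff(y, ph)
    fy = sym.lambdify((th, ph), y, "numpy")
    fdth = sym.lambdify((th, ph), dth, "numpy")
    fdph = sym.lambdify((th, ph), dph, "numpy")

    def wrap(f):
        def g(theta, phi):
            out = f(theta, phi)
            return np.broadcast_to(np.asarray(out, float), np.shape(theta)).copy()

        return g

    return wrap(fy), wrap(fdth), wrap(fdph)


@lru_cache(maxsize=64)
def _harm_scale(l: int, m: int) -> float:
    """Max |Y_l^m| over the sphere, for amplitude normalisation of bumps."""
    fy, _, _ = _real_sph_harm(l, m)
    th = np.linspace(1e-3, np.pi - 1e-3, 181)
    ph = np.linspace(0, 2 * np.pi, 181)
    tt, pp = np.meshgrid(th, ph)
    return float(np.abs(fy(tt, pp)).max())


def _connect_rings(ring_a: np.ndarray, ang_a: np.ndarray,
                   ring_b: np.ndarray, ang_b: np.ndarray) -> list[list[int]]:
    """Triangulate the band between two closed vertex rings.

    Standard two-pointer merge by azimuthal angle; handles rings of
    different vertex counts.  Winding: (a, b, next) so that normals point
    outward when ring_b lies below ring_a on an outward-oriented cap.
    """
    na, nb = len(ring_a), len(ring_b)
    faces = []
    ia = ib = 0
    while ia < na or ib < nb:
        a0, b0 = ring_a[ia % na], ring_b[ib % nb]
        a_next = ang_a[(ia + 1) % na] + 2 * np.pi * ((ia + 1) // na)
        b_next = ang_b[(ib + 1) % nb] + 2 * np.pi * ((ib + 1) // nb)
        advance_a = ia < na and (ib >= nb or a_next <= b_next)
        if advance_a:
            faces.append([a0, b0, ring_a[(ia + 1) % na]])
            ia += 1
        else:
            faces.append([a0, b0, ring_b[(ib + 1) % nb]])
            ib += 1
    return faces


def make_dome_mesh(spec: DomeSpec) -> tuple[TriSurfaceMesh, NeckPlane]:
    """Build a dome mesh and its neck plane from a :class:`DomeSpec`.

    The cap is sampled on latitude rings (pole at +z, sphere centred at the
    origin); the last ring is the neck boundary loop and the neck plane is
    its best-fit plane.  Spherical-harmonic bumps perturb the radius by
    ``amplitude · cap_radius``, tapered quadratically to zero at the rim.
    Deterministic under ``spec.seed``.
    """
    r0, alpha = spec.cap_radius, spec.cap_angle
    rng = np.random.default_rng(spec.seed)
    n_rings = max(3, int(np.ceil(r0 * alpha / spec.mesh_edge_length)))
    thetas = alpha * np.arange(n_rings + 1) / n_rings

    verts: list[np.ndarray] = [np.array([0.0, 0.0, r0])]
    rings: list[np.ndarray] = [np.array([0])]
    ring_angles: list[np.ndarray] = [np.array([0.0])]
    theta_of: list[float] = [0.0]
    phi_of: list[float] = [0.0]
    for i in range(1, n_rings + 1):
        th = thetas[i]
        circ = 2 * np.pi * r0 * np.sin(th)
        n_phi = max(8, int(np.round(circ / spec.mesh_edge_length)))
        n_phi += n_phi % 2  # even count: Feret diameter of the rim is exact
        offset = 0.0 if i == n_rings else float(rng.uniform(0, 2 * np.pi / n_phi))
        phis = offset + 2 * np.pi * np.arange(n_phi) / n_phi
        idx = np.arange(len(verts), len(verts) + n_phi)
        for phv in phis:
            verts.append(
                r0
                * np.array(
                    [np.sin(th) * np.cos(phv), np.sin(th) * np.sin(phv), np.cos(th)]
                )
            )
            theta_of.append(th)
            phi_of.append(phv)
        rings.append(idx)
        ring_angles.append(phis)

    faces: list[list[int]] = []
    # pole fan
    first = rings[1]
    for k in range(len(first)):
        faces.append([0, first[k], first[(k + 1) % len(first)]])
    for i in range(1, n_rings):
        faces.extend(
            _connect_rings(rings[i], ring_angles[i], rings[i + 1], ring_angles[i + 1])
        )

    vertices = np.array(verts)
    theta_arr = np.array(theta_of)
    phi_arr = np.array(phi_of)
    if spec.bumps:
        taper = np.clip(1.0 - (theta_arr / alpha) ** 2, 0.0, 1.0)
        dr = np.zeros(len(vertices))
        for l, m, amp in spec.bumps:
            fy, _, _ = _real_sph_harm(l, m)
            dr += amp * r0 * fy(theta_arr, phi_arr) / _harm_scale(l, m)
        radial = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
        vertices = vertices + (dr * taper)[:, None] * radial

    # fan winding above is viewed-from-outside clockwise; flip to CCW/outward
    faces_arr = np.array(faces, dtype=np.int64)[:, ::-1]
    loop = rings[-1]
    mesh = TriSurfaceMesh(vertices, faces_arr, neck_loop=loop)
    mesh.validate()
    centroid = vertices[loop].mean(axis=0)
    _, _, vt = np.linalg.svd(vertices[loop] - centroid)
    normal = vt[2]
    if normal[2] < 0:  # orient toward the dome (pole at +z)
        normal = -normal
    neck = NeckPlane(point=centroid, normal=normal, loop=loop)
    return mesh, neck


# ---------------------------------------------------------------------------
# pulsatile WSS fields with planted features
# ---------------------------------------------------------------------------

@dataclass
class FlowFeature:
    """One planted disturbed-WSS feature on the dome.

    kind ∈ {high_wss_spot, converging_sink, oscillation_patch,
    high_gradient_rim}; ``center`` is a unit direction from the sphere
    centre; ``angular_radius`` in radians; ``amplitude`` in Pa for
    magnitude-type features, Pa/m for divergence/gradient-type.
    """

    kind: str
    center: np.ndarray
    angular_radius: float
    amplitude: float

    def __post_init__(self) -> None:
        kinds = {
            "high_wss_spot",
            "converging_sink",
            "oscillation_patch",
            "high_gradient_rim",
        }
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("feature amplitude must be ≥ 0")
        self.center = np.asarray(self.center, float)
        self.center = self.center / np.linalg.norm(self.center)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C¹ ramp: 0 for x≤0, 1 for x≥1."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_wss_series(
    mesh: TriSurfaceMesh,
    features: Sequence[FlowFeature] = (),
    n_t: int = 32,
    period: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_magnitude: float = 5.0,
    cap_angle: float = np.pi / 2,
    sphere_radius: float | None = None,
) -> TimeVaryingVectorField:
    """Pulsatile tangential WSS series with planted, recoverable features.

    The base field is an azimuthal swirl of ``base_magnitude`` Pa modulated
    by the cardiac pulse shape (mean 1).  Feature contracts at the feature
    centre (for mesh edge lengths ≲ 0.1 mm on a 2 mm dome):

    * ``high_wss_spot``: TAWSS ≈ amplitude (Pa), within 10 %;
    * ``converging_sink``: WSSD ≈ −amplitude (Pa/m), within 15 %;
    * ``oscillation_patch``: fully reversing at the centre ⇒ OSI → 0.5;
    * ``high_gradient_rim``: WSSG ≈ amplitude (Pa/m) on the rim circle,
      within 20 %.

    Deterministic under ``seed``.
    """
    if n_t < 16:
        raise ValueError("n_t must be ≥ 16")
    v = mesh.vertices
    r = np.linalg.norm(v, axis=1)
    radius = float(np.median(r)) if sphere_radius is None else sphere_radius
    u = v / r[:, None]  # unit directions from the sphere centre
    zhat = np.array([0.0, 0.0, 1.0])
    theta = np.arccos(np.clip(u @ zhat, -1.0, 1.0))

    # azimuthal swirl direction (regularised at the pole)
    phi_dir = np.cross(zhat, u)
    nrm = np.linalg.norm(phi_dir, axis=1, keepdims=True)
    pole = nrm[:, 0] < 1e-12
    phi_dir[pole] = np.array([1.0, 0.0, 0.0])
    nrm[pole] = 1.0
    phi_dir = phi_dir / nrm

    s = pulse_shape(np.arange(n_t) / n_t)  # (n_t,)

    mag = np.full(len(v), float(base_magnitude))
    direction = phi_dir.copy()
    steady_extra = np.zeros((len(v), 3))
    reversing = np.zeros((len(v), 3))

    for feat in features:
        ca = np.clip(u @ feat.center, -1.0, 1.0)
        ang = np.arccos(ca)
        center_theta = np.arccos(np.clip(feat.center @ zhat, -1.0, 1.0))
        if center_theta + feat.angular_radius > cap_angle + 1e-9:
            raise PlacementError(
                f"{feat.kind} at θ={center_theta:.3f} rad with radius "
                f"{feat.angular_radius:.3f} rad extends outside the dome"
            )
        g = np.exp(-((ang / (feat.angular_radius / 2.0)) ** 2))
        # tangential unit vector pointing away from the feature centre
        away = u * ca[:, None] - feat.center
        anrm = np.linalg.norm(away, axis=1, keepdims=True)
        anrm[anrm[:, 0] < 1e-12] = 1.0
        away = away / anrm

        if feat.kind == "high_wss_spot":
            mag = mag + (feat.amplitude - base_magnitude) * g
        elif feat.kind == "converging_sink":
            dist = radius * ang
            taper = 1.0 - _smoothstep(
                (ang - 0.5 * feat.angular_radius) / (0.5 * feat.angular_radius)
            )
            steady_extra = steady_extra - (
                0.5 * feat.amplitude * dist * taper
            )[:, None] * away
            # suppress the base field in the sink core: its discrete
            # divergence error (∝ |τ|/R) would otherwise swamp a planted
            # divergence that is orders of magnitude below the natural
            # |τ|/R scale — mirroring how real WSS fields are nearly
            # divergence-free relative to their gradient magnitude
            mag = mag * _smoothstep(
                (ang - 0.5 * feat.angular_radius) / (0.25 * feat.angular_radius)
            )
        elif feat.kind == "oscillation_patch":
            mag = mag * (1.0 - g)
            reversing = reversing + (feat.amplitude * g)[:, None] * phi_dir
        elif feat.kind == "high_gradient_rim":
            band = np.exp(
                -(((ang - feat.angular_radius) / (feat.angular_radius / 2.0)) ** 2)
            )
            ramp = base_magnitude + feat.amplitude * radius * (
                ang - feat.angular_radius
            )
            mag = mag * (1.0 - band) + band * ramp
            direction = direction * (1.0 - band)[:, None] + band[:, None] * away

    dn = np.linalg.norm(direction, axis=1, keepdims=True)
    dn[dn[:, 0] < 1e-12] = 1.0
    direction = direction / dn
    steady = mag[:, None] * direction + steady_extra  # (n_v, 3)

    samples = s[:, None, None] * steady[None, :, :]
    samples = samples + np.cos(2 * np.pi * np.arange(n_t) / n_t)[:, None, None] * (
        reversing[None, :, :]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, samples.shape)
    return project_tangential(mesh, samples, period=period)


# ---------------------------------------------------------------------------
# spherical-harmonic oracle fields
# ---------------------------------------------------------------------------

@dataclass
class SphereHarmonicField:
    """Oracle field on a unit-sphere mesh with closed-form derivatives."""

    kind: str  # "gradient" | "scalar"
    values: np.ndarray  # (n_v, 3) tangential field, or (n_v,) scalar map
    exact: np.ndarray  # exact ∇_s·τ (gradient) or |∇_s f| (scalar), (n_v,)


def make_analytic_sphere_field(
    mesh: TriSurfaceMesh, l: int, m: int = 0, kind: str = "gradient"
) -> SphereHarmonicField:
    """Spherical-harmonic oracle on a unit-sphere mesh (l ≤ 4).

    * ``kind="gradient"``: τ = ∇_s Y_l^m with exact surface divergence
      −l(l+1)·Y_l^m (the Laplace–Beltrami eigenrelation);
    * ``kind="scalar"``: the map Y_l^m with its exact tangential-gradient
      magnitude.

    Vertices within ~1e-6 rad of the poles evaluate the φ-derivative term
    with a clipped 1/sinθ; tests should restrict to interior vertices for
    m ≠ 0.
    """
    if l > 4 or l < 0:
        raise ValueError("l must be in 0..4")
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    if l == 0:
        const = 1.0 / np.sqrt(4 * np.pi)
        if kind == "gradient":
            return SphereHarmonicField(
                kind, np.zeros_like(u), np.zeros(len(u))
            )
        return SphereHarmonicField(
            kind, np.full(len(u), const), np.zeros(len(u))
        )
    fy, fdth, fdph = _real_sph_harm(l, m)
    yv = fy(theta, phi)
    dth = fdth(theta, phi)
    sin_t = np.maximum(np.sin(theta), 1e-12)
    dph_over_sin = fdph(theta, phi) / sin_t
    theta_hat = np.stack(
        [
            np.cos(theta) * np.cos(phi),
            np.cos(theta) * np.sin(phi),
            -np.sin(theta),
        ],
        axis=1,
    )
    phi_hat = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
    grad = dth[:, None] * theta_hat + dph_over_sin[:, None] * phi_hat
    if kind == "gradient":
        return SphereHarmonicField(kind, grad, -l * (l + 1) * yv)
    if kind == "scalar":
        return SphereHarmonicField(kind, yv, np.linalg.norm(grad, axis=1))
    raise ValueError(f"unknown kind {kind!r}")


def _random_patch(rng: np.random.Generator, u: np.ndarray, radius: float) -> np.ndarray:
    """Gaussian bump (1 at centre) around a random upper-dome direction."""
    ct = rng.uniform(np.cos(np.pi / 3), 1.0)
    stq = np.sqrt(1 - ct * ct)
    ph = rng.uniform(0, 2 * np.pi)
    center = np.array([stq * np.cos(ph), stq * np.sin(ph), ct])
    ang = np.arccos(np.clip(u @ center, -1, 1))
    return np.exp(-((ang / (radius / 1.5)) ** 2))


def make_sweep_cohort_maps(
    mesh: TriSurfaceMesh,
    labels: Sequence[int],
    band: tuple[float, float] = (4.0e4, 6.0e4),
    base_level: float = 1.0e4,
    noise_cv: float = 0.05,
    seed: int = 0,
    null: bool = False,
) -> list[np.ndarray]:
    """Per-aneurysm WSSG-like scalar maps with a planted separating band.

    Every aneurysm carries a "common" elevated patch (fixed angular radius
    0.5 rad, peak drawn below the band in [0.7, 1.0]·band[0]) emulating
    label-independent focal WSSG elevation; *ruptured* aneurysms (label 1)
    additionally carry a smaller high patch (radius 0.3–0.4 rad) whose
    peak lies above the band in [1.2, 1.6]·band[1].  Consequently an
    area-index threshold inside ``band`` exposes a patch-sized high-WSSG
    area on every ruptured dome and (noise tails aside) none on unruptured
    domes, while thresholds below the band mix the groups through the
    common patches.

    With ``null=True`` no patches are planted at all: maps are the
    background scaled by a label-independent per-aneurysm level (lognormal,
    CV 0.3), emulating pure between-aneurysm magnitude heterogeneity.

    Deterministic under ``seed``; returns one (n_v,) array per label.
    """
    rng = np.random.default_rng(seed)
    v = mesh.vertices
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    lo, hi = band
    if not hi > lo > base_level:
        raise ValueError("need base_level < band[0] < band[1]")
    maps = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    sigma_scale = np.sqrt(np.log1p(0.3**2))
    if null:
        # pure magnitude heterogeneity: one shared spatial pattern scaled
        # per aneurysm, so every threshold induces the same area ranking
        # and the sweep degenerates to a single between-group test
        pattern = np.full(len(v), base_level)
        pattern += (0.9 * lo - base_level) * _random_patch(rng, u, 0.6)
        pattern *= np.exp(sigma * rng.standard_normal(len(v)) - sigma**2 / 2)
        for _ in labels:
            scale = np.exp(sigma_scale * rng.standard_normal() - sigma_scale**2 / 2)
            maps.append(pattern * scale)
        return maps
    for lab in labels:
        noise = np.exp(sigma * rng.standard_normal(len(v)) - sigma**2 / 2)
        level = np.full(len(v), base_level)
        # label-independent focal elevation peaking just above the band
        # floor: below the band every dome exposes a patch-core area whose
        # size (∝ radius²) varies independently of the label, mixing the
        # group ranks there
        common_peak = rng.uniform(1.0 * lo, 1.15 * lo)
        common_r = rng.uniform(0.5, 0.9)
        level = level + (common_peak - base_level) * _random_patch(rng, u, common_r)
        if lab:
            high_peak = rng.uniform(1.15 * hi, 1.4 * hi)
            high_r = rng.uniform(0.25, 0.35)
            level = level + (high_peak - base_level) * _random_patch(rng, u, high_r)
        maps.append(level * noise)
    return maps


# ---------------------------------------------------------------------------
# two-group cohorts
# ---------------------------------------------------------------------------

#: per-parameter (ruptured mean, ruptured SD, unruptured mean, unruptured SD)
#: defaults taken from the published 20/20 comparison table.  Length-type
#: values are used verbatim as dimensionless defaults (their printed SI
#: units are internally inconsistent; see docs/methods.md).
TABLE_MEANS_SD: dict[str, tuple[float, float, float, float]] = {
    "DA": (8.886e-5, 6.922e-5, 6.041e-5, 5.036e-5),
    "V_aneu": (9.101e-8, 9.650e-8, 6.179e-8, 6.838e-8),
    "NSI": (2.955e-1, 3.750e-2, 2.666e-1, 2.364e-2),
    "H": (4.426e-2, 2.214e-2, 3.172e-2, 1.587e-2),
    "W": (6.246e-2, 2.247e-2, 5.384e-2, 1.737e-2),
    "D_neck": (5.618e-2, 1.156e-2, 5.770e-2, 1.319e-2),
    "HWR": (7.094e-1, 2.414e-1, 5.724e-1, 1.552e-1),
    "AR": (7.628e-1, 2.673e-1, 5.298e-1, 1.772e-1),
    "BF": (1.098, 2.689e-1, 9.177e-1, 1.126e-1),
    "maxTAWSS": (59.980, 30.297, 38.563, 26.443),
    "minTAWSS": (0.762, 0.357, 1.234, 1.017),
    "SA-TAWSS": (7.807, 3.063, 8.732, 6.180),
    "maxOSI": (0.468, 0.034, 0.465, 0.029),
    "SA-OSI": (0.060, 0.039, 0.064, 0.037),
    "maxWSSG": (2.838e5, 3.184e5, 2.206e5, 5.963e5),
    "SA-WSSG": (1.115e4, 5.986e3, 1.101e4, 7.822e3),
    "minWSSD": (-15.276, 8.323, -9.224, 9.552),
    "SA-WSSD": (0.170, 0.241, 0.226, 0.245),
    "maxGON": (0.880, 0.099, 0.876, 0.059),
    "SA-GON": (0.228, 0.076, 0.249, 0.077),
}

COHORT_COLUMNS = tuple(TABLE_MEANS_SD)

#: marginal family per parameter: lognormal for strictly positive scales,
#: normal for bounded indices, negated lognormal for minWSSD (< 0)
MARGINAL_FAMILY: dict[str, str] = {
    **{k: "lognormal" for k in (
        "DA", "V_aneu", "H", "W", "D_neck",
        "maxTAWSS", "minTAWSS", "SA-TAWSS", "maxWSSG", "SA-WSSG",
    )},
    **{k: "normal" for k in (
        "NSI", "HWR", "AR", "BF", "maxOSI", "SA-OSI",
        "SA-WSSD", "maxGON", "SA-GON",
    )},
    "minWSSD": "neg_lognormal",
}

#: published Spearman rank-correlation matrix (12 parameters)
SPEARMAN_PARAMS = (
    "NSI", "HWR", "AR", "BF", "maxTAWSS", "minWSSD", "maxWSSG",
    "AHS", "ALD", "AHG", "ALDR", "AHGR",
)
SPEARMAN_MATRIX = np.array([
    [1.000, -0.116, 0.188, 0.436, 0.317, -0.333, 0.321, 0.222, 0.367, 0.352, 0.275, 0.249],
    [-0.116, 1.000, 0.857, 0.047, 0.053, -0.050, 0.032, 0.251, 0.064, -0.002, -0.129, -0.171],
    [0.188, 0.857, 1.000, 0.488, 0.258, -0.257, 0.211, 0.494, 0.290, 0.244, 0.040, 0.034],
    [0.436, 0.047, 0.488, 1.000, 0.465, -0.462, 0.385, 0.621, 0.494, 0.465, 0.326, 0.326],
    [0.317, 0.053, 0.258, 0.465, 1.000, -0.896, 0.887, 0.666, 0.856, 0.915, 0.811, 0.874],
    [-0.333, -0.050, -0.257, -0.462, -0.896, 1.000, -0.900, -0.676, -0.914, -0.848, -0.891, -0.825],
    [0.321, 0.032, 0.211, 0.385, 0.887, -0.900, 1.000, 0.485, 0.800, 0.849, 0.791, 0.859],
    [0.222, 0.251, 0.494, 0.621, 0.666, -0.676, 0.485, 1.000, 0.758, 0.630, 0.628, 0.483],
    [0.367, 0.064, 0.290, 0.494, 0.856, -0.914, 0.800, 0.758, 1.000, 0.886, 0.931, 0.817],
    [0.352, -0.002, 0.244, 0.465, 0.915, -0.848, 0.849, 0.630, 0.886, 1.000, 0.838, 0.933],
    [0.275, -0.129, 0.040, 0.326, 0.811, -0.891, 0.791, 0.628, 0.838, 0.838, 1.000, 0.880],
    [0.249, -0.171, 0.034, 0.326, 0.874, -0.825, 0.859, 0.483, 0.817, 0.933, 0.880, 1.000],
])
# symmetrise (the printed table has one asymmetric transcription cell)
SPEARMAN_MATRIX = 0.5 * (SPEARMAN_MATRIX + SPEARMAN_MATRIX.T)


@dataclass
class CohortSpec:
    """Two-group cohort: per-group marginals plus optional rank correlations.

    ``params`` maps parameter name → (mean_rup, sd_rup, mean_unrup,
    sd_unrup); defaults to the published comparison table.  When
    ``use_correlations`` is true the Spearman structure of the published
    correlation matrix is imposed (Gaussian copula) on the parameters it
    covers; other parameters stay independent.
    """

    n_ruptured: int = 20
    n_unruptured: int = 20
    params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE_MEANS_SD)
    )
    families: dict[str, str] = field(default_factory=lambda: dict(MARGINAL_FAMILY))
    use_correlations: bool = False
    correlation: tuple[tuple[str, ...], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (m1, s1, m0, s0) in self.params.items():
            if s1 <= 0 or s0 <= 0:
                raise ValueError(f"{name}: SDs must be positive")


def make_published_model_cohort(
    n: int = 4000, seed: int = 0, which: str = "maxWSSG-NSI-AR"
) -> pd.DataFrame:
    """Cohort drawn from a published polynomial rupture model.

    Starred (mean-normalised) predictors are sampled with population mean
    1 — the polynomial predictor (maxWSSG or AHG) from a four-cluster
    lognormal mixture spanning the regions where the quadratic logit is
    informative (identifiability of the x² term at moderate n), NSI and AR
    from lognormals at the cohort-like coefficients of variation — and the
    rupture label is Bernoulli with the model's probability.  Used for
    parameter-recovery experiments.
    """
    from .stats import PUBLISHED_MODELS  # local import: avoid cycle

    spec = PUBLISHED_MODELS[which]
    poly = spec["predictors"][0]
    coef = np.asarray(spec["coef"], float)
    rng = np.random.default_rng(seed)

    def lognorm(cv: float) -> np.ndarray:
        s = np.sqrt(np.log1p(cv**2))
        return np.exp(s * rng.standard_normal(n) - s * s / 2)

    clusters = np.array([0.25, 0.9, 3.0, 6.5])
    probs = np.array([0.61, 0.24, 0.095, 0.055])
    x = rng.choice(clusters, size=n, p=probs) * lognorm(0.08)
    # starred predictors are cohort-mean-normalised by definition, so make
    # each sample mean exactly 1 (refitting then re-normalises by 1)
    x = x / x.mean()
    nsi = lognorm(0.25)
    nsi = nsi / nsi.mean()
    ar = lognorm(0.5)
    ar = ar / ar.mean()
    eta = coef[0] + coef[1] * x + coef[2] * x**2 + coef[3] * nsi + coef[4] * ar
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({poly: x, "NSI": nsi, "AR": ar, "ruptured": y})


def _nearest_psd_corr(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    if w.min() >= -1e-10:
        return mat
    w = np.clip(w, 1e-8, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _marginal_transform(z: np.ndarray, family: str, mean: float, sd: float) -> np.ndarray:
    if family == "normal":
        return mean + sd * z
    if family in ("lognormal", "neg_lognormal"):
        amean = abs(mean)
        sigma2 = np.log1p((sd / amean) ** 2)
        mu = np.log(amean) - sigma2 / 2.0
        if family == "neg_lognormal":
            # negate value AND flip z so the rank correlation with other
            # parameters keeps the requested sign
            return -np.exp(mu - np.sqrt(sigma2) * z)
        return np.exp(mu + np.sqrt(sigma2) * z)
    raise ValueError(f"unknown marginal family {family!r}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a two-group cohort table; deterministic under ``spec.seed``.

    Per-group marginals match the requested means/SDs (moment-matched
    normal or lognormal); rank correlations follow the requested Spearman
    matrix through a Gaussian copula (Pearson ρ = 2·sin(π·ρ_s/6)).  The
    binary label column is named ``ruptured``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.params)
    k = len(names)
    corr = np.eye(k)
    if spec.use_correlations or spec.correlation is not None:
        if spec.correlation is not None:
            cnames, cmat = spec.correlation
        else:
            cnames, cmat = SPEARMAN_PARAMS, SPEARMAN_MATRIX
        cmat = np.asarray(cmat, float)
        if not np.allclose(cmat, cmat.T) or not np.allclose(np.diag(cmat), 1.0):
            raise GenerationError("correlation matrix must be symmetric with unit diagonal")
        pearson = 2.0 * np.sin(np.pi * cmat / 6.0)
        pearson = _nearest_psd_corr(pearson)
        present = [n for n in cnames if n in names]
        idx = [names.index(n) for n in present]
        sub = [list(cnames).index(n) for n in present]
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                corr[ia, ib] = pearson[sub[a], sub[b]]
        corr = _nearest_psd_corr(corr)
        try:
            np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise GenerationError("correlation matrix infeasible after repair") from exc

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    rows = []
    for label, n in ((1, spec.n_ruptured), (0, spec.n_unruptured)):
        z = rng.standard_normal((n, k)) @ chol.T
        data = {}
        for j, name in enumerate(names):
            m1, s1, m0, s0 = spec.params[name]
            mean, sd = (m1, s1) if label == 1 else (m0, s0)
            family = spec.families.get(name, "normal")
            data[name] = _marginal_transform(z[:, j], family, mean, sd)
        df = pd.DataFrame(data)
        df["ruptured"] = label
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
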