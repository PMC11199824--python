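"""Synthetic callosum-like surface cohorts with known ground truth.

Real corpus-callosum meshes come from manually segmented MRI and are not
redistributable, so the pipeline is exercised on synthetic stand-ins: an
arched, tube-like surface swept along a C-shaped medial curve in the
sagittal (x-z) plane, with a smoothly varying thickness (radius) profile,
mildly elliptic cross-sections, and controllable between-subject
variability.  Because the generator knows its own medial curve and radius
profile, every downstream quantity (medial axis, MAD, Jacobian ratios,
effect localization) can be checked against ground truth.

Group effects are induced in two ways:

* a *radius* effect — thickness multiplied by ``1 + delta`` inside an
  arclength window, with cosine-tapered edges — which MAD and det(J) see;
* a *tangential shear* effect — the elliptic cross-section is twisted
  (rotated circumferentially) by an angle ramping up and back down inside
  the window — which deforms the surface along its tangent plane and is
  picked up by the full deformation tensor.

All randomness flows through explicit integer seeds; generation is a pure
function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, GeometryError

__all__ = [
    "MedialCurve",
    "RadiusProfile",
    "CohortConfig",
    "CohortManifest",
    "make_medial_curve",
    "default_radius_profile",
    "apply_group_effect",
    "apply_shear_effect",
    "make_tube_surface",
    "sample_subject",
    "generate_cohort",
    "derive_seed",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def derive_seed(base_seed: int, *tokens: str) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a base seed and tokens.

    Used to fan one global seed out to per-subject and per-stage seeds
    without any correlation between streams.
    """
    key = f"{base_seed}|" + "|".join(tokens)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# --------------------------------------------------------------------------- #
# medial curve                                                                #
# --------------------------------------------------------------------------- #
@dataclass
class MedialCurve:
    """Ordered medial-axis polyline from the rostral to the caudal end.

    ``points`` are 3-vectors in mm; ``t`` is the arclength fraction in
    [0, 1] of each point.
    """

    points: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if len(self.points) < 8:
            raise ConfigError("medial curve needs at least 8 points")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigError("arclength parameter t must be strictly increasing")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ConfigError("consecutive medial-curve points must be distinct")

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def make_medial_curve(n_points: int, arch_height: float, length: float) -> MedialCurve:
    """C-shaped planar arc in the x-z plane, resampled to uniform arclength.

    The endpoints sit at (0, 0, 0) and (length, 0, 0); the apex rises
    ``arch_height`` above them.  ``arch_height = 0`` degenerates to a
    straight segment.
    """
    if n_points < 8:
        raise ConfigError("n_points must be >= 8")
    if length <= 0 or arch_height < 0:
        raise ConfigError("length must be > 0 and arch_height >= 0")
    # dense parabola arc (odd count, so the apex is a sample), then
    # arclength resampling
    s = np.linspace(0.0, 1.0, 4097)
    x = s * length
    z = arch_height * (1.0 - (2.0 * s - 1.0) ** 2)
    pts = np.column_stack([x, np.zeros_like(x), z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    target = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(target, cum, pts[:, k]) for k in range(3)])
    t = target / total
    return MedialCurve(points=out, t=t)


# --------------------------------------------------------------------------- #
# radius profile                                                              #
# --------------------------------------------------------------------------- #
@dataclass
class RadiusProfile:
    """Tube radius r(t, theta) in mm on a regular sample grid.

    ``t_samples`` spans [0, 1]; ``theta_samples`` spans [0, 2*pi) and is
    periodic.  Evaluation uses bilinear interpolation (periodic in theta,
    clamped in t).
    """

    t_samples: np.ndarray
    theta_samples: np.ndarray
    values: np.ndarray  # (n_t, n_theta)

    def __post_init__(self) -> None:
        self.t_samples = np.asarray(self.t_samples, dtype=np.float64)
        self.theta_samples = np.asarray(self.theta_samples, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.t_samples), len(self.theta_samples)):
            raise ConfigError("values shape must be (n_t, n_theta)")
        if np.any(self.values <= 0):
            raise ConfigError("all radius samples must be positive")
        # smoothness guard: adjacent samples must not jump wildly
        for ax in (0, 1):
            a = self.values
            b = np.roll(self.values, -1, axis=ax)
            if ax == 0:
                a, b = a[:-1], self.values[1:]
            ratio = b / a
            if np.any(ratio < 0.5) or np.any(ratio > 2.0):
                raise ConfigError("radius profile not smooth (adjacent ratio outside [0.5, 2])")

    def __call__(self, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Evaluate r at broadcastable (t, theta)."""
        t = np.clip(np.asarray(t, dtype=np.float64), 0.0, 1.0)
        theta = np.mod(np.asarray(theta, dtype=np.float64), 2.0 * np.pi)
        nt, nth = self.values.shape
        # fractional indices: t non-uniform safe via interp of index
        it = np.interp(t, self.t_samples, np.arange(nt))
        dtheta = 2.0 * np.pi / nth
        jt = theta / dtheta
        i0 = np.clip(np.floor(it).astype(int), 0, nt - 2)
        fi = it - i0
        j0 = np.floor(jt).astype(int) % nth
        fj = jt - np.floor(jt)
        j1 = (j0 + 1) % nth
        v = self.values
        return ((1 - fi) * (1 - fj) * v[i0, j0]
                + (1 - fi) * fj * v[i0, j1]
                + fi * (1 - fj) * v[i0 + 1, j0]
                + fi * fj * v[i0 + 1, j1])

    def copy(self) -> "RadiusProfile":
        return RadiusProfile(self.t_samples.copy(), self.theta_samples.copy(),
                             self.values.copy())


def default_radius_profile(n_t: int = 64, n_theta: int = 16,
                           ellipticity: float = 0.15) -> RadiusProfile:
    """Callosum-like thickness profile.

    Thicker at the genu (t ~ 0.12) and splenium (t ~ 0.88), thinnest at
    the isthmus (t ~ 0.55); the cross-section is mildly elliptic
    (``1 + ellipticity * cos(2 theta)``), wider laterally than tall, as the
    callosal cross-section is.
    """
    t = np.linspace(0.0, 1.0, n_t)
    theta = np.arange(n_theta) * 2.0 * np.pi / n_theta
    r_t = (2.6
           + 1.2 * np.exp(-(((t - 0.12) / 0.10) ** 2))
           + 1.6 * np.exp(-(((t - 0.88) / 0.10) ** 2))
           - 0.4 * np.exp(-(((t - 0.55) / 0.18) ** 2)))
    shape = 1.0 + ellipticity * np.cos(2.0 * theta)
    return RadiusProfile(t, theta, np.outer(r_t, shape))


def _taper_weight(t: np.ndarray, window: tuple[float, float], margin: float) -> np.ndarray:
    """1 inside the window, cosine ramp over ``margin`` outside it, else 0."""
    t_lo, t_hi = window
    w = np.zeros_like(t)
    inside = (t >= t_lo) & (t <= t_hi)
    w[inside] = 1.0
    if margin > 0:
        lo_ramp = (t > t_lo - margin) & (t < t_lo)
        w[lo_ramp] = 0.5 * (1.0 + np.cos(np.pi * (t_lo - t[lo_ramp]) / margin))
        hi_ramp = (t > t_hi) & (t < t_hi + margin)
        w[hi_ramp] = 0.5 * (1.0 + np.cos(np.pi * (t[hi_ramp] - t_hi) / margin))
    return w


def apply_group_effect(profile: RadiusProfile, window: tuple[float, float],
                       delta: float, taper: float = 0.03) -> RadiusProfile:
    """Multiply the radius by (1 + delta) inside ``window``.

    Edges ramp smoothly (cosine taper of width ``taper`` in t) so the
    effect introduces no thickness discontinuity; the profile is unchanged
    outside the tapered margin.
    """
    t_lo, t_hi = window
    if not (0.0 <= t_lo < t_hi <= 1.0):
        raise ConfigError(f"invalid effect window {window}")
    if delta <= -1.0:
        raise ConfigError("effect delta must be > -1")
    w = _taper_weight(profile.t_samples, window, taper)
    out = profile.copy()
    out.values = out.values * (1.0 + delta * w)[:, None]
    return out


def apply_shear_effect(profile: RadiusProfile, window: tuple[float, float],
                       shear_delta: float) -> RadiusProfile:
    """Twist the cross-section inside ``window`` (tangential shear).

    The circumferential angle at which the radius profile is evaluated is
    shifted by ``alpha(t) = shear_delta * sin^2(pi * (t - t_lo)/(t_hi -
    t_lo))`` (radians) inside the window and 0 outside.  Because the
    cross-section is non-circular this rotates the section shape along the
    tube, shearing the surface along its tangent plane while leaving the
    set of radii on each iso-parametric curve unchanged.  A circular
    profile is invariant under this operation.
    """
    t_lo, t_hi = window
    if not (0.0 <= t_lo < t_hi <= 1.0):
        raise ConfigError(f"invalid effect window {window}")
    out = profile.copy()
    tt = profile.t_samples
    tau = np.clip((tt - t_lo) / (t_hi - t_lo), 0.0, 1.0)
    alpha = shear_delta * np.sin(np.pi * tau) ** 2
    theta = profile.theta_samples
    for i, a in enumerate(alpha):
        if a != 0.0:
            out.values[i] = profile(np.full_like(theta, tt[i]), theta - a)
    return out


# --------------------------------------------------------------------------- #
# tube surface                                                                #
# --------------------------------------------------------------------------- #
def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing (parallel transport) frames along a polyline.

    Returns (n1, n2), each (n, 3), orthonormal to the tangent.  Parallel
    transport avoids the frame flips Frenet frames exhibit on straight or
    low-curvature segments, keeping the circumferential angle consistent
    along the tube.
    """
    n = len(points)
    tan = np.zeros((n, 3))
    tan[0] = points[1] - points[0]
    tan[-1] = points[-1] - points[-2]
    tan[1:-1] = points[2:] - points[:-2]
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)

    n1 = np.zeros((n, 3))
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tan[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, tan[0]) * tan[0]
    n1[0] = v / np.linalg.norm(v)
    # double-reflection rotation-minimizing frame propagation
    for i in range(n - 1):
        c = np.dot(tan[i], tan[i + 1])
        if c > 1.0 - 1e-12:
            n1[i + 1] = n1[i]
            continue
        axis = np.cross(tan[i], tan[i + 1])
        s = np.linalg.norm(axis)
        axis = axis / s
        ang = np.arctan2(s, c)
        # Rodrigues rotation of n1 about axis by ang
        k = axis
        vv = n1[i]
        n1[i + 1] = (vv * np.cos(ang) + np.cross(k, vv) * np.sin(ang)
                     + k * np.dot(k, vv) * (1.0 - np.cos(ang)))
        # re-orthogonalize against accumulated error
        n1[i + 1] -= np.dot(n1[i + 1], tan[i + 1]) * tan[i + 1]
        n1[i + 1] /= np.linalg.norm(n1[i + 1])
    n2 = np.cross(tan, n1)
    return n1, n2


def _curvature(points: np.ndarray) -> np.ndarray:
    """Discrete curvature magnitude at each polyline point (1/mm)."""
    n = len(points)
    kappa = np.zeros(n)
    for i in range(1, n - 1):
        a, b, c = points[i - 1], points[i], points[i + 1]
        ab, cb = b - a, c - b
        la, lc = np.linalg.norm(ab), np.linalg.norm(cb)
        cr = np.linalg.norm(np.cross(ab, cb))
        denom = la * lc * np.linalg.norm(c - a)
        kappa[i] = 2.0 * cr / denom if denom > 0 else 0.0
    kappa[0], kappa[-1] = kappa[1], kappa[-2]
    return kappa


def make_tube_surface(curve: MedialCurve, profile: RadiusProfile,
                      grid_dims: tuple[int, int]) -> SurfaceMesh:
    """Sweep a tube of radius r(t, theta) along the medial curve.

    ``grid_dims = (n_u, n_v)``: n_u cross-sections along the curve
    (including both ends, so the mesh has two open boundary loops) and n_v
    vertices around each section.  Cross-section frames are parallel
    transported.  Raises :class:`GeometryError` if the radius exceeds the
    local radius of curvature (self-intersecting sweep).
    """
    n_u, n_v = grid_dims
    if n_u < 8 or n_v < 6:
        raise ConfigError("grid_dims must be at least (8, 6)")
    t = np.linspace(0.0, 1.0, n_u)
    pts = np.column_stack([np.interp(t, curve.t, curve.points[:, k]) for k in range(3)])
    n1, n2 = _parallel_transport_frames(pts)
    kappa = _curvature(pts)
    theta = np.arange(n_v) * 2.0 * np.pi / n_v

    tt = np.repeat(t, n_v)
    th = np.tile(theta, n_u)
    r = profile(tt, th).reshape(n_u, n_v)

    r_max = r.max(axis=1)
    bad = kappa * r_max >= 0.95
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GeometryError(
            f"tube self-intersects near t={t[i]:.3f}: radius {r_max[i]:.2f} mm "
            f"vs radius of curvature {1.0 / kappa[i]:.2f} mm"
        )

    cosv = np.cos(theta)[None, :, None]
    sinv = np.sin(theta)[None, :, None]
    verts = (pts[:, None, :]
             + r[:, :, None] * (cosv * n1[:, None, :] + sinv * n2[:, None, :]))
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_u - 1):
        for j in range(n_v):
            j2 = (j + 1) % n_v
            a = i * n_v + j
            b = (i + 1) * n_v + j
            c = (i + 1) * n_v + j2
            d = i * n_v + j2
            faces.append((a, b, c))
            faces.append((a, c, d))
    faces = np.asarray(faces, dtype=np.int64)

    mesh = SurfaceMesh(verts, faces)
    # orient outward: flip winding if face normals point toward the axis
    f0 = faces[0]
    nrm = np.cross(verts[f0[1]] - verts[f0[0]], verts[f0[2]] - verts[f0[0]])
    centre = pts[0]
    if np.dot(nrm, verts[f0[0]] - centre) < 0:
        mesh = SurfaceMesh(verts, faces[:, ::-1].copy())
    return mesh


# --------------------------------------------------------------------------- #
# cohort configuration and sampling                                           #
# --------------------------------------------------------------------------- #
@dataclass
class CohortConfig:
    """Study conditions for one synthetic two-group cohort.

    Defaults give a callosum-scale tube (70 mm chord, 25 mm arch, 2-4 mm
    radius) with mild between-subject variability: smooth radial noise of
    0.2 mm, ~5% global scale jitter and rigid jitter of up to 5 degrees /
    2 mm.  Group B differs from group A by ``effect_delta`` (relative
    radius change) and/or ``shear_delta`` (cross-section twist, radians)
    inside ``effect_window`` (arclength fractions).
    """

    n_per_group: int = 10
    effect_window: tuple[float, float] = (0.3, 0.5)
    effect_delta: float = 0.0
    shear_delta: float = 0.0
    noise_sd: float = 0.2
    scale_jitter_sd: float = 0.05
    rigid_rot_deg: float = 5.0
    rigid_trans_mm: float = 2.0
    grid_dims: tuple[int, int] = (64, 16)
    mesh_dims: tuple[int, int] = (96, 24)
    seed: int = 0
    arch_height: float = 25.0
    length: float = 70.0
    ellipticity: float = 0.15
    taper: float = 0.03

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        t_lo, t_hi = self.effect_window
        if not (0.0 <= t_lo < t_hi <= 1.0):
            raise ConfigError(f"invalid effect window {self.effect_window}")
        if self.effect_delta <= -1.0:
            raise ConfigError("effect_delta must be > -1")
        if self.noise_sd < 0 or self.scale_jitter_sd < 0:
            raise ConfigError("noise magnitudes must be >= 0")
        self.effect_window = tuple(self.effect_window)
        self.grid_dims = tuple(self.grid_dims)
        self.mesh_dims = tuple(self.mesh_dims)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        return cls(**json.loads(text))

    def base_curve(self) -> MedialCurve:
        return make_medial_curve(max(64, self.mesh_dims[0]), self.arch_height,
                                 self.length)

    def group_profile(self, group: str) -> RadiusProfile:
        """Radius profile for a group: 'A' is the base, 'B' carries the effect."""
        prof = default_radius_profile(ellipticity=self.ellipticity)
        if group == "B":
            if self.effect_delta != 0.0:
                prof = apply_group_effect(prof, self.effect_window,
                                          self.effect_delta, self.taper)
            if self.shear_delta != 0.0:
                prof = apply_shear_effect(prof, self.effect_window,
                                          self.shear_delta)
        return prof


def _smooth_noise_field(rng: np.random.Generator, shape: tuple[int, int],
                        sd: float, coarse: tuple[int, int] = (8, 4)) -> np.ndarray:
    """Spatially smooth zero-mean noise with exact per-sample sd.

    White noise on a coarse (t, theta) grid is bilinearly upsampled
    (periodic in theta) and renormalized by the interpolation weight norm,
    so the field is smooth but every sample keeps marginal sd ``sd``.
    """
    n_t, n_th = shape
    c_t, c_th = coarse
    z = rng.standard_normal((c_t, c_th))
    # fractional coordinates of fine samples on the coarse grid
    ft = np.linspace(0.0, c_t - 1, n_t)
    fth = np.arange(n_th) * c_th / n_th  # periodic
    i0 = np.clip(np.floor(ft).astype(int), 0, c_t - 2)
    a = ft - i0
    j0 = np.floor(fth).astype(int) % c_th
    b = fth - np.floor(fth)
    j1 = (j0 + 1) % c_th
    field = ((1 - a)[:, None] * (1 - b)[None, :] * z[np.ix_(i0, j0)]
             + (1 - a)[:, None] * b[None, :] * z[np.ix_(i0, j1)]
             + a[:, None] * (1 - b)[None, :] * z[np.ix_(i0 + 1, j0)]
             + a[:, None] * b[None, :] * z[np.ix_(i0 + 1, j1)])
    norm = np.sqrt((a**2 + (1 - a) ** 2)[:, None] * (b**2 + (1 - b) ** 2)[None, :])
    return sd * field / norm


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0.0, max_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def sample_subject(config: CohortConfig, group: str, subject_seed: int) -> SurfaceMesh:
    """One subject's surface: group template + individual variability.

    Variability: (a) global isotropic scale ``exp(N(0, scale_jitter_sd^2))``,
    (b) smooth correlated radial noise of sd ``noise_sd`` mm, (c) a random
    rigid transform within ``rigid_rot_deg`` / ``rigid_trans_mm``.
    Deterministic given ``subject_seed``; vertices are snapped to single
    precision so on-disk meshes round-trip bitwise.
    """
    rng = np.random.default_rng(subject_seed)
    prof = config.group_profile(group)
    if config.noise_sd > 0:
        noise = _smooth_noise_field(rng, prof.values.shape, config.noise_sd)
        prof.values = np.maximum(prof.values + noise, 0.2)
    else:
        rng.standard_normal((8, 4))  # keep the stream aligned across settings
    curve = config.base_curve()
    mesh = make_tube_surface(curve, prof, config.mesh_dims)

    verts = mesh.vertices
    scale = float(np.exp(rng.standard_normal() * config.scale_jitter_sd))
    if scale != 1.0:
        centre = verts.mean(axis=0)
        verts = centre + scale * (verts - centre)
    rot = _random_rotation(rng, config.rigid_rot_deg)
    trans = rng.uniform(-config.rigid_trans_mm, config.rigid_trans_mm, size=3)
    verts = verts @ rot.T + trans
    verts = verts.astype(np.float32).astype(np.float64)
    return SurfaceMesh(verts, mesh.faces)


@dataclass
class CohortManifest:
    """Table of generated subjects: id, group, mesh path, seed, effects.

    Mesh paths are stored relative to the manifest's directory so a cohort
    folder can be moved or re-created anywhere.
    """

    table: pd.DataFrame
    config: CohortConfig = None
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        self.base_dir = Path(self.base_dir)
        if self.table["subject_id"].duplicated().any():
            raise ConfigError("subject ids must be unique")

    def paths(self) -> list[Path]:
        return [self.base_dir / p for p in self.table["path"]]

    def path_of(self, subject_id: str) -> Path:
        row = self.table[self.table["subject_id"] == subject_id].iloc[0]
        return self.base_dir / row["path"]

    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def subjects(self, group: str | None = None) -> pd.DataFrame:
        if group is None:
            return self.table
        return self.table[self.table["group"] == group]

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path, config: CohortConfig | None = None) -> "CohortManifest":
        return cls(pd.read_csv(path, dtype={"subject_id": str, "group": str}),
                   config, base_dir=Path(path).parent)


def generate_cohort(config: CohortConfig, out_dir) -> CohortManifest:
    """Write 2 * n_per_group subject meshes (binary PLY) plus manifest.csv.

    Group A uses the base radius profile, group B the effect-modified one.
    Per-subject seeds derive from ``config.seed`` and the subject id.
    """
    from . import io as ccio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group in ("A", "B"):
        for k in range(config.n_per_group):
            sid = f"{group}{k:03d}"
            sseed = derive_seed(config.seed, "subject", sid)
            mesh = sample_subject(config, group, sseed)
            mesh.subject_id = sid
            path = out_dir / f"{sid}.ply"
            ccio.write_mesh(mesh, path)
            rows.append({
                "subject_id": sid,
                "group": group,
                "path": f"{sid}.ply",
                "seed": sseed,
                "effect_delta": config.effect_delta if group == "B" else 0.0,
                "shear_delta": config.shear_delta if group == "B" else 0.0,
            })
    table = pd.DataFrame(rows)
    manifest = CohortManifest(table, config, base_dir=out_dir)
    manifest.save(out_dir / "manifest.csv")
    (out_dir / "config.json").write_text(config.to_json())
    return manifest
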