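"""Synthetic dynamic-vessel phantom with analytic ground truth.

The phantom emulates a ten-phase, ECG-gated-style acquisition of a single
contrast-filled coronary segment: one high-resolution, low-noise volume at
the diastolic reference phase, plus one low-resolution volume per cardiac
phase whose additive-noise level follows a U-shaped schedule over the cycle
(quiet mid-cycle, noisy near full diastole, mirroring dose modulation).

The vessel is a curved tube extruded along z: at cycle time ``t`` (percent)
its centerline is

    c_t(z) = (x_c + B_x sin(pi zeta),  y_c + B_y(t) sin(pi zeta),  z),
    zeta = (z - z0) / L,

with a phase-varying bend amplitude ``B_y(t)`` and a tapering radius

    r_t(z) = s(t) * (r_prox + (r_dist - r_prox) zeta),

where ``s(t)`` is a per-phase lumen scale.  Because the family is analytic,
the exact phase-to-phase point mapping is available in closed form:

    p  ->  ( c_t(z) + rho (p_xy - c_ref(z)),  z ),    rho = s(t)/s(ref),

an orientation-preserving diffeomorphism (in-plane Jacobian determinant
``rho^2 > 0`` everywhere).  Every downstream accuracy claim — segmentation
overlap, registration warp recovery, propagated-mesh fidelity, contour
areas — is measured against this closed-form truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq
from skimage import measure

from .geometry import BinaryMask, ImageVolume, VolumeGeometry, index_to_physical, write_mask, write_nifti
from .surface import SurfaceMesh, write_points_csv, write_stl
from .validation import CuttingPlane, PlanarContour

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "high_res_geometry",
    "low_res_geometry",
    "generate_phase_volume",
    "analytic_contour",
    "generate_sequence",
]

# U-shaped per-phase noise SD (HU): quiet over 30-70%, high near full diastole.
DEFAULT_NOISE_SD = {
    10: 40.0, 20: 28.0, 30: 16.0, 40: 14.0, 50: 13.0,
    60: 14.0, 70: 16.0, 80: 30.0, 90: 48.0, 100: 52.0,
}


def high_res_geometry() -> VolumeGeometry:
    """Desk-scale high-resolution grid: 0.4 mm in-plane, 0.6 mm slices."""
    return VolumeGeometry(shape=(192, 192, 120), spacing=(0.4, 0.4, 0.6))


def low_res_geometry() -> VolumeGeometry:
    """Desk-scale low-resolution grid: 0.8125 mm in-plane, 1.5 mm slices."""
    return VolumeGeometry(shape=(96, 96, 60), spacing=(0.8125, 0.8125, 1.5))


@dataclass
class PhantomSpec:
    """Parameters of the dynamic tube family and of the simulated acquisition.

    Geometry defaults put the tube comfortably inside both desk-scale grids;
    HU levels give a contrast-filled lumen (350) well above the 166 HU
    working threshold, against soft tissue (50) and background (-50).
    """

    phases: tuple = tuple(range(10, 101, 10))
    reference_phase: float = 67.0
    # tube placement / shape (mm)
    center_xy: tuple[float, float] = (38.0, 38.0)
    z_range: tuple[float, float] = (6.0, 66.0)
    bend_x: float = 8.0
    bend_y_base: float = 4.0
    bend_y_amp: float = 2.5
    radius_proximal: float = 2.0
    radius_distal: float = 0.8
    lumen_amp: float = 0.08
    tissue_margin: float = 6.0
    # HU levels
    hu_lumen: float = 350.0
    hu_tissue: float = 50.0
    hu_background: float = -50.0
    # acquisition
    noise_sd_schedule: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    reference_noise_sd: float = 10.0
    supersample: int = 3
    seed: int = 0

    def __post_init__(self):
        ph = tuple(float(p) for p in self.phases)
        if any(b <= a for a, b in zip(ph, ph[1:])) or not all(0 < p <= 100 for p in ph):
            raise ValueError("phases must be strictly increasing in (0, 100]")
        self.phases = ph
        if self.radius_proximal <= 0 or self.radius_distal <= 0:
            raise ValueError("radii must be positive")
        if abs(self.lumen_amp) >= 1:
            raise ValueError("|lumen_amp| must be < 1 so the radius stays positive")
        if any(sd < 0 for sd in self.noise_sd_schedule.values()):
            raise ValueError("noise SD must be non-negative")

    # -- analytic family ----------------------------------------------------

    def bend_y(self, t: float) -> float:
        return self.bend_y_base + self.bend_y_amp * np.sin(2 * np.pi * t / 100.0)

    def lumen_scale(self, t: float) -> float:
        return 1.0 + self.lumen_amp * np.cos(2 * np.pi * t / 100.0)

    def _zeta(self, z):
        z0, z1 = self.z_range
        return (np.asarray(z, dtype=float) - z0) / (z1 - z0)

    def centerline(self, z, t: float) -> np.ndarray:
        """Centerline point(s) at height(s) z for cycle time t (percent)."""
        zeta = np.clip(self._zeta(z), 0.0, 1.0)
        s = np.sin(np.pi * zeta)
        xc, yc = self.center_xy
        x = xc + self.bend_x * s
        y = yc + self.bend_y(t) * s
        return np.stack(np.broadcast_arrays(x, y, np.asarray(z, dtype=float)), axis=-1)

    def centerline_tangent(self, z, t: float) -> np.ndarray:
        z0, z1 = self.z_range
        zeta = np.clip(self._zeta(z), 0.0, 1.0)
        dsdz = np.cos(np.pi * zeta) * np.pi / (z1 - z0)
        tx = self.bend_x * dsdz
        ty = self.bend_y(t) * dsdz
        tan = np.stack(np.broadcast_arrays(tx, ty, np.ones_like(zeta)), axis=-1)
        return tan / np.linalg.norm(tan, axis=-1, keepdims=True)

    def radius(self, z, t: float) -> np.ndarray:
        zeta = np.clip(self._zeta(z), 0.0, 1.0)
        base = self.radius_proximal + (self.radius_distal - self.radius_proximal) * zeta
        return self.lumen_scale(t) * base

    def displace_points(self, points, t_from: float, t_to: float) -> np.ndarray:
        """Exact point mapping from phase ``t_from`` to phase ``t_to``.

        In-plane similarity about the centerline; z preserved.  The map is a
        diffeomorphism with Jacobian determinant ``rho^2 > 0``.
        """
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        rho = self.lumen_scale(t_to) / self.lumen_scale(t_from)
        c_from = self.centerline(p[:, 2], t_from)
        c_to = self.centerline(p[:, 2], t_to)
        out = p.copy()
        out[:, :2] = c_to[:, :2] + rho * (p[:, :2] - c_from[:, :2])
        return out

    def signed_distance(self, points, t: float) -> np.ndarray:
        """Approximate signed distance to the capped tube (negative inside)."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        c = self.centerline(p[:, 2], t)
        radial = np.linalg.norm(p[:, :2] - c[:, :2], axis=1) - self.radius(p[:, 2], t)
        z0, z1 = self.z_range
        zm, hl = 0.5 * (z0 + z1), 0.5 * (z1 - z0)
        caps = np.abs(p[:, 2] - zm) - hl
        return np.maximum(radial, caps)


@dataclass
class PhantomTruth:
    """Ground truth bundle for one phase: analytic fields + discrete artifacts."""

    spec: PhantomSpec
    phase: float
    mask: BinaryMask
    mesh: SurfaceMesh

    def centerline(self, z):
        return self.spec.centerline(z, self.phase)

    def radius(self, z):
        return self.spec.radius(z, self.phase)

    def displacement_from_reference(self, points):
        return self.spec.displace_points(points, self.spec.reference_phase, self.phase)


def _check_phase(spec: PhantomSpec, phase: float) -> float:
    phase = float(phase)
    known = set(spec.phases) | {float(spec.reference_phase)}
    if not any(abs(phase - k) < 1e-9 for k in known):
        raise ValueError(f"phase {phase} not in the phantom spec (phases {spec.phases} "
                         f"or reference {spec.reference_phase})")
    return phase


def _occupancy(spec: PhantomSpec, phase: float, geom: VolumeGeometry, k: int):
    """Supersampled (k^3 per voxel) occupancy fractions of lumen and tissue shell."""
    if not np.allclose(geom.direction, np.eye(3)):
        raise ValueError("phantom grids must be axis-aligned")
    nx, ny, nz = geom.shape
    sp = np.asarray(geom.spacing)
    org = np.asarray(geom.origin)

    def sub(n, axis):
        i = np.arange(n * k) // k
        m = np.arange(n * k) % k
        return org[axis] + sp[axis] * (i - 0.5 + (m + 0.5) / k)

    xs, ys, zs = sub(nx, 0), sub(ny, 1), sub(nz, 2)
    c = spec.centerline(zs, phase)          # (nz*k, 3)
    r2 = spec.radius(zs, phase) ** 2
    t2 = spec.tissue_margin ** 2
    z0, z1 = spec.z_range
    in_z = (zs >= z0) & (zs <= z1)

    f_lumen = np.empty((nx, ny, nz), dtype=np.float32)
    f_tissue = np.empty((nx, ny, nz), dtype=np.float32)
    X = xs[:, None].astype(np.float32)
    Y = ys[None, :].astype(np.float32)
    chunk = max(1, int(4e6 // (nx * ny * k * k)))  # voxels of z per slab
    for zv in range(0, nz, chunk):
        zhi = min(nz, zv + chunk)
        sl = slice(zv * k, zhi * k)
        dx = X[:, :, None] - c[None, None, sl, 0].astype(np.float32)
        dy = Y[:, :, None] - c[None, None, sl, 1].astype(np.float32)
        d2 = dx * dx + dy * dy
        lum = (d2 < r2[None, None, sl].astype(np.float32)) & in_z[None, None, sl]
        tis = (d2 < np.float32(t2)) & in_z[None, None, sl]
        shp = (nx, k, ny, k, zhi - zv, k)
        f_lumen[:, :, zv:zhi] = (
            lum.reshape(nx, k, ny, k, -1, k).transpose(0, 2, 4, 1, 3, 5)
            .reshape(nx, ny, -1, k ** 3).mean(axis=-1)
        )
        f_tissue[:, :, zv:zhi] = (
            tis.reshape(nx, k, ny, k, -1, k).transpose(0, 2, 4, 1, 3, 5)
            .reshape(nx, ny, -1, k ** 3).mean(axis=-1)
        )
    return f_lumen, f_tissue


def generate_phase_volume(
    spec: PhantomSpec, phase: float, geometry: VolumeGeometry
) -> tuple[ImageVolume, BinaryMask]:
    """Simulate one acquisition: partial-volume HU blend plus phase-level noise.

    Voxel values are the k-fold supersampled blend of lumen/tissue/background
    HU; the truth mask is supersampled tube occupancy > 0.5.  Deterministic
    under ``spec.seed`` (phase and grid shape fold into the noise stream).
    """
    phase = _check_phase(spec, phase)
    f_lumen, f_tissue = _occupancy(spec, phase, geometry, spec.supersample)
    f_tissue_only = np.clip(f_tissue - f_lumen, 0.0, 1.0)
    values = (
        f_lumen * spec.hu_lumen
        + f_tissue_only * spec.hu_tissue
        + (1.0 - f_lumen - f_tissue_only) * spec.hu_background
    ).astype(np.float64)

    if abs(phase - spec.reference_phase) < 1e-9 and phase not in spec.phases:
        sd = spec.reference_noise_sd
    else:
        sd = spec.noise_sd_schedule.get(int(round(phase)), spec.reference_noise_sd)
    if sd > 0:
        rng = np.random.default_rng(
            [spec.seed, int(round(phase * 100))] + list(geometry.shape)
        )
        values = values + rng.normal(0.0, sd, size=values.shape)

    mask = BinaryMask(geometry=geometry, values=f_lumen > 0.5)
    return ImageVolume(geometry=geometry, values=values), mask


def truth_surface(spec: PhantomSpec, phase: float, grid_mm: float = 0.3) -> SurfaceMesh:
    """Marching cubes on the analytic signed distance -> ground-truth mesh."""
    phase = _check_phase(spec, phase)
    xc, yc = spec.center_xy
    rmax = spec.radius_proximal * (1 + abs(spec.lumen_amp))
    pad = 2.0
    lo = np.array([xc - rmax - pad,
                   yc - rmax - pad,
                   spec.z_range[0] - pad])
    hi = np.array([xc + spec.bend_x + rmax + pad,
                   yc + spec.bend_y_base + spec.bend_y_amp + rmax + pad,
                   spec.z_range[1] + pad])
    shape = tuple(int(np.ceil((h - l) / grid_mm)) + 1 for l, h in zip(lo, hi))
    geom = VolumeGeometry(shape=shape, spacing=(grid_mm,) * 3, origin=tuple(lo))
    ii = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    pts = index_to_physical(geom, ii.reshape(-1, 3))
    phi = spec.signed_distance(pts, phase).reshape(shape)
    verts_idx, faces, _, _ = measure.marching_cubes(phi, level=0.0, method="lewiner")
    verts = index_to_physical(geom, verts_idx)
    return SurfaceMesh(verts, faces)


def truth(spec: PhantomSpec, phase: float, geometry: VolumeGeometry | None = None) -> PhantomTruth:
    geometry = geometry or low_res_geometry()
    _, mask = generate_phase_volume(spec, phase, geometry)
    return PhantomTruth(spec=spec, phase=float(phase), mask=mask,
                        mesh=truth_surface(spec, phase))


def analytic_contour(
    spec: PhantomSpec, phase: float, plane: CuttingPlane, n_points: int = 256
) -> PlanarContour:
    """Exact cross-section of the tube by a transversal plane.

    The section boundary is found by root-finding on the closed-form
    tube-boundary function ``F(p) = |p_xy - c(p_z)| - r(p_z)`` along rays
    from the axis/plane intersection point, sampled at ``n_points`` angles
    (each boundary point solved to ~1e-12 mm).  For a locally straight,
    constant-radius stretch this reduces to the classical cylinder section:
    a circle for a perpendicular cut, an ellipse with semi-axes ``r`` and
    ``r / cos(theta)`` for a cut tilted by ``theta``.  A plane within ~81
    degrees of containing the local axis raises "non-transversal cut".
    """
    phase = _check_phase(spec, phase)
    z0, z1 = spec.z_range

    def g(z):
        return float((spec.centerline(z, phase) - plane.origin) @ plane.normal)

    zz = np.linspace(z0, z1, 1001)
    gg = np.array([g(z) for z in zz])
    crossings = np.nonzero(np.diff(np.sign(gg)) != 0)[0]
    if len(crossings) == 0:
        raise ValueError("plane does not cross the tube centerline")
    i = crossings[0]
    zstar = brentq(g, zz[i], zz[i + 1])

    T = spec.centerline_tangent(zstar, phase).ravel()
    cos_theta = float(abs(T @ plane.normal))
    if cos_theta < 0.15:
        raise ValueError("non-transversal cut: plane nearly contains the local tube axis")

    r = float(spec.radius(zstar, phase))
    cline = spec.centerline(zstar, phase).ravel()
    # intersection of the local axis with the plane: interior anchor point
    s = float(plane.normal @ (plane.origin - cline)) / float(plane.normal @ T)
    center = cline + s * T

    def boundary(p):
        c = spec.centerline(p[2], phase).ravel()
        return float(np.linalg.norm(p[:2] - c[:2]) - spec.radius(p[2], phase))

    if boundary(center) >= 0:
        raise ValueError("plane/axis intersection fell outside the tube")

    c2 = plane.to_local(center[None, :])[0]
    t_max = 4.0 * r / cos_theta
    psi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts2 = np.empty((n_points, 2))
    for k, a in enumerate(psi):
        d = np.array([np.cos(a), np.sin(a)])

        def f(t):
            return boundary(plane.to_world((c2 + t * d)[None, :])[0])

        hi = t_max
        while f(hi) < 0:  # widen the bracket for strongly oblique sections
            hi *= 2.0
            if hi > 100.0 * r:
                raise ValueError("failed to bracket the tube boundary")
        pts2[k] = c2 + brentq(f, 0.0, hi, xtol=1e-12) * d
    return PlanarContour(plane, pts2)


def generate_sequence(spec: PhantomSpec, out_dir) -> dict:
    """Write the full synthetic acquisition plus ground truth to disk.

    Produces one high-resolution reference volume (at ``reference_phase``,
    low noise) and one low-resolution volume per phase as NIfTI, truth masks
    (NIfTI), truth surfaces (STL), displacement samples (CSV), and a YAML
    manifest.  Re-running with the same seed is byte-identical.
    """
    from pathlib import Path

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    manifest = {"seed": spec.seed, "reference_phase": spec.reference_phase,
                "phases": list(spec.phases), "volumes": {}, "truth": {}}

    hi = high_res_geometry()
    lo = low_res_geometry()

    vol, mask = generate_phase_volume(spec, spec.reference_phase, hi)
    ref_path = out / "volumes" / "reference.nii.gz"
    write_nifti(vol, ref_path)
    write_mask(mask, out / "truth" / "mask_reference.nii.gz")
    ref_mesh = truth_surface(spec, spec.reference_phase)
    write_stl(ref_mesh, out / "truth" / "surface_reference.stl")
    manifest["volumes"]["reference"] = str(ref_path)
    manifest["truth"]["reference"] = {
        "mask": str(out / "truth" / "mask_reference.nii.gz"),
        "surface": str(out / "truth" / "surface_reference.stl"),
    }

    # displacement samples: reference truth-mesh vertices mapped to each phase
    sample = ref_mesh.vertices[:: max(1, len(ref_mesh.vertices) // 500)]
    for phase in spec.phases:
        tag = f"{int(phase):03d}"
        vol, mask = generate_phase_volume(spec, phase, lo)
        vpath = out / "volumes" / f"phase_{tag}.nii.gz"
        write_nifti(vol, vpath)
        write_mask(mask, out / "truth" / f"mask_{tag}.nii.gz")
        mesh = truth_surface(spec, phase)
        write_stl(mesh, out / "truth" / f"surface_{tag}.stl")
        moved = spec.displace_points(sample, spec.reference_phase, phase)
        write_points_csv(moved, out / "truth" / f"displacement_{tag}.csv", t=phase)
        manifest["volumes"][int(phase)] = str(vpath)
        manifest["truth"][int(phase)] = {
            "mask": str(out / "truth" / f"mask_{tag}.nii.gz"),
            "surface": str(out / "truth" / f"surface_{tag}.stl"),
            "displacement": str(out / "truth" / f"displacement_{tag}.csv"),
        }

    spec_digest = hashlib.sha256(repr(spec).encode()).hexdigest()[:16]
    manifest["spec_digest"] = spec_digest
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
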