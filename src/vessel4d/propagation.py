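"""Constant-topology phase sequences: point warping, mesh propagation, and
temporal interpolation.

The reference surface mesh is carried into every cardiac phase by applying
that phase's transform chain to the *vertices only*; the connectivity matrix
is stored once and shared (the same array object) by every phase mesh and
every interpolated mesh.  Keeping the topology bit-identical across the
cycle is what makes downstream mesh morphing possible: a solver can update
boundary-node positions without re-meshing or cross-grid interpolation.

Time is cyclic: phase percent wraps at 100% back to the first phase, and
intermediate shapes at any cycle time are produced by vertex-wise linear
interpolation between the two bracketing phases.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .registration import TransformChain
from .surface import SurfaceMesh, write_points_csv, write_stl

__all__ = [
    "PhaseSequence",
    "apply_chain_to_points",
    "propagate_mesh",
    "interpolate_phase",
    "export_sequence",
    "topology_hash",
]


def topology_hash(faces: np.ndarray) -> str:
    """SHA-256 of the connectivity matrix bytes (the cross-phase invariant)."""
    f = np.ascontiguousarray(np.asarray(faces, dtype=np.int64))
    return hashlib.sha256(f.tobytes()).hexdigest()


@dataclass
class PhaseSequence:
    """Ordered (phase %, mesh) pairs sharing one connectivity matrix."""

    phases: list[float]
    meshes: list[SurfaceMesh]
    faces: np.ndarray
    cycle_period: float = 1.0  # seconds; informational

    def __post_init__(self):
        self.phases = [float(p) for p in self.phases]
        if len(self.phases) != len(self.meshes):
            raise ValueError("phases and meshes length mismatch")
        if sorted(self.phases) != self.phases:
            raise ValueError("phases must be sorted ascending")
        n_vert = {m.n_vertices for m in self.meshes}
        if len(n_vert) > 1:
            raise ValueError("all phase meshes must share one vertex count")
        for m in self.meshes:
            if m.faces is not self.faces and not np.array_equal(m.faces, self.faces):
                raise ValueError("phase mesh connectivity differs from the shared faces")

    @property
    def topology_hash(self) -> str:
        return topology_hash(self.faces)


def apply_chain_to_points(chain: TransformChain | None, points) -> np.ndarray:
    """Map reference-space points to phase space: p -> A(p) + u(A(p)).

    ``chain=None`` is the identity.  Raises if any affinely-mapped point
    leaves the deformation-field domain by more than one voxel.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if chain is None:
        return pts.copy()
    mapped = chain.affine.apply(pts)
    ok = chain.field.contains(mapped, margin_voxels=1.0)
    if not ok.all():
        bad = int(np.nonzero(~ok)[0][0])
        raise ValueError(
            f"point outside deformation field: index {bad}, "
            f"position {tuple(np.round(mapped[bad], 2))}"
        )
    return mapped + chain.field.sample(mapped)


def _warn_degenerate(mesh: SurfaceMesh, phase: float) -> None:
    v = mesh.vertices
    tri = v[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    n_bad = int((areas < 1e-10).sum())
    if n_bad:
        warnings.warn(
            f"phase {phase:g}%: {n_bad} near-degenerate triangles after warping",
            RuntimeWarning,
        )


def propagate_mesh(
    reference: SurfaceMesh,
    chains: list[TransformChain | list[TransformChain]],
    phases: list[float] | None = None,
) -> PhaseSequence:
    """Warp the reference mesh into every phase; topology is shared, not copied.

    Each element of ``chains`` is one TransformChain (reference -> phase
    wiring) or a list applied in order (sequential phase -> phase wiring).
    Vertex arrays are per phase; the faces array is the reference's, shared
    by every output mesh.  Degenerate triangles after warping raise only a
    warning — folding is a quality signal, not a contract violation.
    """
    faces = reference.faces
    phase_list = []
    meshes = []
    for k, chain in enumerate(chains):
        steps = chain if isinstance(chain, (list, tuple)) else [chain]
        pts = reference.vertices
        try:
            for step in steps:
                pts = apply_chain_to_points(step, pts)
        except ValueError as e:
            target = getattr(steps[-1], "target_phase", k)
            raise ValueError(f"phase {target:g}: {e}") from e
        target = getattr(steps[-1], "target_phase", None)
        phase = float(target) if target is not None else float(k)
        mesh = SurfaceMesh.__new__(SurfaceMesh)
        mesh.vertices = pts
        mesh.faces = faces
        _warn_degenerate(mesh, phase)
        phase_list.append(phase)
        meshes.append(mesh)
    if phases is not None:
        phase_list = [float(p) for p in phases]
    order = np.argsort(phase_list)
    return PhaseSequence(
        phases=[phase_list[i] for i in order],
        meshes=[meshes[i] for i in order],
        faces=faces,
    )


def interpolate_phase(seq: PhaseSequence, t_percent: float) -> SurfaceMesh:
    """Mesh at an arbitrary cycle time by cyclic linear interpolation.

    ``t_percent`` in (0, 100]; 100% wraps to the first phase.  At a stored
    phase the stored mesh is returned unchanged; otherwise vertices are the
    linear blend of the two bracketing phase meshes.  Faces are shared.
    """
    if len(seq.phases) < 2:
        raise ValueError("interpolation needs at least 2 phases")
    t = float(t_percent)
    if not (0 < t <= 100):
        raise ValueError("t_percent must lie in (0, 100]")
    phases = np.asarray(seq.phases)
    exact = np.nonzero(np.isclose(phases, t))[0]
    if len(exact):
        return seq.meshes[int(exact[0])]

    # cyclic bracket: previous stored phase (mod 100) and next stored phase
    below = phases[phases < t]
    above = phases[phases > t]
    if len(below):
        p0 = below.max()
        gap0 = t - p0
    else:
        p0 = phases.max()
        gap0 = t + 100.0 - p0
    if len(above):
        p1 = above.min()
        gap1 = p1 - t
    else:
        p1 = phases.min()
        gap1 = p1 + 100.0 - t
    w = gap0 / (gap0 + gap1)
    m0 = seq.meshes[int(np.nonzero(phases == p0)[0][0])]
    m1 = seq.meshes[int(np.nonzero(phases == p1)[0][0])]
    out = SurfaceMesh.__new__(SurfaceMesh)
    out.vertices = (1.0 - w) * m0.vertices + w * m1.vertices
    out.faces = seq.faces
    return out


def export_sequence(seq: PhaseSequence, out_dir, times=None) -> dict:
    """Write one STL per requested time plus a vertex CSV and a manifest.

    ``times`` defaults to the stored phases.  The manifest records the
    shared-topology hash, which is identical for every exported mesh by
    construction.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = list(seq.phases) if times is None else [float(t) for t in times]
    thash = seq.topology_hash
    stl_paths = {}
    rows_pts = []
    rows_t = []
    for t in times:
        mesh = interpolate_phase(seq, t)
        assert topology_hash(mesh.faces) == thash
        path = out / f"phase_{t:06.2f}.stl"
        write_stl(mesh, path)
        stl_paths[t] = str(path)
        rows_pts.append(mesh.vertices)
        rows_t.append(np.full(mesh.n_vertices, t))
    csv_path = out / "vertices.csv"
    write_points_csv(np.vstack(rows_pts), csv_path, t=np.concatenate(rows_t))
    manifest = {
        "topology_hash": thash,
        "n_faces": int(len(seq.faces)),
        "n_vertices": int(seq.meshes[0].n_vertices),
        "times": times,
        "stl": {float(k): v for k, v in stl_paths.items()},
        "vertices_csv": str(csv_path),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
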