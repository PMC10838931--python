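"""Forward models: dipole-in-sphere and corrected single shell.

The lead field ``L`` maps dipole moments (nA*m) at fixed cortical
locations/orientations to the field measured on each channel (fT).

Two conductor models are provided:

* ``sphere`` - the closed-form field of a current dipole in a
  homogeneous conducting sphere (Sarvas).  Only the sphere *centre*
  matters; the field is independent of the radius, and dipoles that are
  radial or at the centre are magnetically silent.

* ``shell`` - a corrected-sphere (single-shell) model on a realistic
  boundary mesh.  It rests on the magnetic lead-field theorem for a
  homogeneous conductor: the lead field equals the infinite-medium
  (Biot-Savart) kernel plus the gradient of a function harmonic inside
  the conductor, fixed by requiring the total lead field to have zero
  normal component on the boundary (no current flows out).  The
  harmonic part is expanded in a nested basis of exterior point-source
  potentials (three radial layers of quasi-uniform directions) and
  fitted by weighted least squares on face-centroid collocation points;
  expansion ``order`` n gives (n+1)^2 - 1 directions per layer, the dof
  count of a degree-n harmonic expansion.

Internally everything is converted to SI; the constant mu0/(4 pi) and
the nA*m -> fT unit change are folded into a single scale so that lead
fields are numerically O(1)-O(100) for superficial sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import TriangleMesh
from .sensors import SensorArray

__all__ = [
    "ConductorModel",
    "SourceSpace",
    "LeadField",
    "fit_sphere",
    "sphere_leadfield",
    "single_shell_leadfield",
    "normal_oriented_sources",
    "brain_shell",
]

# mu0/(4 pi) [T m/A] * 1e-9 [A m per nA m] * 1e15 [fT per T]
_UNIT_SCALE = 1e-7 * 1e-9 * 1e15  # = 0.1, with all distances in metres
_MM = 1e-3


@dataclass(frozen=True)
class ConductorModel:
    """Either a sphere (centre/radius, mm) or a boundary-mesh shell."""

    kind: str  # "sphere" | "shell"
    center: np.ndarray = None
    radius: float = None
    mesh: TriangleMesh = None
    order: int = 10

    def __post_init__(self):
        if self.kind == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere radius must be positive")
            object.__setattr__(
                self, "center", np.asarray(self.center, dtype=np.float64)
            )
        elif self.kind == "shell":
            if self.mesh is None:
                raise ValueError("shell model needs a boundary mesh")
            if self.order < 6:
                raise ValueError("expansion order must be >= 6")
        else:
            raise ValueError(f"unknown conductor kind {self.kind!r}")


@dataclass(frozen=True)
class SourceSpace:
    """Dipole positions (mm) and unit orientations."""

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=np.float64)
        o = np.asarray(self.orientations, dtype=np.float64)
        if p.shape != o.shape or p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("positions and orientations must both be (n, 3)")
        norms = np.linalg.norm(o, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("orientations must be unit length")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "orientations", o)

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, indices) -> "SourceSpace":
        return SourceSpace(self.positions[indices], self.orientations[indices])


@dataclass(frozen=True)
class LeadField:
    """Gain matrix (n_channels x n_sources), fT per nA*m."""

    matrix: np.ndarray
    sources: SourceSpace
    channel_names: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(m)):
            raise ValueError("lead field contains non-finite entries")
        if m.shape != (len(self.channel_names), len(self.sources)):
            raise ValueError("lead-field shape inconsistent with metadata")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def restrict(self, indices) -> "LeadField":
        indices = np.asarray(indices)
        return LeadField(
            self.matrix[:, indices], self.sources.subset(indices), self.channel_names
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("matrix", data=self.matrix)
            fh.create_dataset("source_positions", data=self.sources.positions)
            fh.create_dataset("source_orientations", data=self.sources.orientations)
            fh.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )
            fh.attrs["units"] = "fT per nA*m"

    @classmethod
    def load(cls, path) -> "LeadField":
        with h5py.File(path, "r") as fh:
            return cls(
                matrix=fh["matrix"][()],
                sources=SourceSpace(
                    fh["source_positions"][()], fh["source_orientations"][()]
                ),
                channel_names=tuple(
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in fh["channel_names"][()]
                ),
            )


# ---------------------------------------------------------------------


def fit_sphere(mesh: TriangleMesh) -> ConductorModel:
    """Least-squares sphere through the mesh vertices (algebraic fit)."""
    v = mesh.vertices
    if len(v) < 4:
        raise ValueError("need at least 4 vertices")
    A = np.hstack([2.0 * v, np.ones((len(v), 1))])
    b = (v**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate geometry: vertices are coplanar")
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return ConductorModel(kind="sphere", center=center, radius=radius)


def normal_oriented_sources(cortex: TriangleMesh) -> SourceSpace:
    """One dipole per cortical vertex, oriented along the outward normal."""
    return SourceSpace(cortex.vertices.copy(), cortex.vertex_normals.copy())


def _sarvas_field(sensor_pos_m: np.ndarray, src_pos_m: np.ndarray,
                  src_ori: np.ndarray) -> np.ndarray:
    """Field component matrix builder for the conducting-sphere model.

    Returns the full magnetic field vectors B (n_sensors, n_sources, 3)
    for unit dipoles, in units where mu0/(4 pi) = 1; positions are
    relative to the sphere centre, in metres.
    """
    r = sensor_pos_m[:, None, :]  # (nc, 1, 3)
    r0 = src_pos_m[None, :, :]  # (1, ns, 3)
    q = src_ori[None, :, :]
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=2)
    rn = np.linalg.norm(sensor_pos_m, axis=1)[:, None]
    r0_dot_r = np.sum(r0 * r, axis=2)
    a_dot_r = np.sum(a_vec * r, axis=2)
    F = a * (rn * a + rn**2 - r0_dot_r)
    c1 = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + a_dot_r / a
    gradF = c1[..., None] * r - c2[..., None] * r0
    qxr0 = np.cross(np.broadcast_to(q, a_vec.shape), np.broadcast_to(r0, a_vec.shape))
    qxr0_dot_r = np.sum(qxr0 * r, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        B = (F[..., None] * qxr0 - qxr0_dot_r[..., None] * gradF) / (F**2)[..., None]
    # silent sources (dipole at centre => q x r0 = 0) give 0/0; fix to 0
    B[~np.isfinite(B)] = 0.0
    return B


def sphere_leadfield(
    array: SensorArray, sources: SourceSpace, sphere: ConductorModel
) -> LeadField:
    """Closed-form lead field for a homogeneous conducting sphere."""
    if sphere.kind != "sphere":
        raise ValueError("conductor model must be a sphere")
    c = sphere.center
    src_rel = (sources.positions - c) * _MM
    if np.any(np.linalg.norm(src_rel, axis=1) >= sphere.radius * _MM):
        raise ValueError("all sources must lie strictly inside the sphere")
    sens_rel = (array.channel_positions - c) * _MM
    ori = array.channel_orientations
    B = _sarvas_field(sens_rel, src_rel, sources.orientations)
    gains = np.einsum("cnk,ck->cn", B, ori) * _UNIT_SCALE
    return LeadField(gains, sources, tuple(array.channel_names))


# ---------------------------------------------------------------------
# corrected single shell
# ---------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors; prefixes are nested."""
    i = np.arange(n, dtype=np.float64)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / golden
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


def _linf(sensor_pos_m, sensor_ori, points_m):
    """Infinite-medium lead-field kernel (mu0/4pi = 1) at ``points_m``.

    L_inf(r') = u x n_s with u = (r_s - r') / |r_s - r'|^3; the channel
    signal of a dipole Q at r' is Q . L_inf(r').
    """
    d = sensor_pos_m[:, None, :] - points_m[None, :, :]  # (nc, np, 3)
    u = d / (np.linalg.norm(d, axis=2) ** 3)[..., None]
    return np.cross(u, np.broadcast_to(sensor_ori[:, None, :], u.shape))


# radii (x the shell's maximal radius) of the three nested basis layers;
# near layer resolves sharp sensor-side structure, far layers the smooth part
_BASIS_LAYER_RADII = (1.3, 2.2, 4.0)


def single_shell_leadfield(
    array: SensorArray,
    sources: SourceSpace,
    shell: ConductorModel,
    residual_tol: float = 0.3,
) -> LeadField:
    """Corrected-sphere (single-shell) lead field on a boundary mesh.

    The correction ``grad U`` (U harmonic inside the shell) is fitted by
    area-weighted least squares so that the total lead field has zero
    normal component on the shell surface.  A relative boundary
    residual (Frobenius, all channels) above ``residual_tol`` triggers
    a warning; the achieved value is attached as ``boundary_residual``.
    """
    if shell.kind != "shell":
        raise ValueError("conductor model must be a shell")
    mesh = shell.mesh
    center = fit_sphere(mesh).center
    tm = mesh.as_trimesh()
    centroids = (np.asarray(tm.triangles_center) - center) * _MM
    fnorm = np.asarray(tm.face_normals, dtype=np.float64)
    areas = mesh.face_areas
    w = np.sqrt(areas / areas.sum())

    # nested exterior point-source basis, three radial layers
    n_dirs = (shell.order + 1) ** 2 - 1
    rmax = np.linalg.norm(mesh.vertices - center, axis=1).max() * _MM
    dirs = _fibonacci_directions(n_dirs)
    basis_pts = np.vstack([rf * rmax * dirs for rf in _BASIS_LAYER_RADII])

    def basis_grad(points):  # (np, nb, 3): grad of 1/|r - p_j|
        d = points[:, None, :] - basis_pts[None, :, :]
        return -d / (np.linalg.norm(d, axis=2) ** 3)[..., None]

    A = np.einsum("mk,mjk->mj", fnorm, basis_grad(centroids)) * w[:, None]

    sens_rel = (array.channel_positions - center) * _MM
    ori = array.channel_orientations
    linf_surf = _linf(sens_rel, ori, centroids)  # (nc, nf, 3)
    rhs = -np.einsum("mk,cmk->mc", fnorm, linf_surf) * w[:, None]

    coeff, _, _, _ = np.linalg.lstsq(A, rhs, rcond=None)
    rel = np.linalg.norm(A @ coeff - rhs) / np.linalg.norm(rhs)
    if rel > residual_tol:
        warnings.warn(
            "single-shell boundary fit residual above tolerance: "
            f"{rel:.3g} (order {shell.order}); "
            "consider a higher expansion order",
            RuntimeWarning,
            stacklevel=2,
        )

    src_rel = (sources.positions - center) * _MM
    linf_src = _linf(sens_rel, ori, src_rel)  # (nc, ns, 3)
    grad_src = basis_grad(src_rel)  # (ns, nb, 3)
    corr = np.einsum("jc,njk->cnk", coeff, grad_src)
    gains = np.einsum("cnk,nk->cn", linf_src + corr, sources.orientations)
    lf = LeadField(gains * _UNIT_SCALE, sources, tuple(array.channel_names))
    object.__setattr__(lf, "boundary_residual", float(rel))
    return lf


def brain_shell(head, margin: float = 6.0, order: int = 3) -> TriangleMesh:
    """Boundary surface for the single-shell model of a synthetic head.

    For each direction of an icosphere template, the radius is the
    largest cortex-vertex radius within a 20-degree cone plus
    ``margin`` mm, which keeps every cortical source strictly inside
    while following the cortex's large-scale shape.
    """
    from .geometry import make_icosphere

    template = make_icosphere(order, 1.0)
    dirs = template.vertices
    cv = head.cortex.vertices
    cr = np.linalg.norm(cv, axis=1)
    cd = cv / cr[:, None]
    cos_ang = dirs @ cd.T  # (n_dirs, n_cortex)
    radii = np.empty(len(dirs))
    cone = np.cos(np.deg2rad(20.0))
    for i in range(len(dirs)):
        sel = cos_ang[i] >= cone
        radii[i] = (cr[sel].max() if sel.any() else cr.max()) + margin
    return TriangleMesh(dirs * radii[:, None], template.faces)
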