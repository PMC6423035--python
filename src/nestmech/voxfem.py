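"""Voxel-hexahedral linear-elastic finite elements for segmented volumes.

Every material voxel becomes one 8-node trilinear brick element with shared
nodes (the micro-FE convention common for μCT-derived structures).  The
material is isotropic at the element level — structural anisotropy arises
from geometry alone.  Element stiffness uses full 2x2x2 Gauss quadrature of
the isotropic Hooke law; because all elements are identical cubes, a single
24x24 stiffness matrix is assembled over the mesh.  Gravity enters as a
consistent body force (equal 1/8 nodal shares of rho*g*V per element) with
per-element densities proportional to mean grayscale, rescaled so the total
model mass matches a measured nest mass.  Constraints are fully pinned nodes
(zero displacement in all directions) on the wall face; named load sets
distribute each external force equally over their node set.

The linear system is solved with Jacobi-preconditioned conjugate gradients
to a relative residual of 1e-8 (fixed ordering, deterministic on a given
platform); failure to converge raises, never returns silently.  Stresses are
recovered at element centroids and the maximum principal stress (largest
eigenvalue of the symmetric stress tensor, tension positive) is reported —
the fracture criterion appropriate for a brittle material.

Unit system: mm - N - MPa - tonne/mm^3, with g = 9806.65 mm/s^2.  In these
units 1 tonne/mm^3 x mm^3 x mm/s^2 = 1 N, so an elastic modulus in MPa and
forces in N can be used without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .volume_io import MaskVolume, VoxelVolume, axis_index

#: standard gravity, mm/s^2
G_MM_S2 = 9806.65

#: grams -> tonnes
G_TO_TONNE = 1e-6


class FEError(RuntimeError):
    """Invalid model construction or solver failure."""


# local corner offsets, VTK hexahedron ordering in (axis0, axis1, axis2)
_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)


def hooke_isotropic(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt order
    (xx, yy, zz, yz, xz, xy) with engineering shear strains."""
    if E <= 0:
        raise FEError("E must be > 0")
    if not (0 <= nu < 0.5):
        raise FEError("nu must be in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """d(N_a)/d(x_i) at local point xi in [-1,1]^3 for a cube of edge h.

    Returns (8, 3); the Jacobian of the cube map is (h/2) I.
    """
    signs = _CORNERS * 2 - 1  # corners in {-1, +1}
    g = np.empty((8, 3))
    for a in range(8):
        s = signs[a]
        g[a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
        g[a, 1] = 0.125 * (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2])
        g[a, 2] = 0.125 * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2]
    return g * (2.0 / h)


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) from shape gradients (8 x 3).

    DOF order is node-major (u0x, u0y, u0z, u1x, ...), Voigt order as in
    :func:`hooke_isotropic`.
    """
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def hex_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cube element of edge h, full 2x2x2 quadrature."""
    D = hooke_isotropic(E, nu)
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    K = np.zeros((24, 24))
    detJ_w = (h / 2.0) ** 3  # unit Gauss weights
    for x in gp:
        for y in gp:
            for z in gp:
                B = _b_matrix(_shape_gradients(np.array([x, y, z]), h))
                K += B.T @ D @ B * detJ_w
    return K


@dataclass
class MaterialModel:
    """Linear elastic isotropic material with grayscale-derived density.

    ``density`` (tonne/mm^3 per element) is filled in by
    :func:`build_model`, rescaled so the summed element mass equals
    ``total_mass_g``.
    """

    E: float = 155.0             # MPa
    nu: float = 0.3
    total_mass_g: float | None = None
    density: np.ndarray | None = None   # per element, tonne/mm^3

    def __post_init__(self):
        hooke_isotropic(self.E, self.nu)  # validates


@dataclass
class LoadROI:
    """A named region where an external force is applied.

    ``kind='cuboid'`` selects by an axis-aligned box in mm; ``kind='ellipse'``
    by an elliptic cylinder along U-D (plan-view ellipse in the B-F/R-L
    plane).  The force is resolved onto exterior material nodes with an
    upward-exposed face inside the region and split equally among them.
    Only nodes within ``surface_band`` (mm) of the highest selected node
    carry load: a standing bird or resting egg contacts the top surface,
    not crater floors or ledges further down the same plan footprint.
    """

    name: str
    force: np.ndarray                  # total force vector (N)
    kind: str = "cuboid"
    center: tuple = (0.0, 0.0, 0.0)    # mm (U-D, B-F, R-L); U-D ignored
    size: tuple = (5.0, 5.0)           # (B-F, R-L) extents or ellipse axes, mm
    surface_band: float = 1.5          # mm below the top contact node

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        if self.force.shape != (3,):
            raise FEError("ROI force must be a 3-vector")
        if self.kind not in ("cuboid", "ellipse"):
            raise FEError(f"unknown ROI kind {self.kind!r}")


@dataclass
class FEModel:
    nodes: np.ndarray                  # (n_nodes, 3) mm
    elements: np.ndarray               # (n_elems, 8) node ids
    elem_index: np.ndarray             # (n_elems, 3) voxel indices
    spacing: float                     # element edge, mm
    pinned_nodes: np.ndarray           # node ids, fully pinned
    load_sets: dict                    # name -> (node ids, total force (3,))
    material: MaterialModel
    shape: tuple = None                # voxel grid shape

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def node_sets(self) -> dict:
        out = {"pinned": self.pinned_nodes}
        for name, (ids, _f) in self.load_sets.items():
            out[name] = ids
        return out

    def total_applied_force(self, gravity: bool = False) -> np.ndarray:
        f = np.zeros(3)
        for _name, (_ids, force) in self.load_sets.items():
            f = f + force
        if gravity:
            w = self.material.density * self.spacing ** 3 * G_MM_S2
            f = f + np.array([-w.sum(), 0.0, 0.0])
        return f


@dataclass
class StressField:
    displacements: np.ndarray          # (n_nodes, 3) mm
    stress_tensor: np.ndarray          # (n_elems, 6) Voigt, MPa, at centroids
    max_principal: np.ndarray          # (n_elems,) MPa, tension positive
    iterations: int
    residual: float

    def tensor_matrix(self, e: int) -> np.ndarray:
        xx, yy, zz, yz, xz, xy = self.stress_tensor[e]
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _node_numbering(mask: np.ndarray):
    """Shared-node numbering of the corner lattice of material voxels."""
    nz = np.argwhere(mask)
    grid_shape = tuple(s + 1 for s in mask.shape)
    corner_flags = np.zeros(grid_shape, dtype=bool)
    for d in _CORNERS:
        corner_flags[nz[:, 0] + d[0], nz[:, 1] + d[1], nz[:, 2] + d[2]] = True
    node_id = np.full(grid_shape, -1, dtype=np.int64)
    node_id[corner_flags] = np.arange(int(corner_flags.sum()))
    elems = np.empty((len(nz), 8), dtype=np.int64)
    for a, d in enumerate(_CORNERS):
        elems[:, a] = node_id[nz[:, 0] + d[0], nz[:, 1] + d[1], nz[:, 2] + d[2]]
    coords = np.argwhere(corner_flags).astype(float)
    return nz, elems, coords, node_id


def exterior_up_nodes(mask: np.ndarray, node_id: np.ndarray) -> np.ndarray:
    """Node ids on upward-exposed material faces (air above along +U-D)."""
    up_exposed = np.empty_like(mask)
    up_exposed[-1] = mask[-1]
    up_exposed[:-1] = mask[:-1] & ~mask[1:]
    vox = np.argwhere(up_exposed)
    ids = []
    for dj, dk in ((0, 0), (0, 1), (1, 0), (1, 1)):
        ids.append(node_id[vox[:, 0] + 1, vox[:, 1] + dj, vox[:, 2] + dk])
    return np.unique(np.concatenate(ids))


def _roi_select(node_xyz: np.ndarray, roi: LoadROI) -> np.ndarray:
    """Boolean selector over node coordinates for the ROI plan footprint."""
    cy, cl = roi.center[1], roi.center[2]
    y, l = node_xyz[:, 1], node_xyz[:, 2]
    if roi.kind == "cuboid":
        hy, hl = roi.size[0] / 2.0, roi.size[1] / 2.0
        return (np.abs(y - cy) <= hy) & (np.abs(l - cl) <= hl)
    ay, al = roi.size[0] / 2.0, roi.size[1] / 2.0
    return ((y - cy) / ay) ** 2 + ((l - cl) / al) ** 2 <= 1.0


def build_model(mask: MaskVolume, gray: VoxelVolume | None,
                material: MaterialModel, pin_axis="B-F", pin_face: int = 0,
                load_rois: list | None = None) -> FEModel:
    """Mesh the material mask and attach constraints, loads and densities.

    One hexahedral element per material voxel with shared nodes.  Element
    densities are proportional to the voxel's grayscale (uniform when
    ``gray`` is None) and rescaled so the summed mass equals
    ``material.total_mass_g`` (skipped when no target mass is set).
    Pinned nodes are the material nodes lying on the requested grid face
    (default: the wall face, B-F index 0).  Each load ROI is resolved to the
    exterior up-facing material nodes it intersects; an ROI that catches no
    node (placed "in air") is an error.
    """
    m = mask.data
    if not m.any():
        raise FEError("empty material mask")
    if gray is not None and gray.data.shape != m.shape:
        raise FEError("grayscale and mask grids differ")

    nz, elems, coords, node_id = _node_numbering(m)
    spacing = mask.spacing
    nodes = coords * spacing

    ax = axis_index(pin_axis)
    face_coord = 0 if pin_face == 0 else m.shape[ax]
    pinned = np.flatnonzero(coords[:, ax] == face_coord)
    if pinned.size == 0:
        raise FEError(
            "no material nodes on the pinned face: the model would float freely"
        )

    # grayscale-proportional density, calibrated to the target mass
    mat = MaterialModel(material.E, material.nu, material.total_mass_g)
    vv = spacing ** 3
    if gray is not None:
        g = gray.data[nz[:, 0], nz[:, 1], nz[:, 2]].astype(float)
        g = np.maximum(g, 1e-3)
    else:
        g = np.ones(len(nz))
    if mat.total_mass_g is not None:
        rho = g / (g.sum() * vv) * (mat.total_mass_g * G_TO_TONNE)
    else:
        rho = np.zeros(len(nz))
    mat.density = rho

    up_nodes = exterior_up_nodes(m, node_id)
    load_sets = {}
    for roi in (load_rois or []):
        sel = _roi_select(nodes[up_nodes], roi)
        ids = up_nodes[sel]
        if ids.size == 0:
            raise FEError(f"load ROI {roi.name!r} intersects no material surface")
        u = nodes[ids, 0]
        ids = ids[u >= u.max() - roi.surface_band]
        load_sets[roi.name] = (ids, roi.force.copy())

    return FEModel(nodes=nodes, elements=elems, elem_index=nz, spacing=spacing,
                   pinned_nodes=pinned, load_sets=load_sets, material=mat,
                   shape=m.shape)


# ---------------------------------------------------------------------------
# assembly and solution
# ---------------------------------------------------------------------------

def assemble_stiffness(model: FEModel) -> sparse.csr_matrix:
    """Global stiffness in CSR form (all elements share one cube stiffness)."""
    Ke = hex_stiffness(model.material.E, model.material.nu, model.spacing)
    dofs = (model.elements[:, :, None] * 3
            + np.arange(3)[None, None, :]).reshape(len(model.elements), 24)
    dofs = dofs.astype(np.int32)  # halves assembly memory on large meshes
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    data = np.tile(Ke.ravel(), len(model.elements))
    n = model.n_nodes * 3
    K = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return K


def load_vector(model: FEModel, gravity: bool = True) -> np.ndarray:
    """Global nodal force vector: equal shares over load sets, plus the
    consistent gravity body force (equal 1/8 shares, directed along -U-D)."""
    f = np.zeros(model.n_nodes * 3)
    for _name, (ids, force) in model.load_sets.items():
        share = force / len(ids)
        for c in range(3):
            if share[c] != 0.0:
                np.add.at(f, ids * 3 + c, share[c])
    if gravity and model.material.density is not None:
        w_elem = model.material.density * model.spacing ** 3 * G_MM_S2  # N
        share = np.repeat(w_elem / 8.0, 8)
        np.add.at(f, model.elements.ravel() * 3 + 0, -share)
    return f


def _pcg(K: sparse.csr_matrix, f: np.ndarray, rtol: float, maxiter: int):
    """Jacobi-preconditioned conjugate gradients, fixed ordering."""
    d = K.diagonal()
    if np.any(d <= 0):
        raise FEError("singular system: non-positive stiffness diagonal "
                      "(insufficient constraints?)")
    Minv = 1.0 / d
    x = np.zeros_like(f)
    r = f.copy()
    fnorm = np.linalg.norm(f)
    if fnorm == 0.0:
        return x, 0, 0.0
    z = Minv * r
    p = z.copy()
    rz = r @ z
    for it in range(1, maxiter + 1):
        Kp = K @ p
        alpha = rz / (p @ Kp)
        x += alpha * p
        r -= alpha * Kp
        res = np.linalg.norm(r) / fnorm
        if res <= rtol:
            return x, it, res
        z = Minv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise FEError(
        f"PCG failed to converge: residual {res:.3e} after {maxiter} iterations"
    )


def solve(model: FEModel, gravity: bool = True, rtol: float = 1e-8,
          maxiter: int = 50_000) -> StressField:
    """Solve the pinned model and recover centroid stresses.

    Raises :class:`FEError` on non-convergence or a singular system.
    """
    K = assemble_stiffness(model)
    f = load_vector(model, gravity=gravity)

    n_dof = model.n_nodes * 3
    free = np.ones(n_dof, dtype=bool)
    pinned_dofs = (model.pinned_nodes[:, None] * 3 + np.arange(3)).ravel()
    free[pinned_dofs] = False
    free_idx = np.flatnonzero(free)

    Kff = K[free_idx][:, free_idx]
    uf, iters, res = _pcg(Kff, f[free_idx], rtol, maxiter)

    u = np.zeros(n_dof)
    u[free_idx] = uf

    S = centroid_stress(model, u)
    smax = max_principal(S)
    return StressField(displacements=u.reshape(-1, 3), stress_tensor=S,
                       max_principal=smax, iterations=iters, residual=res)


def centroid_stress(model: FEModel, u: np.ndarray) -> np.ndarray:
    """Per-element Voigt stress at the element centroid (single-point
    recovery, no Gauss extrapolation)."""
    D = hooke_isotropic(model.material.E, model.material.nu)
    B0 = _b_matrix(_shape_gradients(np.zeros(3), model.spacing))
    DB = D @ B0  # (6, 24)
    dofs = (model.elements[:, :, None] * 3
            + np.arange(3)[None, None, :]).reshape(len(model.elements), 24)
    return u[dofs] @ DB.T


def max_principal(voigt: np.ndarray) -> np.ndarray:
    """Largest principal stress (tension positive) per element."""
    T = voigt_to_tensor(voigt)
    return np.linalg.eigvalsh(T)[..., -1]


def voigt_to_tensor(voigt: np.ndarray) -> np.ndarray:
    v = np.asarray(voigt, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    T = np.empty((len(v), 3, 3))
    T[:, 0, 0] = v[:, 0]
    T[:, 1, 1] = v[:, 1]
    T[:, 2, 2] = v[:, 2]
    T[:, 1, 2] = T[:, 2, 1] = v[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = v[:, 4]
    T[:, 0, 1] = T[:, 1, 0] = v[:, 5]
    return T[0] if single else T


def principal_stress(tensor: np.ndarray) -> tuple:
    """Principal stresses of one symmetric 3x3 tensor, sorted descending."""
    T = np.asarray(tensor, dtype=float)
    if T.shape != (3, 3):
        raise FEError("expected a 3x3 tensor")
    if not np.allclose(T, T.T, atol=1e-9 * max(1.0, np.abs(T).max())):
        raise FEError("stress tensor must be symmetric")
    vals = np.linalg.eigvalsh(T)
    return tuple(vals[::-1])


def reaction_forces(model: FEModel, field: StressField,
                    gravity: bool = True) -> np.ndarray:
    """Nodal reactions at pinned nodes: (K u - f) restricted to pinned DOFs.

    In equilibrium their sum equals minus the total applied load.
    """
    K = assemble_stiffness(model)
    f = load_vector(model, gravity=gravity)
    u = field.displacements.ravel()
    r = K @ u - f
    pinned_dofs = (model.pinned_nodes[:, None] * 3 + np.arange(3)).ravel()
    return r[pinned_dofs].reshape(-1, 3)


def apply_damage(mask: MaskVolume, sites: list) -> MaskVolume:
    """Remove material inside spherical damage sites.

    ``sites`` is a list of ``((u, y, l) center in mm, radius in mm)``.  The
    caller re-runs closed-pore classification downstream.  Removing the
    entire pinned wall face is rejected.
    """
    m = mask.data.copy()
    s = mask.spacing
    for center, radius in sites:
        if radius < 0:
            raise FEError("damage radius must be >= 0")
        if radius == 0:
            continue
        c = np.asarray(center, dtype=float)
        lo = np.maximum(np.floor((c - radius) / s - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c + radius) / s + 0.5).astype(int) + 1,
                        np.array(m.shape))
        if np.any(lo >= hi):
            continue
        sub = np.meshgrid(*[(np.arange(a, b) + 0.5) * s for a, b in zip(lo, hi)],
                          indexing="ij")
        ball = sum((g - ci) ** 2 for g, ci in zip(sub, c)) <= radius ** 2
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] &= ~ball
    if mask.data[:, 0, :].any() and not m[:, 0, :].any():
        raise FEError("damage removed the entire wall-anchored face")
    return MaskVolume(m, s, mask.axes)
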