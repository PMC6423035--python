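"""Synthetic nest phantom: a seeded stand-in for a μCT scan of an
edible-nest swiftlet nest, with ground-truth material and closed-pore masks.

The phantom emulates the architecture reported for real nests: a spherical
half-cup shell (~77.5 mm right-left x 39.8 mm up-down, ~5.93 g) anchored to
a vertical wall, built from horizontally deposited saliva strands.  The
shell is the region between two concentric half-ellipsoids clipped at the
horizontal rim plane and at the wall plane, with wall thickness graded from
a thick anchor to a thin rim and a slight flare of the anchor pad onto the
wall.  The strand texture is emulated by carving a quasi-periodic lattice of
ellipsoidal voids elongated along the R-L axis; the acceptance probability
of each candidate void follows a linear porosity ramp from anchor to rim, so
closed porosity increases back to front while the cross-section decreases —
the two gradients the real nests show.  Voids that would open onto the
exterior (or the cup cavity) are filled back, keeping every ground-truth
pore closed.

Grayscale is painted from per-region means (anchor denser and brighter than
rim, mirroring the density gradient) plus clipped additive Gaussian noise.
Beam hardening, ring artifacts and scanner physics are not modelled.  The
per-voxel mass density is *not* assigned here: the finite-element stage
calibrates grayscale-proportional densities against the target mass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

import yaml

from .segmentation import CONN6
from .volume_io import LabelVolume, MaskVolume, VoxelVolume
from . import morphometrics


class PhantomError(ValueError):
    """Invalid phantom parameters or an unbuildable geometry request."""


@dataclass
class PhantomParams:
    """Geometry, texture and imaging parameters of the synthetic nest.

    Lengths in mm, mass in g, grayscale in 8-bit units.  The overall
    dimensions and mass follow the measured nests; the depth (B-F extent)
    and wall thicknesses are not reported for real nests and are package
    assumptions (see docs/methods.md).
    """

    width_rl: float = 77.5
    height_ud: float = 39.8
    depth_bf: float = 38.0
    wall_thickness_anchor: float = 6.0
    wall_thickness_rim: float = 4.5
    fiber_pitch: float = 0.25
    porosity_anchor: float = 0.03
    porosity_rim: float = 0.09
    target_mass: float = 5.93
    voxel_spacing: float = 0.35
    noise_sd: float = 8.0
    mat_gray_anchor: float = 90.0
    mat_gray_rim: float = 60.0
    bg_gray: float = 10.0
    seed: int = 42
    max_voxels: int = 300_000_000   # voxel budget guard

    def __post_init__(self):
        for name in ("width_rl", "height_ud", "depth_bf", "wall_thickness_anchor",
                     "wall_thickness_rim", "fiber_pitch", "voxel_spacing",
                     "target_mass"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be > 0")
        if not (0 <= self.porosity_anchor <= self.porosity_rim < 1):
            raise PhantomError(
                "need 0 <= porosity_anchor <= porosity_rim < 1"
            )
        if self.wall_thickness_rim >= self.wall_thickness_anchor:
            raise PhantomError("wall_thickness_rim must be < wall_thickness_anchor")
        for name in ("mat_gray_anchor", "mat_gray_rim", "bg_gray"):
            if not (0 <= getattr(self, name) <= 255):
                raise PhantomError(f"{name} must be within [0, 255]")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.wall_thickness_rim < self.voxel_spacing:
            raise PhantomError(
                f"shell thinner than one voxel at the rim "
                f"({self.wall_thickness_rim} mm < {self.voxel_spacing} mm spacing)"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class PhantomBundle:
    """A phantom image plus its ground truth, all on one grid."""

    image: VoxelVolume
    material_truth: MaskVolume
    pore_truth: LabelVolume
    params: PhantomParams


_PAD = 2  # air voxels around the nest (except the wall face)


def generate_phantom(params: PhantomParams | None = None) -> PhantomBundle:
    """Build the seeded synthetic nest volume.

    Identical parameters and seed give bit-identical output.  Raises
    :class:`PhantomError` if the requested grid exceeds the voxel budget or
    the geometry degenerates below one voxel of shell thickness.
    """
    p = params or PhantomParams()
    s = p.voxel_spacing

    n0 = int(np.ceil(p.height_ud / s)) + 2 * _PAD
    n1 = int(np.ceil(p.depth_bf / s)) + _PAD           # wall face at j = 0
    n2 = int(np.ceil(p.width_rl / s)) + 2 * _PAD
    if n0 * n1 * n2 > p.max_voxels:
        raise PhantomError(
            f"requested grid {n0}x{n1}x{n2} = {n0 * n1 * n2} voxels exceeds "
            f"the voxel budget of {p.max_voxels}"
        )

    # physical voxel-center coordinates with the nest at u,l >= 0, wall at y=0
    u = (np.arange(n0) + 0.5) * s - _PAD * s
    y = (np.arange(n1) + 0.5) * s
    l = (np.arange(n2) + 0.5) * s - _PAD * s
    U = u[:, None, None]
    Y = y[None, :, None]
    L = l[None, None, :]

    H, D, W = p.height_ud, p.depth_bf, p.width_rl
    a_u, a_y, a_l = H, D, W / 2.0

    yhat = np.clip(Y / a_y, 0.0, 1.0)
    t = p.wall_thickness_anchor + (p.wall_thickness_rim - p.wall_thickness_anchor) * yhat
    # anchor pad flared onto the wall: extra inward thickening near y = 0
    # (spreads material over the wall plane without growing the outer hull,
    # so the overall dimensions stay at the nominal envelope)
    t = t + 0.5 * p.wall_thickness_anchor * np.clip(
        1.0 - Y / p.wall_thickness_anchor, 0.0, 1.0) ** 2

    du = U - H
    dl = L - W / 2.0
    r_out = (du / a_u) ** 2 + (Y / a_y) ** 2 + (dl / a_l) ** 2
    r_in = (du / np.maximum(a_u - t, s)) ** 2 + (Y / np.maximum(a_y - t, s)) ** 2 \
        + (dl / np.maximum(a_l - t, s)) ** 2

    shell = (r_out <= 1.0) & (r_in >= 1.0) & (U <= H) & (Y >= 0)
    if not shell.any():
        raise PhantomError("degenerate geometry: empty shell")

    rng = np.random.default_rng(p.seed)
    voids = _strand_voids(p, shell, rng, n0, n1, n2, yhat)

    material = shell & ~voids
    # fill back any carved air connected to the exterior so all pores close
    air_labels, _ = ndimage.label(~material, structure=CONN6)
    exterior = _border_label_mask(air_labels)
    reopen = voids & shell & exterior
    material |= reopen

    carved = shell & ~material
    pore_labels, n_pores = ndimage.label(carved, structure=CONN6)
    pore_truth = LabelVolume(pore_labels, s, label_count=n_pores)

    gray = _paint_grayscale(p, material, yhat, rng)

    return PhantomBundle(
        image=VoxelVolume(gray, s),
        material_truth=MaskVolume(material, s),
        pore_truth=pore_truth,
        params=p,
    )


def _strand_voids(p, shell, rng, n0, n1, n2, yhat):
    """Quasi-periodic lattice of R-L-elongated ellipsoidal voids.

    The lattice pitch derives from ``fiber_pitch`` in voxels, clamped to
    >= 6 voxels so voids stay resolvable at coarse desk spacings (at 34 um
    spacing the clamp is inactive).  Acceptance probability per site follows
    the linear anchor->rim porosity ramp normalized by the lattice's maximum
    achievable porosity, and sites are only eligible where the void plus a
    one-voxel material margin fits inside the shell — which keeps every
    carved pore closed by construction.
    """
    pitch = max(int(round(p.fiber_pitch / p.voxel_spacing)), 6)
    pitch_rl = int(round(2.2 * pitch))
    semi = np.array([0.28 * pitch, 0.28 * pitch, 0.28 * pitch_rl])
    # voxelized void extent (odd box) and closure margin for site eligibility
    ext = 2 * np.floor(semi).astype(int) + 1
    void_vol = 4.0 / 3.0 * np.pi * semi.prod()
    cell_vol = pitch * pitch * pitch_rl
    p_max = void_vol / cell_vol
    if p.porosity_rim > p_max:
        raise PhantomError(
            f"porosity_rim {p.porosity_rim:.3f} exceeds the lattice maximum "
            f"{p_max:.3f}; increase void size or lower the target"
        )

    # two-voxel closure margin: survives the one-voxel boundary erosion of
    # the default smoothing + threshold without pores leaking to the exterior
    fits = ndimage.minimum_filter(shell, size=tuple(ext + 4), mode="constant")

    ii = np.arange(pitch // 2, n0, pitch)
    jj = np.arange(pitch // 2, n1, pitch)
    kk = np.arange(pitch_rl // 2, n2, pitch_rl)
    ci, cj, ck = np.meshgrid(ii, jj, kk, indexing="ij")
    # stagger alternate U-D rows by half a pitch in R-L (quasi-periodic weave)
    ck = ck + (np.arange(len(ii))[:, None, None] % 2) * (pitch_rl // 2)
    centers = np.column_stack([ci.ravel(), cj.ravel(), ck.ravel()]).astype(float)
    centers += rng.uniform(-0.6, 0.6, centers.shape)  # jitter

    # porosity target at each site from its B-F position
    site_yhat = np.clip((centers[:, 1] + 0.5) / (p.depth_bf / p.voxel_spacing), 0, 1)
    p_target = p.porosity_anchor + (p.porosity_rim - p.porosity_anchor) * site_yhat
    accept = rng.random(len(centers)) < (p_target / p_max)
    centers = np.round(centers[accept]).astype(int)
    inside = ((centers >= 0) & (centers < np.array(shell.shape))).all(axis=1)
    centers = centers[inside]
    centers = centers[fits[centers[:, 0], centers[:, 1], centers[:, 2]]]

    voids = np.zeros(shell.shape, dtype=bool)
    ri, rj, rk = np.floor(semi).astype(int)
    di = np.arange(-ri, ri + 1)
    dj = np.arange(-rj, rj + 1)
    dk = np.arange(-rk, rk + 1)
    DI, DJ, DK = np.meshgrid(di, dj, dk, indexing="ij")
    ball = (DI / semi[0]) ** 2 + (DJ / semi[1]) ** 2 + (DK / semi[2]) ** 2 <= 1.0
    offs = np.column_stack([DI[ball], DJ[ball], DK[ball]])

    for c in centers:
        vox = c + offs
        voids[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return voids & shell


def _border_label_mask(labels: np.ndarray) -> np.ndarray:
    border = set()
    for f in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
              labels[:, :, 0], labels[:, :, -1]):
        border.update(np.unique(f).tolist())
    border.discard(0)
    lut = np.zeros(int(labels.max()) + 1, dtype=bool)
    lut[list(border)] = True
    return lut[labels]


def _paint_grayscale(p, material, yhat, rng):
    mat_gray = p.mat_gray_anchor + (p.mat_gray_rim - p.mat_gray_anchor) * yhat
    gray = np.broadcast_to(mat_gray, material.shape) * material \
        + p.bg_gray * (~material)
    if p.noise_sd > 0:
        gray = gray + rng.normal(0.0, p.noise_sd, material.shape)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def ground_truth_profiles(bundle: PhantomBundle, axis) -> morphometrics.SliceProfile:
    """Reference per-slice material area and closed-pore percentage computed
    from the ground-truth masks (the oracle for segmentation recovery)."""
    return morphometrics.slice_profile(bundle.material_truth, bundle.pore_truth, axis)


def save_bundle(bundle: PhantomBundle, outdir) -> dict:
    """Write image, truth masks (TIFF + sidecars) and params YAML to a
    directory; returns the path map."""
    from pathlib import Path
    from .volume_io import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "image.tif",
        "material_truth": outdir / "material_truth.tif",
        "pore_truth": outdir / "pore_truth.tif",
        "params": outdir / "params.yaml",
    }
    write_volume(bundle.image, paths["image"])
    write_volume(bundle.material_truth, paths["material_truth"])
    write_volume(bundle.pore_truth, paths["pore_truth"])
    bundle.params.to_yaml(paths["params"])
    return paths
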