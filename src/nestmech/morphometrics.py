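"""Structural descriptors of a segmented nest.

Whole-nest quantities (material volume, surface area, mean density),
slice-by-slice profiles along any of the three anatomical axes, and per-pore
shape statistics from the multi-label closed-pore mask.

Surface area uses exposed voxel-face counting.  This estimator is exactly
computable and deterministic, but for smooth bodies it converges to 1.5x the
true area (the staircase bias of axis-aligned faces); it is therefore used
comparatively — e.g. the anchor-to-rim surface-area profile — never as an
absolute area.  Pore orientation comes from the second-moment (inertia)
tensor of each pore's voxel centers; for a uniform solid ellipsoid the
covariance eigenvalue along a semi-axis a is a^2/5, so full principal
lengths are reported as 2*sqrt(5*lambda), which recovers analytic ellipsoids
exactly in the continuum limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import LabelVolume, MaskVolume, axis_index, AXES


@dataclass
class NestSummary:
    material_volume: float          # mm^3
    total_surface_area: float       # mm^2 (face-count estimator)
    closed_pore_count: int
    closed_pore_volume: float       # mm^3
    mass: float | None = None       # g, user supplied
    mean_density: float | None = None  # g/mm^3 = mass / material_volume

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class SliceProfile:
    """Per-slice material area, surface-area contribution and closed-pore
    percentage along one axis."""

    axis: str
    positions: np.ndarray        # physical slice-center coordinate (mm)
    indices: np.ndarray
    material_area: np.ndarray    # mm^2
    surface_area: np.ndarray     # mm^2, faces owned by the slice's voxels
    closed_pore_pct: np.ndarray  # 100 * pore / (pore + material), 0 if empty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": self.axis,
            "slice_index": self.indices,
            "position_mm": self.positions,
            "material_area_mm2": self.material_area,
            "surface_area_mm2": self.surface_area,
            "closed_pore_pct": self.closed_pore_pct,
        })


@dataclass
class PoreStats:
    label: int
    volume: float                    # mm^3
    centroid: tuple                  # mm
    principal_lengths: tuple         # mm, sorted descending
    major_axis: tuple                # unit vector
    angles_to_axes: tuple            # degrees to U-D, B-F, R-L in [0, 90]
    elongation: float                # major / minor, >= 1
    degenerate: bool = False         # single voxel / zero variance
    near_isotropic: bool = False     # elongation < 1.1: angles unreliable


def exposed_faces(mask: np.ndarray) -> list:
    """Per-axis arrays of exposed-face counts, attributed to the material
    voxel owning the face. Returns a (3, 2)-nested list of boolean arrays
    [axis][low/high side] of shape == mask."""
    out = []
    for ax in range(3):
        m = np.moveaxis(mask, ax, 0)
        low = np.empty_like(m)
        low[0] = m[0]
        low[1:] = m[1:] & ~m[:-1]
        high = np.empty_like(m)
        high[-1] = m[-1]
        high[:-1] = m[:-1] & ~m[1:]
        out.append([np.moveaxis(low, 0, ax), np.moveaxis(high, 0, ax)])
    return out


def surface_area(mask: MaskVolume) -> float:
    """Total exposed material-face area (mm^2), face-count estimator."""
    faces = exposed_faces(mask.data)
    n = sum(int(side.sum()) for ax in faces for side in ax)
    return n * mask.spacing ** 2


def summarize(mask: MaskVolume, pores: LabelVolume | None = None,
              mass: float | None = None) -> NestSummary:
    """Whole-nest morphometrics.

    ``mass`` (g) is a user-supplied measurement; mean density is
    mass / material volume and is reported only when mass is given.
    """
    if pores is not None and pores.data.shape != mask.data.shape:
        raise ValueError("mask and pore volumes must share a grid")
    vv = mask.spacing ** 3
    vol = mask.count() * vv
    area = surface_area(mask) if mask.count() else 0.0
    n_pores = int(pores.label_count) if pores is not None else 0
    pore_vol = float((pores.data > 0).sum()) * vv if pores is not None else 0.0
    density = (mass / vol) if (mass is not None and vol > 0) else None
    return NestSummary(vol, area, n_pores, pore_vol, mass, density)


def slice_profile(mask: MaskVolume, pores: LabelVolume | None,
                  axis) -> SliceProfile:
    """Slice-by-slice profile along ``axis`` (U-D, B-F or R-L).

    The closed-pore percentage denominator is material + pore voxels in the
    slice (exterior air excluded), so the profile does not depend on
    bounding-box padding; empty slices report 0.
    """
    ax = axis_index(axis)
    if pores is not None and pores.data.shape != mask.data.shape:
        raise ValueError("mask and pore volumes must share a grid")
    m = mask.data
    sum_axes = tuple(i for i in range(3) if i != ax)
    mat_counts = m.sum(axis=sum_axes).astype(np.int64)

    face_counts = np.zeros_like(mat_counts)
    for per_side in exposed_faces(m):
        for side in per_side:
            face_counts += side.sum(axis=sum_axes)

    if pores is not None:
        pore_counts = (pores.data > 0).sum(axis=sum_axes).astype(np.int64)
    else:
        pore_counts = np.zeros_like(mat_counts)

    denom = mat_counts + pore_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * pore_counts / np.maximum(denom, 1), 0.0)

    s = mask.spacing
    idx = np.arange(m.shape[ax])
    return SliceProfile(
        axis=AXES[ax],
        positions=(idx + 0.5) * s,
        indices=idx,
        material_area=mat_counts * s * s,
        surface_area=face_counts * s * s,
        closed_pore_pct=pct,
    )


def pore_orientation(pores: LabelVolume) -> list:
    """Per-pore inertia-tensor shape statistics.

    Principal lengths are full axis lengths 2*sqrt(5 * eigenvalue) of the
    voxel-center covariance (uniform-ellipsoid identity); angles are between
    the major principal axis and each anatomical axis, folded to [0, 90]
    degrees since pore orientation is sign-free.  Single-voxel (or otherwise
    zero-variance) pores are flagged degenerate with elongation 1 and NaN
    angles; nearly isotropic pores keep their angles but carry a flag.
    """
    data = pores.data
    s = pores.spacing
    stats: list[PoreStats] = []
    if pores.label_count == 0:
        return stats

    flat = data.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    start = np.searchsorted(sorted_labels, np.arange(1, pores.label_count + 2))
    coords_all = np.column_stack(np.unravel_index(order, data.shape))

    for lab in range(1, pores.label_count + 1):
        vox = coords_all[start[lab - 1]:start[lab]]
        n = len(vox)
        xyz = (vox + 0.5) * s
        centroid = xyz.mean(axis=0)
        vol = n * s ** 3
        if n == 1:
            stats.append(PoreStats(lab, vol, tuple(centroid), (s, s, s),
                                   (np.nan,) * 3, (np.nan,) * 3, 1.0,
                                   degenerate=True))
            continue
        cov = np.cov((xyz - centroid).T, bias=True)
        # voxels are cubes, not points: add each voxel's own uniform second
        # moment so principal lengths stay unbiased for few-voxel-thick pores
        cov += np.eye(3) * (s * s / 12.0)
        evals, evecs = np.linalg.eigh(cov)          # ascending
        evals = np.maximum(evals, 0.0)
        lengths = 2.0 * np.sqrt(5.0 * evals)[::-1]  # descending
        major = evecs[:, -1]
        if lengths[-1] <= 0:
            stats.append(PoreStats(lab, vol, tuple(centroid), tuple(lengths),
                                   tuple(major), (np.nan,) * 3, np.inf,
                                   degenerate=True))
            continue
        elong = lengths[0] / lengths[-1]
        angles = np.degrees(np.arccos(np.clip(np.abs(major), 0.0, 1.0)))
        stats.append(PoreStats(lab, vol, tuple(centroid), tuple(lengths),
                               tuple(major / np.linalg.norm(major)),
                               tuple(angles), float(elong),
                               near_isotropic=bool(elong < 1.1)))
    return stats


def pore_table(stats: list) -> pd.DataFrame:
    rows = []
    for p in stats:
        rows.append({
            "label": p.label, "volume_mm3": p.volume,
            "centroid_ud_mm": p.centroid[0], "centroid_bf_mm": p.centroid[1],
            "centroid_rl_mm": p.centroid[2],
            "len_major_mm": p.principal_lengths[0],
            "len_mid_mm": p.principal_lengths[1],
            "len_minor_mm": p.principal_lengths[2],
            "angle_ud_deg": p.angles_to_axes[0],
            "angle_bf_deg": p.angles_to_axes[1],
            "angle_rl_deg": p.angles_to_axes[2],
            "elongation": p.elongation,
            "degenerate": p.degenerate,
            "near_isotropic": p.near_isotropic,
        })
    return pd.DataFrame(rows)
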