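"""Segmentation of nest volumes: smoothing, thresholding, artifact removal,
downsampling, and closed-pore extraction with the small-pore fill rule.

The pipeline order is fixed and mirrors the workflow used for the original
scans: Gaussian smoothing (sigma 1 voxel) -> grayscale window threshold
(40..255 inclusive) -> keep the largest connected component (flood-fill
artifact removal) -> optional linear-interpolation downsampling (34.04 um ->
68.1 um class) -> closed-pore classification, where pores smaller than 125
voxels are filled back into the material mask.

Connectivity convention: 26-connectivity for material/foreground,
6-connectivity for background and pores.  Complementary connectivities avoid
the topological paradox of a "closed" pore leaking through a voxel corner.
The source software's connectivity choices are not published; these defaults
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, MaskVolume, VoxelVolume

CONN26 = np.ones((3, 3, 3), dtype=bool)
CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationParams:
    """Parameters of the segmentation recipe (defaults follow the original
    scan-processing protocol; lengths in voxels of the *input* volume)."""

    gray_low: int = 40
    gray_high: int = 255
    gaussian_sigma: float = 1.0
    resample_factor: int = 2
    min_pore_voxels: int = 125
    material_connectivity: int = 26
    pore_connectivity: int = 6
    resample_before_pores: bool = True

    def __post_init__(self):
        if not (0 <= self.gray_low <= self.gray_high <= 255):
            raise ValueError(
                f"need 0 <= gray_low <= gray_high <= 255, got "
                f"[{self.gray_low}, {self.gray_high}]"
            )
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if int(self.resample_factor) != self.resample_factor or self.resample_factor < 1:
            raise ValueError("resample_factor must be an integer >= 1")
        if self.min_pore_voxels < 1:
            raise ValueError("min_pore_voxels must be >= 1")
        if self.material_connectivity not in (6, 18, 26) or \
                self.pore_connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def smooth(vol: VoxelVolume, sigma: float) -> VoxelVolume:
    """Gaussian smoothing, separable per axis, re-quantized round-half-even.

    The discrete Gaussian kernel is truncated at 4 sigma.  ``sigma = 0`` is
    the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return VoxelVolume(vol.data.copy(), vol.spacing, vol.axes)
    out = ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma=sigma, mode="nearest", truncate=4.0
    )
    return VoxelVolume(
        np.clip(np.rint(out), 0, 255).astype(np.uint8), vol.spacing, vol.axes
    )


def threshold(vol: VoxelVolume, params: SegmentationParams) -> MaskVolume:
    """Window threshold: voxel is material iff gray_low <= value <= gray_high
    (both bounds inclusive, so the 255 end stays reachable)."""
    d = vol.data
    mask = (d >= params.gray_low) & (d <= params.gray_high)
    return MaskVolume(mask, vol.spacing, vol.axes)


def keep_largest_component(mask: MaskVolume, connectivity: int = 26) -> MaskVolume:
    """Retain only the largest connected foreground component.

    Ties are broken deterministically in favour of the component whose first
    voxel comes earliest in raster (C) order.
    """
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 0:
        raise ValueError("mask is empty; no component to keep")
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # earliest first-voxel in raster order wins
        first = [np.argmax(labels.ravel() == b) for b in best]
        winner = best[int(np.argmin(first))]
    else:
        winner = best[0]
    return MaskVolume(labels == winner, mask.spacing, mask.axes)


def downsample(vol, factor: int):
    """Resample by linear interpolation onto a grid ``factor`` times coarser.

    Output spacing = input spacing x factor; output shape = ceil(shape/factor).
    Output voxel centers are mapped into input index space (center-aligned)
    and sampled with trilinear interpolation, clamped at the edges; grayscale
    output is re-quantized round-half-even.  ``factor = 1`` is the identity.
    Works on grayscale volumes and (by nearest-equivalent thresholding at
    0.5) on masks.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    is_mask = isinstance(vol, MaskVolume)
    data = vol.data.astype(np.float64)
    if factor == 1:
        out = data
    else:
        new_shape = tuple(int(np.ceil(s / factor)) for s in data.shape)
        coords = np.meshgrid(
            *[(np.arange(n) + 0.5) * factor - 0.5 for n in new_shape],
            indexing="ij",
        )
        out = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    spacing = vol.spacing * factor
    if is_mask:
        return MaskVolume(out >= 0.5, spacing, vol.axes)
    return VoxelVolume(np.clip(np.rint(out), 0, 255).astype(np.uint8),
                       spacing, vol.axes)


def extract_closed_pores(mask: MaskVolume, params: SegmentationParams):
    """Classify closed pores and apply the small-pore fill rule.

    Background is labelled with 6-connectivity (or ``params.pore_connectivity``);
    every background component touching a volume border belongs to the
    exterior.  The remaining components are closed pores.  Pores smaller than
    ``min_pore_voxels`` are added to the material mask; survivors are
    relabelled 1..N in raster order of their first voxel.

    Returns ``(updated material MaskVolume, pore LabelVolume)``.  Idempotent
    on its own output, and never fills a border-connected cavity.
    """
    material = mask.data.copy()
    labels, n = ndimage.label(~material, structure=_structure(params.pore_connectivity))
    border_labels = _border_labels(labels)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)

    is_pore = np.ones(n + 1, dtype=bool)
    is_pore[0] = False
    is_pore[list(border_labels)] = False

    small = is_pore & (sizes < params.min_pore_voxels)
    if small.any():
        material |= small[labels]

    keep = np.flatnonzero(is_pore & ~small)
    remap = np.zeros(n + 1, dtype=np.uint32)
    remap[keep] = np.arange(1, len(keep) + 1)  # scipy labels in raster order
    pore_labels = remap[labels]

    return (
        MaskVolume(material, mask.spacing, mask.axes),
        LabelVolume(pore_labels, mask.spacing, mask.axes, label_count=len(keep)),
    )


def _border_labels(labels: np.ndarray) -> set:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def downsample_labels(labels: LabelVolume, factor: int) -> LabelVolume:
    """Nearest-neighbour downsampling of a label field (labels renumbered
    contiguously; small labels may vanish at coarse spacing)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return LabelVolume(labels.data.copy(), labels.spacing, labels.axes)
    new_shape = tuple(int(np.ceil(s / factor)) for s in labels.data.shape)
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * factor - 0.5 for n in new_shape], indexing="ij"
    )
    out = ndimage.map_coordinates(labels.data, coords, order=0, mode="nearest")
    survivors = np.unique(out)
    survivors = survivors[survivors > 0]
    remap = np.zeros(int(labels.data.max()) + 1, dtype=np.uint32)
    remap[survivors] = np.arange(1, len(survivors) + 1)
    return LabelVolume(remap[out], labels.spacing * factor, labels.axes,
                       label_count=len(survivors))


def segment(vol: VoxelVolume, params: SegmentationParams | None = None):
    """Full pipeline: smooth -> threshold -> largest component ->
    downsample -> closed pores.

    Returns ``(material mask, pore labels, provenance dict)``.  The
    provenance record logs the fixed stage order and every parameter used.
    With ``params.resample_before_pores = False`` the pore classification
    runs at native resolution and the downsampling (mask plus
    nearest-neighbour labels) happens last.
    """
    params = params or SegmentationParams()
    smoothed = smooth(vol, params.gaussian_sigma)
    mask = threshold(smoothed, params)
    mask = keep_largest_component(mask, params.material_connectivity)
    if params.resample_before_pores:
        if params.resample_factor > 1:
            mask = downsample(mask, params.resample_factor)
        material, pores = extract_closed_pores(mask, params)
    else:
        material, pores = extract_closed_pores(mask, params)
        if params.resample_factor > 1:
            material = downsample(material, params.resample_factor)
            pores = downsample_labels(pores, params.resample_factor)
    provenance = {
        "pipeline": ["smooth", "threshold", "keep_largest_component",
                     "downsample", "extract_closed_pores"]
        if params.resample_before_pores else
        ["smooth", "threshold", "keep_largest_component",
         "extract_closed_pores", "downsample"],
        "params": asdict(params),
        "input_shape": list(vol.shape),
        "input_spacing_mm": vol.spacing,
        "output_spacing_mm": material.spacing,
        "material_voxels": material.count(),
        "closed_pores": pores.label_count,
    }
    return material, pores, provenance
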