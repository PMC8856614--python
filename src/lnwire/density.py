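"""Glomerular neurite density from voxel masks and fluorescence volumes.

Per-glomerulus arbor density is quantified from a confocal stack and
manually segmented glomerulus masks in three steps:

1. Background: the mean per-voxel intensity of a reference glomerulus that
   the neuron never innervates (DM5 by convention) estimates the imaging
   background of the lobe.
2. Background-adjusted total of glomerulus x:
   (total signal)'_x = (total signal)_x - background_per_voxel * (voxel count)_x.
   Values below background come out negative and are deliberately not
   clamped.
3. Density: the adjusted total is divided by an internal normalizing
   constant — the summed adjusted totals of a consistently densely
   innervated trio (VA1d, VA1v, DA1 by convention) — and then by the
   glomerulus voxel count:
   (neurite density)_x = (total signal)'_x / sum_trio (total signal)'_i
   / (voxel count)_x.
   The normalization cancels per-lobe batch effects; densities are exactly
   invariant to global intensity rescaling and to adding a spatially
   uniform background.

Masks drawn on a sparse subset of z slices are completed by shape-based
(signed-distance) interpolation.
"""
from __future__ import annotations

import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import IntegrityError, SchemaError

#: Default reference glomerulus for per-voxel background estimation.
BACKGROUND_REFERENCE = "DM5"
#: Default internal-normalization trio (consistently densely innervated).
NORMALIZING_TRIO = ("VA1d", "VA1v", "DA1")


@dataclass
class LabeledVolume:
    """A 3-D intensity grid (z, y, x) plus per-glomerulus boolean masks.

    Masks must share the intensity shape and be pairwise disjoint — the
    density equations assume disjoint glomerular compartments.
    """

    intensity: np.ndarray
    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise SchemaError("intensity must be a 3-D (z, y, x) array")
        if (self.intensity < 0).any():
            raise ValueError("intensity values must be non-negative")
        clean = {}
        for name, mask in self.masks.items():
            mask = np.asarray(mask).astype(bool)
            if mask.shape != self.intensity.shape:
                raise SchemaError(
                    f"mask {name!r} shape {mask.shape} != intensity shape "
                    f"{self.intensity.shape}")
            clean[name] = mask
        overlap = np.zeros(self.intensity.shape, dtype=np.int8)
        for mask in clean.values():
            overlap += mask
        if (overlap > 1).any():
            raise IntegrityError("glomerulus masks overlap")
        self.masks = clean

    def require_mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise SchemaError(f"missing mask for glomerulus {name!r}")
        return self.masks[name]


@dataclass
class GlomerulusSignal:
    """Raw and derived fluorescence quantities for one glomerulus."""

    glomerulus: str
    total_signal: float
    voxel_count: int
    adjusted_total: float
    density: float


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside (Euclidean)."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_mask(annotated_slices: Mapping[int, np.ndarray],
                     z_extent: int) -> np.ndarray:
    """Complete a sparse per-slice annotation into a full 3-D mask.

    Slices between two annotated z-indices are filled by linear
    interpolation of signed distance fields (shape-based interpolation);
    annotated slices are reproduced bit-exact; slices outside the annotated
    z-range stay empty. A single annotated slice is returned as-is with a
    warning (nothing to interpolate between).
    """
    if not annotated_slices:
        raise ValueError("no annotated slices")
    zs = sorted(annotated_slices)
    if zs[0] < 0 or zs[-1] >= z_extent:
        raise ValueError("annotated z-index outside volume")
    planes = {z: np.asarray(annotated_slices[z]).astype(bool) for z in zs}
    shape = planes[zs[0]].shape
    for z, plane in planes.items():
        if plane.shape != shape:
            raise SchemaError("annotated slices differ in shape")
        if not plane.any():
            raise ValueError(f"annotated slice z={z} is empty")
    out = np.zeros((z_extent,) + shape, dtype=bool)
    if len(zs) == 1:
        warnings.warn("single annotated slice; returned without "
                      "interpolation", stacklevel=2)
        out[zs[0]] = planes[zs[0]]
        return out
    sdf = {z: _signed_distance(planes[z]) for z in zs}
    for z0, z1 in zip(zs, zs[1:]):
        out[z0] = planes[z0]
        for z in range(z0 + 1, z1):
            t = (z - z0) / (z1 - z0)
            out[z] = (1 - t) * sdf[z0] + t * sdf[z1] > 0
    out[zs[-1]] = planes[zs[-1]]
    return out


def background_per_voxel(volume: LabeledVolume,
                         reference: str = BACKGROUND_REFERENCE) -> float:
    """Mean per-voxel intensity of the background reference glomerulus."""
    mask = volume.require_mask(reference)
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"reference mask {reference!r} is empty")
    return float(volume.intensity[mask].sum()) / count


def adjusted_total(volume: LabeledVolume, glomerulus: str,
                   reference: str = BACKGROUND_REFERENCE) -> float:
    """Background-adjusted total signal of one glomerulus.

    total_x - background_per_voxel * voxel_count_x; may be negative for
    regions dimmer than the reference (not clamped).
    """
    mask = volume.require_mask(glomerulus)
    bg = background_per_voxel(volume, reference)
    return float(volume.intensity[mask].sum()) - bg * int(mask.sum())


def neurite_density(volume: LabeledVolume,
                    glomeruli: Sequence[str] | None = None,
                    normalizers: Sequence[str] = NORMALIZING_TRIO,
                    reference: str = BACKGROUND_REFERENCE
                    ) -> list[GlomerulusSignal]:
    """Normalized per-voxel neurite density for the requested glomeruli.

    The normalizing constant is the summed adjusted totals of
    ``normalizers``; a non-positive constant means the lobe is unusable
    (no signal above background in the trio) and raises ``ValueError``.
    """
    if glomeruli is None:
        glomeruli = sorted(volume.masks)
    for needed in (*normalizers, reference):
        volume.require_mask(needed)
    bg = background_per_voxel(volume, reference)

    def adj(name: str) -> tuple[float, int]:
        mask = volume.masks[name]
        count = int(mask.sum())
        if count == 0:
            raise ValueError(f"mask {name!r} is empty")
        return float(volume.intensity[mask].sum()) - bg * count, count

    norm_const = sum(adj(n)[0] for n in normalizers)
    if norm_const <= 0:
        raise ValueError(
            f"normalizing constant {norm_const:.3g} <= 0; lobe unusable")
    out = []
    for name in glomeruli:
        total = float(volume.intensity[volume.require_mask(name)].sum())
        adjusted, count = adj(name)
        out.append(GlomerulusSignal(
            glomerulus=name, total_signal=total, voxel_count=count,
            adjusted_total=adjusted,
            density=adjusted / norm_const / count))
    return out


def density_frame(signals: Sequence[GlomerulusSignal]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in signals])


def region_total_fluorescence(image: np.ndarray,
                              region: np.ndarray) -> float:
    """Total fluorescence of a 2-D region: mean intensity x pixel count
    (algebraically the sum of intensities within the region)."""
    image = np.asarray(image, dtype=float)
    region = np.asarray(region).astype(bool)
    if image.shape != region.shape:
        raise SchemaError("image and region shapes differ")
    count = int(region.sum())
    if count == 0:
        raise ValueError("empty region")
    return float(image[region].mean()) * count


def read_labeled_volume(intensity_path: str | Path,
                        labels_path: str | Path,
                        label_map_path: str | Path) -> LabeledVolume:
    """Load a multi-page TIFF intensity stack plus an integer label volume.

    The JSON sidecar maps label values (as strings) to glomerulus names,
    e.g. ``{"1": "DA1", "2": "VA1d"}``. Label 0 is background.
    """
    intensity = tifffile.imread(str(intensity_path))
    labels = tifffile.imread(str(labels_path))
    if labels.shape != intensity.shape:
        raise SchemaError("label volume shape != intensity shape")
    with open(label_map_path) as fh:
        label_map = {int(k): v for k, v in json.load(fh).items()}
    masks = {name: labels == value for value, name in label_map.items()}
    return LabeledVolume(intensity=intensity, masks=masks)


def write_labeled_volume(volume: LabeledVolume, intensity_path: str | Path,
                         labels_path: str | Path,
                         label_map_path: str | Path) -> None:
    """Write a volume in the format :func:`read_labeled_volume` accepts."""
    tifffile.imwrite(str(intensity_path),
                     volume.intensity.astype(np.float32))
    labels = np.zeros(volume.intensity.shape, dtype=np.uint16)
    label_map = {}
    for value, name in enumerate(sorted(volume.masks), start=1):
        labels[volume.masks[name]] = value
        label_map[str(value)] = name
    tifffile.imwrite(str(labels_path), labels)
    with open(label_map_path, "w") as fh:
        json.dump(label_map, fh, indent=1)
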