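"""Gray-level lesion segmentation and necrosis detection on 3D volumes.

The segmentation mirrors the semi-automatic clinical workflow for
contrast-enhanced T1-weighted MRI of brain metastases: the enhancing (CE)
tumor is selected by a gray-level threshold, and necrosis is identified as
the central non-enhancing regions fully surrounded by ring enhancement —
a topological enclosure statement, implemented as 3D binary hole filling.

Label coding in :class:`LesionMask`: 0 = background, 1 = CE tumor,
2 = enclosed necrosis.  Total tumor = CE + necrosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .phantoms import LABEL_BACKGROUND, LABEL_CE, LABEL_NECROSIS

__all__ = [
    "ImageVolume",
    "LesionMask",
    "EmptyLesionError",
    "segment_ce",
    "detect_necrosis",
    "otsu_threshold",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


class EmptyLesionError(ValueError):
    """Raised when a segmentation step yields no contrast-enhancing voxels."""


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with per-axis voxel spacing.

    Axis order is fixed as (x, y, z); ``spacing`` is in mm and ``origin``
    gives the world coordinates (mm) of the voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"image must be 3D, got {self.intensities.ndim}D")
        if self.intensities.size == 0:
            raise ValueError("image grid is empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class LesionMask:
    """Labeled lesion grid: 0 background, 1 CE tumor, 2 enclosed necrosis."""

    labels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    provenance: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.labels.ndim}D")
        valid = {LABEL_BACKGROUND, LABEL_CE, LABEL_NECROSIS}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"mask contains labels outside {sorted(valid)}: {sorted(present)}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


def otsu_threshold(image: ImageVolume) -> float:
    """Otsu's threshold on the intensity histogram.

    Provided as a convenience starting point only — the segmentation
    threshold is always an explicit, logged parameter and is never chosen
    silently.
    """
    return float(threshold_otsu(image.intensities))


def segment_ce(image: ImageVolume, threshold: float, component_policy: str = "largest") -> LesionMask:
    """Threshold the enhancing tumor out of a CE-T1w-like volume.

    Voxels with intensity >= ``threshold`` are labeled CE; 26-connected
    components are then kept according to ``component_policy`` ("largest"
    keeps only the largest component, "all" keeps every component).
    Necrosis is not assigned at this stage — see :func:`detect_necrosis`.
    """
    lo = float(np.min(image.intensities))
    if threshold < lo:
        raise ValueError(f"threshold {threshold} below the intensity range (min {lo})")
    if component_policy not in ("largest", "all"):
        raise ValueError("component_policy must be 'largest' or 'all'")
    binary = image.intensities >= threshold
    if not binary.any():
        raise EmptyLesionError("no voxel at or above the threshold")
    comps, n_comp = cc_label(binary, connectivity=3, return_num=True)
    if component_policy == "largest" and n_comp > 1:
        sizes = np.bincount(comps.ravel())[1:]
        binary = comps == (int(np.argmax(sizes)) + 1)
    if _touches_boundary(binary):
        warnings.warn(
            "CE segmentation reaches the image boundary; features may be truncated",
            stacklevel=2,
        )
    labels = np.where(binary, LABEL_CE, LABEL_BACKGROUND).astype(np.uint8)
    return LesionMask(
        labels=labels,
        spacing=image.spacing,
        origin=image.origin,
        provenance=f"segment_ce(threshold={threshold}, component_policy={component_policy})",
    )


def _touches_boundary(binary: np.ndarray) -> bool:
    return bool(
        binary[0].any() or binary[-1].any()
        or binary[:, 0].any() or binary[:, -1].any()
        or binary[:, :, 0].any() or binary[:, :, -1].any()
    )


def detect_necrosis(mask: LesionMask) -> LesionMask:
    """Label enclosed non-enhancing regions as necrosis.

    Necrosis is defined as the 3D hole fill of the CE label minus the CE
    label: non-CE regions that cannot 6-reach the grid boundary through
    non-CE voxels.  The background complement uses 6-connectivity so a
    single-voxel perforation of the rim disqualifies the core (it is then
    connected to the outside, hence not enclosed).  Idempotent: existing
    necrosis labels are recomputed from the CE label alone.
    """
    ce = mask.labels == LABEL_CE
    if not ce.any():
        raise EmptyLesionError("mask has no CE voxels")
    filled = ndimage.binary_fill_holes(ce)  # default structure = 6-connectivity in 3D
    necrosis = filled & ~ce
    labels = np.where(ce, LABEL_CE, LABEL_BACKGROUND).astype(np.uint8)
    labels[necrosis] = LABEL_NECROSIS
    return LesionMask(
        labels=labels,
        spacing=mask.spacing,
        origin=mask.origin,
        provenance=(mask.provenance + "; " if mask.provenance else "")
        + "detect_necrosis(fill=6-connected)",
    )


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_image(image: ImageVolume, path) -> None:
    """Write an intensity volume as NIfTI; spacing goes into the affine."""
    nib.save(nib.Nifti1Image(image.intensities.astype(np.float32), _affine(image.spacing, image.origin)), str(path))


def read_image(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header lacks positive voxel spacing")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(intensities=data.astype(float), spacing=tuple(float(z) for z in zooms), origin=origin)


def write_mask(mask: LesionMask, path) -> None:
    """Write a label volume as NIfTI (uint8, 0/1/2 coding)."""
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header["descrip"] = mask.provenance[:79].encode()
    nib.save(img, str(path))


def read_mask(path) -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header lacks positive voxel spacing")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    return LesionMask(
        labels=np.rint(data).astype(np.uint8),
        spacing=tuple(float(z) for z in zooms),
        origin=origin,
        provenance=descrip,
    )
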