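"""OCT volume morphometry: wall / antrum / COC segmentation, relative
antrum volume, midplane extraction, and local wall-thickness mapping.

In reconstructed OCT intensity volumes cellular material is bright and
fluid is dark; the follicle wall therefore appears as a bright shell
around a dark antral cavity, with the cumulus-oocyte complex (COC) as
an intermediate-intensity body floating in the fluid. Thickness is
quantified with the largest-inscribed-disk ("local thickness")
definition: the thickness at a point is the diameter of the largest
disk that fits entirely inside the wall and contains that point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .synthetic import Phantom

__all__ = [
    "SegmentationMasks",
    "ThicknessDistribution",
    "MidplaneGeometry",
    "SegmentationError",
    "GeometryError",
    "segment_volume",
    "relative_antrum_volume",
    "extract_midplane",
    "local_thickness_map",
    "thickness_distribution",
]


class SegmentationError(ValueError):
    """No enclosed cavity (or no wall) could be segmented."""


class GeometryError(ValueError):
    """The midplane slice lacks a closed annulus."""


@dataclass
class SegmentationMasks:
    """Disjoint wall / antrum / COC voxel label sets."""

    wall: np.ndarray
    antrum: np.ndarray
    coc: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if (self.wall & self.antrum).any() or (self.wall & self.coc).any() \
                or (self.antrum & self.coc).any():
            raise ValueError("wall/antrum/coc masks must be pairwise disjoint")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass(frozen=True)
class ThicknessDistribution:
    """Pixel-count-weighted wall-thickness histogram (mass sums to 1)."""

    bin_edges: np.ndarray  # um
    weights: np.ndarray  # area fraction per bin
    weighted_mean: float  # um, computed from raw pixel values
    n_pixels: int


@dataclass(frozen=True)
class MidplaneGeometry:
    """Equatorial cross-section of the segmented follicle."""

    radius_um: float  # equivalent-area radius of the outer wall boundary
    cross_section_mask: np.ndarray  # 0 bg, 1 wall, 2 antrum, 3 coc
    pixel_size: float
    z_index: int


def segment_volume(volume: np.ndarray | Phantom, voxel_size: float | None = None,
                   thresholds: tuple[float, float] | None = None,
                   smooth_sigma: float = 1.0) -> SegmentationMasks:
    """Segment an OCT intensity volume into wall, antrum and COC.

    Parameters
    ----------
    volume : ndarray or Phantom
        3D intensity grid (bright = cellular, dark = fluid).
    voxel_size : float
        um per voxel (taken from the phantom when one is passed).
    thresholds : (t_fluid, t_coc), optional
        Fluid/COC and COC/wall intensity cuts; by default both come
        from a three-class Otsu split of the (optionally smoothed)
        volume.
    smooth_sigma : float
        Gaussian pre-smoothing in voxels applied before thresholding to
        suppress speckle; 0 disables it. Masks are derived from the
        smoothed volume.

    Notes
    -----
    The wall is the largest connected bright component; the antrum is
    the dark region it encloses; COC voxels are the intermediate class
    inside the cavity, excluding a one-voxel margin along the wall so
    mural cells are not mistaken for the COC.
    """
    if isinstance(volume, Phantom):
        voxel_size = volume.pixel_size if voxel_size is None else voxel_size
        volume = volume.payload
    if voxel_size is None:
        raise ValueError("voxel_size is required for raw volumes")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma)
    if thresholds is None:
        t1, t2 = filters.threshold_multiotsu(vol, classes=3)
        # refine the cuts to midpoints between class means so that each
        # boundary lands at the half-level of its intensity transition
        # (an Otsu cut sitting off-centre would bias the wall width)
        m0 = float(vol[vol < t1].mean())
        m1 = float(vol[(vol >= t1) & (vol < t2)].mean())
        m2 = float(vol[vol >= t2].mean())
        t_fluid = 0.5 * (m0 + m1)
        t_coc = 0.5 * (m1 + m2)
        wall_cut = 0.5 * (m0 + m2)  # fluid -> wall transition half-level
    else:
        t_fluid, t_coc = thresholds
        if not t_fluid < t_coc:
            raise ValueError("thresholds must satisfy t_fluid < t_coc")
        wall_cut = t_coc

    bright = vol >= wall_cut
    labels = measure.label(bright)
    if labels.max() == 0:
        raise SegmentationError("no bright wall voxels found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    wall = labels == counts.argmax()
    interior = ndimage.binary_fill_holes(wall) & ~wall
    if not interior.any():
        raise SegmentationError("wall encloses no cavity")

    # COC: the largest intermediate-intensity component inside the
    # cavity that does not touch the wall (components hugging the wall
    # are partial-volume rim voxels or mural cells, not the COC)
    intermediate = (vol >= t_fluid) & (vol < wall_cut) & interior
    near_wall = ndimage.binary_dilation(wall, iterations=2)
    coc = np.zeros_like(wall)
    if intermediate.any():
        clabels, _ = ndimage.label(intermediate)
        ccounts = np.bincount(clabels.ravel())
        ccounts[0] = 0
        for lab in np.unique(clabels[near_wall & (clabels > 0)]):
            ccounts[lab] = 0
        if ccounts.max() > 0:
            coc = clabels == ccounts.argmax()
    # fluid assignment uses the fluid->wall half-level so the antrum
    # boundary is unbiased; bright speckle blobs in the cavity (>= the
    # wall cut but disconnected from the wall) belong to neither class
    antrum = interior & (vol < wall_cut) & ~coc
    return SegmentationMasks(wall=wall, antrum=antrum, coc=coc,
                             voxel_size=float(voxel_size))


def relative_antrum_volume(masks: SegmentationMasks) -> float:
    """Antrum volume normalized to follicle-wall volume (dimensionless).

    COC voxels count toward neither compartment.
    """
    wall_n = int(masks.wall.sum())
    if wall_n == 0:
        raise ZeroDivisionError("empty wall mask")
    return float(masks.antrum.sum()) / wall_n


def extract_midplane(masks: SegmentationMasks, z_index: int | None = None
                     ) -> MidplaneGeometry:
    """Equatorial cross-section through the wall centroid.

    The slice is taken along the first (axial) dimension at the wall
    centroid (or a fixed ``z_index``); the outer wall boundary must
    close into an annulus there. The reported radius is the
    equivalent-area radius of the region enclosed by the outer
    boundary, ``sqrt(area/pi)``.
    """
    if z_index is None:
        z_index = int(round(ndimage.center_of_mass(masks.wall)[0]))
    wall2d = masks.wall[z_index]
    if not wall2d.any():
        raise GeometryError(f"no wall pixels in slice z={z_index}")
    enclosed = ndimage.binary_fill_holes(wall2d)
    cavity2d = enclosed & ~wall2d
    if not cavity2d.any():
        raise GeometryError("midplane slice lacks a closed annulus")
    cross = np.zeros(wall2d.shape, dtype=np.uint8)
    cross[wall2d] = 1
    coc2d = masks.coc[z_index]
    cross[cavity2d & masks.antrum[z_index] & ~coc2d] = 2
    cross[coc2d] = 3
    radius = float(np.sqrt(enclosed.sum() / np.pi) * masks.voxel_size)
    return MidplaneGeometry(radius_um=radius, cross_section_mask=cross,
                            pixel_size=masks.voxel_size, z_index=z_index)


def local_thickness_map(mask_2d: np.ndarray, pixel_size: float = 1.0
                        ) -> np.ndarray:
    """Local thickness of a binary 2D mask (largest inscribed disk).

    The thickness at pixel ``p`` is the diameter of the largest disk
    fully contained in the mask that covers ``p`` — the
    Hildebrand-Ruegsegger definition used for trabecular and wall
    morphometry. Computed by the distance-transform + disk-propagation
    construction: every mask pixel ``c`` carries an inscribed disk of
    radius ``EDT(c)``, and each pixel takes the largest diameter among
    disks covering it. The distance transform measures to the nearest
    background pixel *centre*, half a pixel beyond the true boundary on
    each side, so the reported diameter is ``2*EDT - 1`` pixels. Output
    in um (zeros off the mask).
    """
    mask = np.asarray(mask_2d).astype(bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2D mask")
    if not mask.any():
        raise ValueError("empty mask")
    edt = ndimage.distance_transform_edt(mask)
    thickness = np.zeros_like(edt)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    radii = edt[ys, xs]
    order = np.argsort(-radii)
    for idx in order:
        cy, cx, r = ys[idx], xs[idx], radii[idx]
        ri = int(np.floor(r))
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, h)
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, w)
        sub = thickness[y0:y1, x0:x1]
        if sub.size and sub.min() >= 2.0 * r:
            continue  # every pixel in reach is already at least this thick
        dy = np.arange(y0, y1) - cy
        dx = np.arange(x0, x1) - cx
        within = (dy[:, None] ** 2 + dx[None, :] ** 2) <= r * r
        np.maximum(sub, np.where(within, 2.0 * r, 0.0), out=sub)
    thickness[~mask] = 0.0
    thickness[mask] -= 1.0  # half-pixel boundary offset on each side
    return thickness * pixel_size


def thickness_distribution(thickness: np.ndarray, bin_width: float = 5.0
                           ) -> ThicknessDistribution:
    """Pixel-count-weighted histogram of a local-thickness map.

    Only on-mask pixels (thickness > 0) contribute; weights are area
    fractions summing to 1, and the weighted mean is computed from the
    raw pixel values (so it is independent of the binning).
    """
    vals = np.asarray(thickness, dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("thickness map has no on-mask pixels")
    mean = float(vals.mean())
    top = float(vals.max())
    n_bins = max(int(np.ceil(top / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] <= top:  # include the max value in the last bin
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    weights = counts / counts.sum()
    return ThicknessDistribution(bin_edges=edges, weights=weights,
                                 weighted_mean=mean, n_pixels=int(vals.size))
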