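"""The 33 knowledge-based morphometric features.

Per image, three handcrafted sets are computed over the segmented nuclei
and averaged across the L instances:

* geometric (f1-f5): nucleus count L, mean area A, mean perimeter P, the
  ratio AP = A/P and roundness R = 4*pi*A/P^2;
* directional (f6-f30): the Euclidean distance from each nucleus centroid
  to its boundary along the 8 compass directions, summarised per direction
  by mean (f6-f13), population standard deviation (f14-f21, divisor L) and
  range (f22-f29), plus the mean ratio of nucleus area to its axis-aligned
  bounding-box area (f30);
* intensity (f31-f33): mean of per-nucleus mean intensity, of per-nucleus
  population standard deviation (divisor x_k) and of per-nucleus intensity
  range.

Irregular (malignant-like) nuclei show larger spread in the directional
distances across a field and lower roundness; heterogeneous chromatin shows
up in f32/f33.

Conventions: (row, col) indexing, 0-based; North is decreasing row, East is
increasing column. Perimeter is the count of border pixels (nucleus pixels
with at least one 4-neighbour outside the nucleus or on the image edge), a
literal pixel-count reading, so digital roundness of a disk is not capped
at 1. Area uses pixel counts. Intensity defaults to luminance
(0.299 R + 0.587 G + 0.114 B) on the 0-255 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DIRECTIONS",
    "FEATURE_NAMES",
    "NucleusRegion",
    "to_grayscale",
    "extract_regions",
    "geometric_features",
    "directional_distances",
    "directional_features",
    "intensity_features",
    "extract_features",
]

# Compass order fixed across all directional features.
DIRECTIONS = ("N", "S", "E", "W", "NW", "NE", "SW", "SE")
_STEPS = {
    "N": (-1, 0),
    "S": (1, 0),
    "E": (0, 1),
    "W": (0, -1),
    "NW": (-1, -1),
    "NE": (-1, 1),
    "SW": (1, -1),
    "SE": (1, 1),
}

FEATURE_NAMES = tuple(
    ["f1", "f2", "f3", "f4", "f5"]
    + [f"f{6 + i}" for i in range(8)]   # mean distance per direction
    + [f"f{14 + i}" for i in range(8)]  # std per direction
    + [f"f{22 + i}" for i in range(8)]  # range per direction
    + ["f30", "f31", "f32", "f33"]
)


@dataclass
class NucleusRegion:
    """One segmented nucleus with its per-nucleus quantities."""

    label: int
    pixels: np.ndarray          # (x_k, 2) int array of (row, col)
    x_k: int                    # pixel count (area A_k)
    border_pixels: np.ndarray   # (P_k, 2) int array
    P_k: int                    # border pixel count
    centroid: tuple[float, float]
    intensities: np.ndarray     # J_ki on the 0-255 scale
    I_k: float                  # mean intensity
    sigma_Ik: float             # population std of intensities
    RI_k: float                 # max - min intensity
    d_Dk: np.ndarray            # 8 centroid-to-boundary distances, DIRECTIONS order
    AR_k: int                   # axis-aligned bounding-box area

    @property
    def A_k(self) -> int:
        return self.x_k


def to_grayscale(image: np.ndarray, channel: str = "luminance") -> np.ndarray:
    """Scalar intensity image on the 0-255 scale from an RGB (or 2-D) input."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected RGB or 2-D grayscale image")
    rgb = image.astype(float)
    if channel == "luminance":
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    if channel in ("red", "green", "blue"):
        return rgb[..., ("red", "green", "blue").index(channel)]
    if channel == "hematoxylin":
        from .segmentation import hematoxylin_channel

        h = hematoxylin_channel(image)
        return 255.0 * h / max(h.max(), 1e-12)
    raise ValueError(f"unknown intensity channel {channel!r}")


def directional_distances(
    mask_or_region, centroid: tuple[float, float] | None = None
) -> np.ndarray:
    """Centroid-to-boundary distance along the 8 compass directions.

    Walks in unit steps from the rounded centroid pixel while the visited
    pixel stays inside the region; the distance is the Euclidean norm from
    the rounded centroid to the last in-region pixel. Directions whose first
    step already leaves the region (possible when the centroid of a concave
    shape falls outside it) yield 0 and are logged.
    """
    if isinstance(mask_or_region, NucleusRegion):
        region = mask_or_region
        mask = np.zeros(
            (region.pixels[:, 0].max() + 1, region.pixels[:, 1].max() + 1), dtype=bool
        )
        mask[region.pixels[:, 0], region.pixels[:, 1]] = True
        centroid = region.centroid
    else:
        mask = np.asarray(mask_or_region, dtype=bool)
        if centroid is None:
            rr, cc = np.nonzero(mask)
            centroid = (float(rr.mean()), float(cc.mean()))
    rows, cols = mask.shape
    m = int(round(centroid[0]))
    n = int(round(centroid[1]))

    dists = np.zeros(len(DIRECTIONS))
    if not (0 <= m < rows and 0 <= n < cols) or not mask[m, n]:
        logger.warning("centroid pixel (%d, %d) outside region; distances set to 0", m, n)
        return dists
    for i, D in enumerate(DIRECTIONS):
        sr, sc = _STEPS[D]
        r, c = m, n
        while 0 <= r + sr < rows and 0 <= c + sc < cols and mask[r + sr, c + sc]:
            r, c = r + sr, c + sc
        dists[i] = np.hypot(r - m, c - n)
    return dists


def extract_regions(label_map: np.ndarray, gray: np.ndarray) -> list[NucleusRegion]:
    """Build one :class:`NucleusRegion` per nonzero label.

    Border pixels are nucleus pixels with >= 1 of their 4-neighbours outside
    the nucleus (image-edge pixels count as border).
    """
    label_map = np.asarray(label_map)
    gray = np.asarray(gray, dtype=float)
    if label_map.shape != gray.shape:
        raise ValueError("label_map and intensity image shapes differ")

    regions: list[NucleusRegion] = []
    for lab in np.unique(label_map):
        if lab == 0:
            continue
        mask = label_map == lab
        rr, cc = np.nonzero(mask)
        x_k = rr.size
        padded = np.pad(mask, 1)
        interior = (
            padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
        )
        border = mask & ~interior
        br, bc = np.nonzero(border)
        centroid = (float(rr.mean()), float(cc.mean()))
        J = gray[rr, cc]
        J_range = float(J.max() - J.min())
        # a constant region has exactly zero spread; np.std would leave
        # ~1e-15 residue from the inexact mean
        sigma = float(J.std()) if J_range > 0 else 0.0
        regions.append(
            NucleusRegion(
                label=int(lab),
                pixels=np.column_stack([rr, cc]),
                x_k=int(x_k),
                border_pixels=np.column_stack([br, bc]),
                P_k=int(br.size),
                centroid=centroid,
                intensities=J,
                I_k=float(J.mean()),
                sigma_Ik=sigma,  # population divisor x_k
                RI_k=J_range,
                d_Dk=directional_distances(mask, centroid),
                AR_k=int((rr.max() - rr.min() + 1) * (cc.max() - cc.min() + 1)),
            )
        )
    return regions


def _empty_warning(what: str) -> None:
    logger.warning("no nuclei in image; %s set to zeros", what)


def geometric_features(regions: list[NucleusRegion]) -> np.ndarray:
    """f1..f5: L, mean area A, mean perimeter P, AP = A/P, R = 4*pi*A/P^2."""
    if not regions:
        _empty_warning("geometric features")
        return np.zeros(5)
    L = len(regions)
    A = float(np.mean([r.x_k for r in regions]))
    P = float(np.mean([r.P_k for r in regions]))
    AP = A / P if P > 0 else 0.0
    R = 4.0 * A * np.pi / P**2 if P > 0 else 0.0
    return np.array([L, A, P, AP, R])


def directional_features(regions: list[NucleusRegion]) -> np.ndarray:
    """f6..f30: per-direction mean, population std and range of d_Dk over
    the L nuclei, then the mean bounding-box fill ratio A_k/AR_k."""
    if not regions:
        _empty_warning("directional features")
        return np.zeros(25)
    d = np.stack([r.d_Dk for r in regions])  # (L, 8)
    means = d.mean(axis=0)
    stds = d.std(axis=0)  # population divisor L
    ranges = d.max(axis=0) - d.min(axis=0)
    ar_ratio = float(np.mean([r.x_k / r.AR_k for r in regions]))
    return np.concatenate([means, stds, ranges, [ar_ratio]])


def intensity_features(regions: list[NucleusRegion]) -> np.ndarray:
    """f31..f33: means over nuclei of I_k, sigma_Ik and RI_k."""
    if not regions:
        _empty_warning("intensity features")
        return np.zeros(3)
    return np.array(
        [
            float(np.mean([r.I_k for r in regions])),
            float(np.mean([r.sigma_Ik for r in regions])),
            float(np.mean([r.RI_k for r in regions])),
        ]
    )


def extract_features(
    image: np.ndarray,
    label_map: np.ndarray,
    intensity_channel: str = "luminance",
) -> np.ndarray:
    """Full 33-feature vector f1..f33 for one image and its label map.

    An image with L = 0 nuclei yields an all-zero vector (with a logged
    warning) so batch runs never abort.
    """
    gray = to_grayscale(image, intensity_channel)
    regions = extract_regions(np.asarray(label_map), gray)
    vec = np.concatenate(
        [
            geometric_features(regions),
            directional_features(regions),
            intensity_features(regions),
        ]
    )
    assert vec.shape == (33,)
    return vec
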