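"""Pore/ligament morphometry and cell-shape descriptors for binary images.

Desk-scale analogue of SEM image characterization of nanoporous gold:
feature sizes are measured as local widths (largest inscribed-disk
diameters at the regional maxima of the Euclidean distance transform,
the same idea as ImageJ local thickness), pore and ligament sizes are
related by ordinary least squares, and adhered-cell shape is summarised
by the circularity 4*pi*A/L^2 (1 for a circle, < 1 otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "BinaryImage",
    "MorphometryResult",
    "CellMask",
    "granulometry_size",
    "circularity",
    "pixel_mask_circularity",
    "fit_pore_ligament",
    "make_synthetic_pores",
    "PORE_LIGAMENT_MEANS",
]

#: Measured mean pore and ligament sizes (nm) of the five fabricated
#: substrates nominally labelled 10, 20, 30, 50 and 180 nm; packaged as the
#: reference fixture for the pore-ligament regression.
PORE_LIGAMENT_MEANS: dict[str, tuple[float, ...]] = {
    "nominal_nm": (10, 20, 30, 50, 180),
    "pore_nm": (7.649, 23.060, 29.175, 54.411, 186.641),
    "ligament_nm": (19.472, 25.905, 45.667, 71.251, 210.937),
}


class MorphometryError(ValueError):
    """Image or data unsuitable for the requested measurement."""


@dataclass(frozen=True)
class BinaryImage:
    """A binary phase image with physical pixel size.

    ``pixels`` is boolean (True = foreground phase to be sized);
    ``phase_label`` names what the foreground is (pore, ligament or cell).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    phase_label: str = "pore"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise MorphometryError(f"pixels must be 2-D, got shape {px.shape}")
        if self.pixel_size <= 0:
            raise MorphometryError(f"pixel_size must be positive, got {self.pixel_size}")

    def inverted(self) -> "BinaryImage":
        swap = {"pore": "ligament", "ligament": "pore"}
        return BinaryImage(
            ~self.pixels, self.pixel_size, swap.get(self.phase_label, self.phase_label)
        )


@dataclass(frozen=True)
class MorphometryResult:
    """Per-feature sizes in nm with their mean and standard error."""

    mean_size: float
    sem: float
    n: int
    sizes: tuple[float, ...]


@dataclass(frozen=True)
class CellMask:
    """Exact area A (length^2) and perimeter L (length) of one cell outline."""

    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise MorphometryError(
                f"area and perimeter must be positive, got A={self.area}, L={self.perimeter}"
            )


def granulometry_size(img: BinaryImage, wrap: bool = False) -> MorphometryResult:
    """Local-width sizes of the foreground phase, in nm.

    Each feature is a regional maximum of the Euclidean distance transform
    of the foreground; its size is twice the distance there (the diameter of
    the largest inscribed disk).  This measures local widths even when the
    phase is one connected bicontinuous network, where connected-component
    sizing would collapse to a single number.  ``wrap`` treats the image as
    periodic (appropriate for simulated substrate fields).

    Raises :class:`MorphometryError` if either phase is absent.
    """
    px = img.pixels
    if px.all() or not px.any():
        raise MorphometryError(
            f"both phases must be present to size the {img.phase_label} phase"
        )
    if wrap:
        # pad periodically so distances and maxima see the wrapped structure
        n, m = px.shape
        tiled = np.tile(px, (3, 3))
        edt = ndimage.distance_transform_edt(tiled)[n : 2 * n, m : 2 * m]
    else:
        edt = ndimage.distance_transform_edt(px)
    from skimage.morphology import local_maxima

    peaks = local_maxima(edt, connectivity=2) & px
    labels, n_feat = ndimage.label(peaks, structure=np.ones((3, 3)))
    if n_feat == 0:
        raise MorphometryError("no distance-transform maxima found")
    radii = ndimage.maximum(edt, labels, index=np.arange(1, n_feat + 1))
    sizes = 2.0 * np.asarray(radii, dtype=float) * img.pixel_size
    mean = float(sizes.mean())
    sem = float(sizes.std(ddof=1) / math.sqrt(len(sizes))) if len(sizes) > 1 else 0.0
    return MorphometryResult(mean, sem, len(sizes), tuple(sizes.tolist()))


def circularity(mask: CellMask) -> float:
    """Shape circularity 4*pi*A/L^2 from exact area and perimeter."""
    return 4.0 * math.pi * mask.area / mask.perimeter**2


def pixel_mask_circularity(img: BinaryImage) -> float:
    """Approximate circularity of a pixel mask (foreground = cell).

    Pixel-counted perimeters are biased (a digitised circle's crofton or
    marching perimeter differs from 2*pi*r by a few percent); use
    :func:`circularity` with exact A and L where a closed form exists.
    """
    from skimage.measure import label, regionprops

    lab = label(img.pixels)
    props = regionprops(lab)
    if not props:
        raise MorphometryError("mask contains no foreground")
    biggest = max(props, key=lambda p: p.area)
    if biggest.perimeter <= 0:
        raise MorphometryError("degenerate mask perimeter")
    return 4.0 * math.pi * biggest.area / biggest.perimeter**2


def fit_pore_ligament(
    pore_sizes_nm: "np.typing.ArrayLike", ligament_sizes_nm: "np.typing.ArrayLike"
) -> dict[str, float]:
    """Ordinary least-squares fit of ligament size on pore size.

    Returns slope, intercept, r_squared and the two-sided p-value of the
    slope.  Requires n >= 3 paired observations with non-degenerate x.
    """
    x = np.asarray(pore_sizes_nm, dtype=float)
    y = np.asarray(ligament_sizes_nm, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MorphometryError("pore and ligament size lists must be equal-length 1-D")
    if len(x) < 3:
        raise MorphometryError(f"need at least 3 points for a fit, got {len(x)}")
    if np.ptp(x) == 0:
        raise MorphometryError("pore sizes have zero variance; fit undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }


def make_synthetic_pores(
    pattern: str,
    feature_nm: float,
    pixel_size: float,
    seed: int = 0,
    size_px: int = 256,
) -> BinaryImage:
    """Deterministic binary test patterns with known feature size.

    ``discs``: a square array of discs of diameter ``feature_nm`` (foreground
    = discs); ``stripes``: straight stripes of width ``feature_nm``;
    ``voronoi``: a random two-phase tessellation with cells of roughly that
    scale (no closed-form size).  Features must span at least two pixels.
    """
    if feature_nm < 2 * pixel_size:
        raise MorphometryError(
            f"feature_nm={feature_nm} below resolution limit 2*pixel_size={2*pixel_size}"
        )
    f_px = feature_nm / pixel_size
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    if pattern == "discs":
        pitch = max(int(round(2 * f_px)), 2)
        r = f_px / 2.0
        cy = (yy % pitch) - pitch // 2
        cx = (xx % pitch) - pitch // 2
        mask = cy * cy + cx * cx <= r * r
    elif pattern == "stripes":
        period = max(int(round(2 * f_px)), 2)
        mask = (xx % period) < f_px
    elif pattern == "voronoi":
        rng = np.random.default_rng(seed)
        n_seeds = max(4, int((size_px / f_px) ** 2))
        pts = rng.random((n_seeds, 2)) * size_px
        phase = rng.integers(0, 2, n_seeds).astype(bool)
        d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
        mask = phase[np.argmin(d2, axis=-1)]
    else:
        raise MorphometryError(f"unknown pattern {pattern!r}")
    return BinaryImage(mask, pixel_size=pixel_size, phase_label="pore")
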