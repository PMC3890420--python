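"""Stain quantification in RGB tissue images by color deconvolution.

Stains absorb light, so absorbances add: converting an 8-bit RGB image to
optical density (OD = -log10 of relative transmitted intensity) turns each
pixel into a nonnegative linear combination of per-stain OD vectors.
Inverting that 3x3 system (color deconvolution) separates a specific
immunostain (e.g. DAB) from the nonspecific hematoxylin counterstain, and the
mean deconvolved density over tissue pixels quantifies stain abundance per
image.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "StainMatrix",
    "StainQuant",
    "default_stain_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "color_deconvolve",
    "tissue_mask",
    "mean_stain_intensity",
    "read_image",
    "write_density_map",
]

#: offset avoiding log(0) at intensity 0; OD = -log10((I + 1) / 256) so a
#: saturated (255) channel maps to exactly 0 OD.
_OD_OFFSET = 1.0
_OD_SCALE = 256.0

#: fixed-point scale for density maps stored as 16-bit grayscale images
DENSITY_MAP_SCALE = 10000.0


@dataclass(frozen=True)
class StainMatrix:
    """3x3 matrix of unit-norm stain OD vectors (rows: stain1, stain2, residual)."""

    matrix: np.ndarray
    names: tuple[str, str, str] = ("stain1", "stain2", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if (norms == 0).any():
            raise ValueError("zero stain vector")
        m = m / norms[:, None]
        if np.linalg.cond(m) > 1e8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_two_stains(
        cls, s1, s2, names: tuple[str, str] = ("stain1", "stain2")
    ) -> "StainMatrix":
        """Build a full matrix from two stain vectors; the residual channel is
        their normalized cross product."""
        s1 = np.asarray(s1, dtype=float)
        s2 = np.asarray(s2, dtype=float)
        residual = np.cross(s1 / np.linalg.norm(s1), s2 / np.linalg.norm(s2))
        nr = np.linalg.norm(residual)
        if nr == 0:
            raise ValueError("stain vectors are collinear")
        return cls(
            matrix=np.vstack([s1, s2, residual / nr]),
            names=(names[0], names[1], "residual"),
        )


@dataclass
class StainQuant:
    """Mean density of the target stain over the evaluated pixels."""

    mean_density: float
    n_pixels: int
    mask_description: str


def default_stain_matrix() -> StainMatrix:
    """Packaged DAB + hematoxylin stain matrix (DAB first: the target stain)."""
    text = resources.files("immunopolar").joinpath("data", "stain_vectors.yaml").read_text()
    vecs = yaml.safe_load(text)
    return StainMatrix.from_two_stains(
        vecs["dab"], vecs["hematoxylin"], names=("dab", "hematoxylin")
    )


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density per channel.

    OD = -log10((I + 1) / 256), which is >= 0 with OD = 0 exactly at full
    intensity and ~1 per decade of attenuation.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.floating) or img.max() > 255 or img.min() < 0:
            raise ValueError("expected 8-bit channels")
    return -np.log10((img.astype(float) + _OD_OFFSET) / _OD_SCALE)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (rounded to 8-bit)."""
    intensity = _OD_SCALE * np.power(10.0, -np.asarray(od, dtype=float)) - _OD_OFFSET
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def color_deconvolve(
    od: np.ndarray, stains: StainMatrix
) -> tuple[np.ndarray, float]:
    """Solve OD = densities @ stain_matrix per pixel.

    Returns the per-stain density maps (H x W x 3, ordered as the stain
    matrix rows) and the fraction of density values clipped at 0 (negative
    solutions arise from noise and unmodeled absorbers).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError("expected an OD image (H x W x 3)")
    inv = np.linalg.inv(stains.matrix)
    dens = od @ inv
    n_neg = int(np.count_nonzero(dens < 0))
    frac_clipped = n_neg / dens.size
    return np.clip(dens, 0.0, None), frac_clipped


def tissue_mask(od: np.ndarray, threshold: float = 0.15) -> np.ndarray:
    """Pixels with total OD above ``threshold`` (excludes background glass)."""
    return np.asarray(od, dtype=float).sum(axis=-1) > threshold


def mean_stain_intensity(
    density_map: np.ndarray,
    mask: np.ndarray | None = None,
    description: str | None = None,
) -> StainQuant:
    """Mean density of one stain channel over masked pixels."""
    dm = np.asarray(density_map, dtype=float)
    if mask is None:
        mask = np.ones(dm.shape, dtype=bool)
        description = description or "full image"
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dm.shape:
        raise ValueError("mask shape must match the density map")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return StainQuant(
        mean_density=float(dm[mask].mean()),
        n_pixels=n,
        mask_description=description or "caller-provided mask",
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as 8-bit RGB."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_density_map(density: np.ndarray, path: str | Path) -> None:
    """Write one density channel as 16-bit grayscale PNG/TIFF.

    Densities are stored in fixed point at ``DENSITY_MAP_SCALE`` counts per
    OD unit (values above ~6.5 OD saturate).
    """
    arr = np.clip(
        np.asarray(density, dtype=float) * DENSITY_MAP_SCALE, 0, 65535
    ).astype(np.uint16)
    Image.fromarray(arr).save(path)
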