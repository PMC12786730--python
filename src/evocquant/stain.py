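"""Optical-density conversion and linear stain unmixing for H-DAB images.

Brightfield absorbances combine additively in optical-density space
(Beer-Lambert), so a pixel's OD triple is modelled as a non-negative linear
combination of per-stain unit vectors.  Unmixing solves the resulting 3x3
linear system per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from evocquant.errors import ConfigurationError, FormatError

#: Widely used H-DAB absorbance vectors (RGB order, re-normalised on load).
RUIFROK_HEMATOXYLIN = (0.651, 0.701, 0.290)
RUIFROK_DAB = (0.269, 0.568, 0.778)

_UNIT_NORM_TOL = 1e-9


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainVectorSet:
    """Unit absorbance vectors for hematoxylin, DAB and the residual stain.

    The residual vector completes the basis so that the 3x3 stain matrix is
    invertible; by default it is the normalised cross product of the two
    chromogen vectors and therefore orthogonal to both.
    """

    h_vector: np.ndarray
    dab_vector: np.ndarray
    residual_vector: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        for attr in ("h_vector", "dab_vector", "residual_vector"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (3,):
                raise ConfigurationError(f"{attr} must have 3 components")
            if abs(np.linalg.norm(v) - 1.0) > _UNIT_NORM_TOL:
                raise ConfigurationError(f"{attr} must have unit norm")
            object.__setattr__(self, attr, v)
        if np.any(self.h_vector < 0) or np.any(self.dab_vector < 0):
            raise ConfigurationError("h and dab vectors must be non-negative")
        if not np.isfinite(np.linalg.cond(self.matrix)):
            raise ConfigurationError("stain matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """Stain matrix with one column per stain (h, dab, residual)."""
        return np.stack(
            [self.h_vector, self.dab_vector, self.residual_vector], axis=1
        )

    @classmethod
    def from_rows(cls, rows, name: str = "custom") -> "StainVectorSet":
        """Build from three RGB rows (h, dab, residual); rows are normalised.

        A zero residual row is replaced by the cross product of h and dab.
        """
        rows = np.asarray(rows, dtype=float)
        if rows.shape != (3, 3):
            raise ConfigurationError("expected a 3x3 matrix of stain rows")
        h = _normalize(rows[0])
        d = _normalize(rows[1])
        if np.allclose(rows[2], 0.0):
            r = _normalize(np.cross(h, d))
        else:
            r = _normalize(rows[2])
        return cls(h_vector=h, dab_vector=d, residual_vector=r, name=name)


@dataclass(frozen=True)
class ODImage:
    """Per-pixel optical densities (base-10) with physical pixel size."""

    od: np.ndarray  # (H, W, 3) float array
    pixel_size_um: float

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[2] != 3:
            raise FormatError("OD array must have shape (H, W, 3)")
        if not np.all(np.isfinite(od)):
            raise FormatError("OD values must be finite")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        object.__setattr__(self, "od", od)

    @property
    def height(self) -> int:
        return self.od.shape[0]

    @property
    def width(self) -> int:
        return self.od.shape[1]


@dataclass(frozen=True)
class StainChannels:
    """Unmixed per-pixel stain concentrations (unitless OD amounts)."""

    h_map: np.ndarray
    dab_map: np.ndarray
    residual_map: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(m).shape
            for m in (self.h_map, self.dab_map, self.residual_map)
        }
        if len(shapes) != 1:
            raise FormatError("channel maps must share one shape")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")


def rgb_to_od(image_rgb: np.ndarray, i0: float = 255.0,
              pixel_size_um: float = 0.5) -> ODImage:
    """Convert an 8-bit RGB raster to base-10 optical densities.

    ``OD_c = log10(i0 / max(I_c, 1))`` per channel; intensities are floored
    at 1 so fully opaque pixels map to a finite OD, and values brighter than
    the white point clip to OD 0.
    """
    if i0 <= 0:
        raise ConfigurationError("white point i0 must be positive")
    img = np.asarray(image_rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError("expected a 3-channel RGB image")
    intensity = np.maximum(img.astype(float), 1.0)
    od = np.log10(i0 / intensity)
    np.clip(od, 0.0, None, out=od)
    return ODImage(od=od, pixel_size_um=pixel_size_um)


def default_hdab_vectors() -> StainVectorSet:
    """Return the standard H-DAB stain vectors (unit-normalised).

    The residual axis is the normalised cross product of the hematoxylin and
    DAB vectors, making the basis complete for arbitrary RGB absorbances.
    """
    h = _normalize(RUIFROK_HEMATOXYLIN)
    d = _normalize(RUIFROK_DAB)
    r = _normalize(np.cross(h, d))
    return StainVectorSet(h_vector=h, dab_vector=d, residual_vector=r,
                          name="h-dab-default")


def unmix(od_image: ODImage, vectors: StainVectorSet | None = None) -> StainChannels:
    """Deconvolve an OD image into stain concentration maps.

    Solves ``od = M @ c`` per pixel where the columns of ``M`` are the stain
    vectors.  Negative concentrations (noise pushing a pixel outside the
    stain cone) are clipped to zero.
    """
    if vectors is None:
        vectors = default_hdab_vectors()
    m = vectors.matrix
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise ConfigurationError("stain matrix is singular or ill-conditioned")
    inv = np.linalg.inv(m)
    flat = od_image.od.reshape(-1, 3)
    conc = flat @ inv.T
    np.clip(conc, 0.0, None, out=conc)
    conc = conc.reshape(od_image.od.shape)
    return StainChannels(
        h_map=np.ascontiguousarray(conc[..., 0]),
        dab_map=np.ascontiguousarray(conc[..., 1]),
        residual_map=np.ascontiguousarray(conc[..., 2]),
        pixel_size_um=od_image.pixel_size_um,
    )


def render_od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Forward render OD triples to 8-bit intensities: ``I = i0 * 10**-OD``."""
    intensity = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
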