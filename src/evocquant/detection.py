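"""Nucleus detection, splitting and DAB positivity calling.

Detection runs on the unmixed hematoxylin channel: foreground thresholding,
hole filling, marker-based watershed splitting of touching nuclei, and a
size gate on the equivalent circular radius.  Positivity is called on the
mean DAB optical density over the nuclear mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation

from evocquant.errors import ConfigurationError
from evocquant.stain import StainChannels

MARKERS = ("Ki67", "PLAP")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the positive-cell detector.

    Radii bound the equivalent circular radius of a detected nucleus
    (area between ``pi*min**2`` and ``pi*max**2``).  The splitting
    threshold is the minimum OD prominence that separates two watershed
    markers.  All length parameters are in micrometres.
    """

    pixel_size_um: float | None = 0.5
    min_radius_um: float = 5.0
    max_radius_um: float = 10.0
    splitting_threshold: float = 0.15
    cell_expansion_um: float = 3.0
    dab_od_threshold: float = 0.15
    smoothing_sigma_um: float = 1.0
    h_od_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if not 0 < self.min_radius_um < self.max_radius_um:
            raise ConfigurationError(
                "need 0 < min_radius_um < max_radius_um"
            )
        for name in ("splitting_threshold", "cell_expansion_um",
                     "dab_od_threshold", "smoothing_sigma_um",
                     "h_od_threshold"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Nucleus:
    """One detected nucleus with geometry and mean stain ODs.

    ``centroid_um`` is (x, y) from the tile's top-left corner, pixel-center
    convention (micron coordinate = pixel index * pixel size).  ``pixels``
    holds the (rows, cols) index arrays of the nuclear mask and is carried
    so later stages can aggregate over the same mask.
    """

    id: int
    centroid_um: tuple[float, float]
    area_um2: float
    equiv_radius_um: float
    mean_h_od: float
    mean_dab_od: float = 0.0
    positive: bool = False
    marker: str = "Ki67"
    pixels: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False,
                                                  compare=False)

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ConfigurationError(f"marker must be one of {MARKERS}")


@dataclass(frozen=True)
class CellTerritory:
    """Expanded cell region owned by one nucleus; territories are disjoint."""

    nucleus_id: int
    area_um2: float
    pixels: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False,
                                                  compare=False)


def _as_h_map(h_map) -> tuple[np.ndarray, float | None]:
    if isinstance(h_map, StainChannels):
        return np.asarray(h_map.h_map, dtype=float), h_map.pixel_size_um
    return np.asarray(h_map, dtype=float), None


def detect_nuclei(h_map, params: DetectionParams,
                  marker: str = "Ki67") -> list[Nucleus]:
    """Detect nuclei on a hematoxylin OD map.

    Pipeline: Gaussian smoothing (for marker extraction and watershed
    topography) -> foreground threshold -> hole filling -> watershed with
    prominence-gated markers -> size filter on equivalent radius.  The
    foreground mask is taken on the raw map so that smoothing does not
    systematically inflate nuclear areas; the smoothed map drives only the
    splitting.  Output is ordered by centroid (y, x) and fully
    deterministic.
    """
    arr, carried_psz = _as_h_map(h_map)
    pixel_size = carried_psz if carried_psz is not None else params.pixel_size_um
    if pixel_size is None or pixel_size <= 0:
        raise ConfigurationError("pixel size missing: provide StainChannels "
                                 "or set DetectionParams.pixel_size_um")
    if arr.ndim != 2:
        raise ConfigurationError("h_map must be a 2-D raster")

    sigma_px = params.smoothing_sigma_um / pixel_size
    smoothed = ndi.gaussian_filter(arr, sigma=sigma_px) if sigma_px > 0 else arr

    foreground = arr > params.h_od_threshold
    foreground = ndi.binary_fill_holes(foreground)
    if not foreground.any():
        return []

    if params.splitting_threshold > 0:
        peaks = morphology.h_maxima(smoothed, params.splitting_threshold)
    else:
        peaks = morphology.local_maxima(smoothed)
    peaks &= foreground
    marker_labels, n_markers = ndi.label(peaks)
    if n_markers == 0:
        # Flat foreground with no interior maxima: fall back to components.
        labels, _ = ndi.label(foreground)
    else:
        labels = segmentation.watershed(-smoothed, markers=marker_labels,
                                        mask=foreground)

    min_area_px = np.pi * (params.min_radius_um / pixel_size) ** 2
    max_area_px = np.pi * (params.max_radius_um / pixel_size) ** 2

    nuclei: list[Nucleus] = []
    for region in measure.regionprops(labels, intensity_image=arr):
        if not (min_area_px <= region.area <= max_area_px):
            continue
        cy, cx = region.centroid
        area_um2 = region.area * pixel_size**2
        rows, cols = np.nonzero(labels[region.slice] == region.label)
        rows = rows + region.slice[0].start
        cols = cols + region.slice[1].start
        nuclei.append(Nucleus(
            id=-1,
            centroid_um=(cx * pixel_size, cy * pixel_size),
            area_um2=area_um2,
            equiv_radius_um=float(np.sqrt(area_um2 / np.pi)),
            mean_h_od=float(region.intensity_mean),
            marker=marker,
            pixels=(rows, cols),
        ))

    nuclei.sort(key=lambda n: (n.centroid_um[1], n.centroid_um[0]))
    return [replace(n, id=i) for i, n in enumerate(nuclei)]


def classify_positive(nuclei: list[Nucleus], dab_map,
                      threshold: float = 0.15) -> list[Nucleus]:
    """Call DAB positivity per nucleus: positive iff mean nuclear DAB OD
    strictly exceeds the threshold.  Input order is preserved."""
    if isinstance(dab_map, StainChannels):
        dab = np.asarray(dab_map.dab_map, dtype=float)
    else:
        dab = np.asarray(dab_map, dtype=float)
    out = []
    for n in nuclei:
        mean_dab = float(dab[n.pixels].mean()) if n.pixels is not None else n.mean_dab_od
        out.append(replace(n, mean_dab_od=mean_dab,
                           positive=bool(mean_dab > threshold)))
    return out


def expand_cells(nuclei: list[Nucleus], shape: tuple[int, int],
                 expansion_um: float,
                 pixel_size_um: float) -> list[CellTerritory]:
    """Dilate each nuclear mask outward by ``expansion_um``, truncated where
    territories would collide (nearest-nucleus assignment), so that the
    resulting territories are pairwise disjoint and each contains its
    nucleus."""
    if expansion_um < 0:
        raise ConfigurationError("expansion_um must be >= 0")
    labels = np.zeros(shape, dtype=np.int32)
    for n in nuclei:
        labels[n.pixels] = n.id + 1
    expanded = segmentation.expand_labels(
        labels, distance=expansion_um / pixel_size_um)
    territories = []
    for n in nuclei:
        rows, cols = np.nonzero(expanded == n.id + 1)
        territories.append(CellTerritory(
            nucleus_id=n.id,
            area_um2=float(rows.size) * pixel_size_um**2,
            pixels=(rows, cols),
        ))
    return territories


DETECTION_COLUMNS = ["nucleus_id", "x_um", "y_um", "area_um2",
                     "equiv_radius_um", "mean_h_od", "mean_dab_od",
                     "positive", "marker"]


def detections_to_frame(nuclei: list[Nucleus]) -> pd.DataFrame:
    """Tabulate detections in the canonical CSV schema (positive as 0/1)."""
    rows = [{
        "nucleus_id": n.id,
        "x_um": n.centroid_um[0],
        "y_um": n.centroid_um[1],
        "area_um2": n.area_um2,
        "equiv_radius_um": n.equiv_radius_um,
        "mean_h_od": n.mean_h_od,
        "mean_dab_od": n.mean_dab_od,
        "positive": int(n.positive),
        "marker": n.marker,
    } for n in nuclei]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)
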