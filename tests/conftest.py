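import numpy as np
import pytest

from evocquant.stain import default_hdab_vectors


@pytest.fixture(scope="session")
def hdab():
    return default_hdab_vectors()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def paint_disk(h_map: np.ndarray, cx_um: float, cy_um: float, r_um: float,
               pixel_size_um: float, od: float = 0.8) -> None:
    """Paint a flat-profile disk onto an OD map (max composition)."""
    yy, xx = np.mgrid[0:h_map.shape[0], 0:h_map.shape[1]]
    mask = ((xx * pixel_size_um - cx_um) ** 2
            + (yy * pixel_size_um - cy_um) ** 2) <= r_um ** 2
    np.maximum(h_map, np.where(mask, od, 0.0), out=h_map)


def paint_dome(h_map: np.ndarray, cx_um: float, cy_um: float, r_um: float,
               pixel_size_um: float, peak_od: float = 0.8) -> None:
    """Paint a domed-profile nucleus (hemispheric OD profile)."""
    yy, xx = np.mgrid[0:h_map.shape[0], 0:h_map.shape[1]]
    d2 = (((xx * pixel_size_um - cx_um) ** 2
           + (yy * pixel_size_um - cy_um) ** 2) / r_um ** 2)
    dome = np.where(d2 <= 1, peak_od * np.sqrt(np.clip(1 - d2, 0, 1)), 0.0)
    np.maximum(h_map, dome, out=h_map)
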