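"""Ground-truthed synthetic inputs: rendered H-DAB tiles and count cohorts.

Tiles are rendered through the same physical model the analysis inverts
(additive OD stain mixing, 8-bit exponential intensity), so detection and
unmixing can be validated against exact planted truth.  Cohort simulation
produces 12-sample longitudinal count tables whose per-day means/SDs follow
a configurable calibration; the shipped default reproduces the reference
seminoma culture morphometry (OCN ~47,595 at baseline declining to ~21,413
by day 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evocquant.errors import CapacityError, ConfigurationError
from evocquant.morphometry import TimePointCounts
from evocquant.stain import StainVectorSet, default_hdab_vectors, render_od_to_rgb

#: Default per-day calibration of the simulated seminoma cohort
#: (means and SDs of each morphometric quantity on days 0/3/7/10).
REFERENCE_DAYS = (0, 3, 7, 10)
REFERENCE_CALIBRATION = {
    "OCN": {"means": (47595.2, 42166.7, 32109.4, 21413.17),
            "sds": (3617.6, 3494.2, 3649.9, 1933.9)},
    "TCN": {"means": (40611.89, 37960.3, 29408.2, 18986.72),
            "sds": (1890.5, 2811.3, 3211.4, 1197.4)},
    "stromal": {"means": (5983.3, 4206.4, 2695.17, 2426.44),
                "sds": (3685.2, 2346.2, 1059.9, 1644.8)},
    "PI": {"means": (89.47, 88.05, 68.002, 43.886),
           "sds": (5.522, 6.424, 7.013, 5.501)},
}


@dataclass(frozen=True)
class ImageSimSpec:
    """Parameters of one rendered H-DAB tile with planted nuclei."""

    tile_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_nuclei: int = 40
    radius_um_range: tuple[float, float] = (5.5, 9.5)
    positive_fraction: float = 0.5
    h_od_mean: float = 0.8
    h_od_sd: float = 0.05
    dab_od_pos_mean: float = 0.6
    dab_od_pos_sd: float = 0.08
    dab_od_neg_mean: float = 0.03
    noise_sd: float = 0.0
    min_separation_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ConfigurationError("positive_fraction must be in [0, 1]")
        if self.min_separation_um < 0:
            raise ConfigurationError("min_separation_um must be >= 0")
        for name in ("h_od_mean", "dab_od_pos_mean", "dab_od_neg_mean",
                     "noise_sd", "h_od_sd", "dab_od_pos_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.radius_um_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid radius_um_range")


@dataclass(frozen=True)
class GroundTruthTable:
    """Planted nuclei: positions (µm), radii, stain ODs, positivity."""

    centroids_um: np.ndarray  # (n, 2) as (x, y)
    radii_um: np.ndarray
    h_od: np.ndarray
    dab_od: np.ndarray
    positive: np.ndarray  # bool

    def __len__(self) -> int:
        return self.centroids_um.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_um": self.centroids_um[:, 0] if len(self) else [],
            "y_um": self.centroids_um[:, 1] if len(self) else [],
            "radius_um": self.radii_um,
            "h_od": self.h_od,
            "dab_od": self.dab_od,
            "positive": self.positive.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruthTable":
        return cls(
            centroids_um=df[["x_um", "y_um"]].to_numpy(dtype=float),
            radii_um=df["radius_um"].to_numpy(dtype=float),
            h_od=df["h_od"].to_numpy(dtype=float),
            dab_od=df["dab_od"].to_numpy(dtype=float),
            positive=df["positive"].to_numpy().astype(bool),
        )


def _place_centers(rng: np.random.Generator, spec: ImageSimSpec,
                   radii_um: np.ndarray) -> np.ndarray:
    """Seeded rejection sampling of non-overlapping nucleus centers."""
    h_px, w_px = spec.tile_px
    height_um = h_px * spec.pixel_size_um
    width_um = w_px * spec.pixel_size_um
    centers = np.empty((spec.n_nuclei, 2))
    max_attempts = 2000 * max(spec.n_nuclei, 1)
    attempts = 0
    for i in range(spec.n_nuclei):
        margin = radii_um[i] + spec.pixel_size_um
        if 2 * margin >= width_um or 2 * margin >= height_um:
            raise CapacityError("nucleus does not fit in tile")
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not place {spec.n_nuclei} nuclei at separation "
                    f"{spec.min_separation_um} µm in a "
                    f"{width_um:.0f}x{height_um:.0f} µm tile")
            x = rng.uniform(margin, width_um - margin)
            y = rng.uniform(margin, height_um - margin)
            if i == 0:
                break
            d2 = np.sum((centers[:i] - (x, y)) ** 2, axis=1)
            if np.all(d2 >= spec.min_separation_um ** 2):
                break
        centers[i] = (x, y)
    return centers


def simulate_ihc_tile(spec: ImageSimSpec,
                      vectors: StainVectorSet | None = None
                      ) -> tuple[np.ndarray, GroundTruthTable]:
    """Render one 8-bit RGB tile of H-DAB stained nuclei plus its truth.

    Nuclei are disks with per-nucleus hematoxylin/DAB OD draws; positives
    receive DAB OD from the positive distribution, negatives the constant
    background DAB level.  The positive count is ``round(n * fraction)``
    (round-half-even).  Per-channel Gaussian OD noise is added before the
    exponential 8-bit rendering; the same seed gives a byte-identical tile.
    """
    if vectors is None:
        vectors = default_hdab_vectors()
    rng = np.random.default_rng(spec.seed)
    h_px, w_px = spec.tile_px
    n = spec.n_nuclei

    radii = rng.uniform(*spec.radius_um_range, size=n)
    centers = _place_centers(rng, spec, radii) if n else np.empty((0, 2))
    h_od = np.clip(rng.normal(spec.h_od_mean, spec.h_od_sd, size=n), 0, None)
    n_pos = int(round(n * spec.positive_fraction))
    pos_idx = rng.choice(n, size=n_pos, replace=False) if n else np.array([], int)
    positive = np.zeros(n, dtype=bool)
    positive[pos_idx] = True
    dab_od = np.full(n, spec.dab_od_neg_mean)
    dab_od[positive] = np.clip(
        rng.normal(spec.dab_od_pos_mean, spec.dab_od_pos_sd, size=n_pos),
        0, None)

    od = np.zeros((h_px, w_px, 3))
    if n:
        yy, xx = np.mgrid[0:h_px, 0:w_px]
        xx_um = xx * spec.pixel_size_um
        yy_um = yy * spec.pixel_size_um
        for i in range(n):
            cx, cy = centers[i]
            mask = (xx_um - cx) ** 2 + (yy_um - cy) ** 2 <= radii[i] ** 2
            od[mask] += (h_od[i] * vectors.h_vector
                         + dab_od[i] * vectors.dab_vector)
    if spec.noise_sd > 0:
        od += rng.normal(0.0, spec.noise_sd, size=od.shape)
        np.clip(od, 0.0, None, out=od)

    rgb = render_od_to_rgb(od)
    truth = GroundTruthTable(centroids_um=centers, radii_um=radii,
                             h_od=h_od, dab_od=dab_od, positive=positive)
    return rgb, truth


@dataclass(frozen=True)
class CohortSimSpec:
    """Structural model of a longitudinal count cohort.

    Per sample, a baseline cell count splits into tumor and stromal
    compartments that decay along per-day survival fractions; a per-sample
    per-day lognormal effect (sigma = ``sample_effect_sd``) adds correlated
    biological/measurement noise, and the proliferation index follows its
    own per-day normal curve truncated to [0, 100].
    """

    n_samples: int = 12
    days: tuple[int, ...] = REFERENCE_DAYS
    baseline_ocn_mean: float = REFERENCE_CALIBRATION["OCN"]["means"][0]
    baseline_ocn_sd: float = REFERENCE_CALIBRATION["OCN"]["sds"][0]
    tumor_fraction_mean: float = (REFERENCE_CALIBRATION["TCN"]["means"][0]
                                  / REFERENCE_CALIBRATION["OCN"]["means"][0])
    tumor_survival: tuple[float, ...] = tuple(
        m / REFERENCE_CALIBRATION["TCN"]["means"][0]
        for m in REFERENCE_CALIBRATION["TCN"]["means"])
    stromal_survival: tuple[float, ...] = tuple(
        m / REFERENCE_CALIBRATION["stromal"]["means"][0]
        for m in REFERENCE_CALIBRATION["stromal"]["means"])
    pi_curve: tuple[float, ...] = REFERENCE_CALIBRATION["PI"]["means"]
    pi_sd: float = 6.0
    sample_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.days)
        for name in ("tumor_survival", "stromal_survival", "pi_curve"):
            if len(getattr(self, name)) != k:
                raise ConfigurationError(f"{name} must have one value per day")
        for surv in (self.tumor_survival, self.stromal_survival):
            if any(not 0 <= s <= 1 for s in surv):
                raise ConfigurationError("survival fractions must be in [0, 1]")
            if any(b > a + 1e-12 for a, b in zip(surv, surv[1:])):
                pass  # non-monotone allowed for stromal rebound scenarios
        if any(not 0 <= p <= 100 for p in self.pi_curve):
            raise ConfigurationError("pi_curve values must be in [0, 100]")
        if not 0 < self.tumor_fraction_mean <= 1:
            raise ConfigurationError("tumor_fraction_mean must be in (0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    records: tuple[TimePointCounts, ...]
    truth: CohortSimSpec


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = np.inf,
                      size: int | None = None) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far in the tails here)."""
    n = 1 if size is None else size
    out = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        bad = (out <= low) | (out >= high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    np.clip(out, low + 1e-9, high - 1e-9 if np.isfinite(high) else None,
            out=out)
    return out[0] if size is None else out


def simulate_cohort(spec: CohortSimSpec) -> SimulatedCohort:
    """Generate a full longitudinal cohort of PLAP and Ki67 count records."""
    rng = np.random.default_rng(spec.seed)
    records: list[TimePointCounts] = []
    k = len(spec.days)
    for i in range(spec.n_samples):
        sample = f"S{i + 1:02d}"
        ocn0 = float(_truncated_normal(rng, spec.baseline_ocn_mean,
                                       spec.baseline_ocn_sd, low=0.0))
        tcn0 = spec.tumor_fraction_mean * ocn0
        stromal0 = ocn0 - tcn0
        if spec.sample_effect_sd > 0:
            effects = rng.lognormal(0.0, spec.sample_effect_sd, size=(2, k))
        else:
            effects = np.ones((2, k))
        effects[:, 0] = 1.0  # day 0 is each sample's own observed baseline
        for j, day in enumerate(spec.days):
            tcn = int(round(tcn0 * spec.tumor_survival[j] * effects[0, j]))
            stromal = int(round(stromal0 * spec.stromal_survival[j]
                                * effects[1, j]))
            ocn = tcn + stromal
            records.append(TimePointCounts(
                sample_id=sample, day=int(day), marker="PLAP",
                ocn=ocn, positive_count=tcn, tcn=tcn, stromal=stromal))
            pi = float(_truncated_normal(rng, spec.pi_curve[j], spec.pi_sd,
                                         low=0.0, high=100.0))
            ki_pos = int(round(pi / 100.0 * ocn))
            records.append(TimePointCounts(
                sample_id=sample, day=int(day), marker="Ki67",
                ocn=ocn, positive_count=ki_pos,
                pi_percent=(100.0 * ki_pos / ocn) if ocn else None,
                flags=("pi_undefined",) if ocn == 0 else ()))
    return SimulatedCohort(records=tuple(records), truth=spec)


def simulate_quantity_matrix(means, sds, n_samples: int,
                             sample_effect_sd: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Simulate an (n_samples, k) matrix of one quantity from per-day
    means/SDs with a shared per-sample multiplicative lognormal effect.

    The shared effect induces within-subject correlation across days while
    cancelling out of per-sample day-0-relative ratios.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape:
        raise ConfigurationError("means and sds must align")
    k = means.size
    effects = (rng.lognormal(0.0, sample_effect_sd, size=n_samples)
               if sample_effect_sd > 0 else np.ones(n_samples))
    out = np.empty((n_samples, k))
    for j in range(k):
        out[:, j] = _truncated_normal(rng, means[j], sds[j], low=0.0,
                                      size=n_samples)
    return out * effects[:, None]


@dataclass(frozen=True)
class MatchResult:
    precision: float
    recall: float
    f1: float
    positivity_agreement: float | None
    n_matched: int


def ground_truth_compare(detections, truth: GroundTruthTable,
                         match_radius_um: float) -> MatchResult:
    """Greedy nearest-neighbour matching of detections against truth.

    Candidate pairs within ``match_radius_um`` are matched in increasing
    distance order, each detection and each truth row at most once.
    Positivity agreement is the fraction of matched pairs whose positive
    labels coincide (None when nothing matched).
    """
    det_xy = np.asarray([n.centroid_um for n in detections], dtype=float)
    det_pos = np.asarray([n.positive for n in detections], dtype=bool)
    n_det, n_truth = len(detections), len(truth)
    if n_det == 0 or n_truth == 0:
        precision = 1.0 if n_det == 0 and n_truth == 0 else 0.0
        recall = precision
        f1 = precision
        return MatchResult(precision, recall, f1, None, 0)

    d = np.linalg.norm(det_xy[:, None, :] - truth.centroids_um[None, :, :],
                       axis=2)
    pairs = np.argwhere(d <= match_radius_um)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_det = np.zeros(n_det, dtype=bool)
    used_truth = np.zeros(n_truth, dtype=bool)
    agree = 0
    matched = 0
    for di, ti in pairs[order]:
        if used_det[di] or used_truth[ti]:
            continue
        used_det[di] = used_truth[ti] = True
        matched += 1
        if det_pos[di] == truth.positive[ti]:
            agree += 1
    precision = matched / n_det
    recall = matched / n_truth
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MatchResult(precision=precision, recall=recall, f1=f1,
                       positivity_agreement=(agree / matched) if matched
                       else None,
                       n_matched=matched)
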