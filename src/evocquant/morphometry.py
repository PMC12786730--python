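"""ROI restriction, per-time-point counting and cohort summaries.

Quantities follow the study design of PLAP/Ki-67 stained serial sections:

- OCN: all detected cells inside the tumor ROI,
- TCN: PLAP-positive cells (tumor cells),
- stromal: OCN - TCN on PLAP slides,
- PI: percentage of Ki-67-positive nuclei among all nuclei.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import MultiPolygon, Polygon, shape
from shapely.prepared import prep

from evocquant.detection import MARKERS, Nucleus
from evocquant.errors import EmptyRoiError, ValidationError
from evocquant.viability import TrajectorySeries

DEFAULT_SCHEDULE = (0, 3, 7, 10)
QUANTITIES = ("OCN", "TCN", "stromal", "PI")

COUNTS_COLUMNS = ["sample_id", "day", "marker", "ocn", "positive_count",
                  "pi_percent", "tcn", "stromal"]


@dataclass(frozen=True)
class RegionOfInterest:
    """Pathologist-drawn tumor region as polygons in micron coordinates."""

    polygons: tuple[Polygon, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.polygons) == 0:
            raise EmptyRoiError("ROI contains no polygons")
        for p in self.polygons:
            if len(p.exterior.coords) < 4:  # closed ring: >= 3 distinct vertices
                raise ValidationError("ROI ring needs at least 3 vertices")

    @classmethod
    def from_rings(cls, rings, label: str = "") -> "RegionOfInterest":
        """Build from a list of coordinate rings (one polygon per ring)."""
        return cls(polygons=tuple(Polygon(r) for r in rings), label=label)

    def union(self) -> MultiPolygon:
        polys = [p if p.is_valid else p.buffer(0) for p in self.polygons]
        return MultiPolygon(polys) if len(polys) > 1 else polys[0]


def roi_from_geojson(source, pixel_size_um: float | None = None,
                     label: str = "") -> RegionOfInterest:
    """Load an ROI from GeoJSON (FeatureCollection, Feature or geometry).

    Coordinates are taken as microns; pass ``pixel_size_um`` for exports in
    pixel coordinates (QuPath dialect), which are converted on load.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            obj = json.load(fh)
    else:
        obj = source

    geoms = []
    if obj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in obj.get("features", [])]
    elif obj.get("type") == "Feature":
        geoms = [obj["geometry"]]
    else:
        geoms = [obj]

    polygons: list[Polygon] = []
    for g in geoms:
        geom = shape(g)
        if geom.geom_type == "Polygon":
            polygons.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polygons.extend(geom.geoms)
        else:
            raise ValidationError(f"unsupported ROI geometry {geom.geom_type}")
    if pixel_size_um is not None:
        from shapely.affinity import scale as _scale
        polygons = [_scale(p, xfact=pixel_size_um, yfact=pixel_size_um,
                           origin=(0, 0)) for p in polygons]
    return RegionOfInterest(polygons=tuple(polygons), label=label)


def apply_roi(nuclei: list[Nucleus],
              roi: RegionOfInterest) -> list[Nucleus]:
    """Keep nuclei whose centroid lies inside (or on the boundary of) any
    ROI polygon."""
    from shapely.geometry import Point

    prepared = [prep(p if p.is_valid else p.buffer(0)) for p in roi.polygons]
    kept = []
    for n in nuclei:
        pt = Point(n.centroid_um)
        if any(p.covers(pt) for p in prepared):
            kept.append(n)
    return kept


@dataclass(frozen=True)
class TimePointCounts:
    """Counts for one (sample, day, marker) slide.

    ``pi_percent`` is populated for Ki67 slides (None when OCN is zero, with
    the ``pi_undefined`` flag), ``tcn``/``stromal`` for PLAP slides.
    """

    sample_id: str
    day: int
    marker: str
    ocn: int
    positive_count: int
    pi_percent: float | None = None
    tcn: int | None = None
    stromal: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"marker must be one of {MARKERS}")
        if not 0 <= self.positive_count <= self.ocn:
            raise ValidationError("need 0 <= positive_count <= ocn")
        if self.pi_percent is not None and not 0 <= self.pi_percent <= 100:
            raise ValidationError("pi_percent outside [0, 100]")
        if self.stromal is not None and self.stromal < 0:
            raise ValidationError("stromal must be >= 0")


def count_cells(nuclei_in_roi: list[Nucleus], marker: str,
                sample_id: str = "", day: int = 0) -> TimePointCounts:
    """Aggregate ROI-restricted detections into the per-slide counts."""
    if any(n.marker != marker for n in nuclei_in_roi):
        raise ValidationError("all nuclei must carry the requested marker")
    ocn = len(nuclei_in_roi)
    positive = sum(1 for n in nuclei_in_roi if n.positive)
    if marker == "Ki67":
        if ocn == 0:
            return TimePointCounts(sample_id=sample_id, day=day, marker=marker,
                                   ocn=0, positive_count=0, pi_percent=None,
                                   flags=("pi_undefined",))
        return TimePointCounts(sample_id=sample_id, day=day, marker=marker,
                               ocn=ocn, positive_count=positive,
                               pi_percent=100.0 * positive / ocn)
    return TimePointCounts(sample_id=sample_id, day=day, marker=marker,
                           ocn=ocn, positive_count=positive,
                           tcn=positive, stromal=ocn - positive)


@dataclass(frozen=True)
class SampleTimecourse:
    """Ordered records of one (sample, marker) pair with missing-day flags."""

    sample_id: str
    marker: str
    records: tuple[TimePointCounts, ...]
    missing_days: tuple[int, ...] = ()

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(r.day for r in self.records)


def assemble_timecourse(records: list[TimePointCounts],
                        schedule=DEFAULT_SCHEDULE
                        ) -> dict[tuple[str, str], SampleTimecourse]:
    """Group records into per-(sample, marker) day-ordered series.

    Duplicate (sample, day, marker) combinations are a validation error;
    days absent from the schedule are flagged on the series.
    """
    seen: set[tuple[str, int, str]] = set()
    grouped: dict[tuple[str, str], list[TimePointCounts]] = {}
    for r in records:
        key = (r.sample_id, r.day, r.marker)
        if key in seen:
            raise ValidationError(f"duplicate record for {key}")
        seen.add(key)
        grouped.setdefault((r.sample_id, r.marker), []).append(r)

    out = {}
    for (sample, marker), recs in grouped.items():
        recs = sorted(recs, key=lambda r: r.day)
        present = {r.day for r in recs}
        missing = tuple(d for d in schedule if d not in present)
        out[(sample, marker)] = SampleTimecourse(
            sample_id=sample, marker=marker, records=tuple(recs),
            missing_days=missing)
    return out


def _record_value(rec: TimePointCounts, quantity: str) -> float | None:
    if quantity == "OCN":
        return float(rec.ocn)
    if quantity == "TCN":
        return None if rec.tcn is None else float(rec.tcn)
    if quantity == "stromal":
        return None if rec.stromal is None else float(rec.stromal)
    if quantity == "PI":
        return rec.pi_percent
    raise ValidationError(f"unknown quantity {quantity!r}")


def extract_series(tc: SampleTimecourse, quantity: str) -> TrajectorySeries:
    """Pull one quantity out of a timecourse as a TrajectorySeries."""
    days, values = [], []
    for rec in tc.records:
        v = _record_value(rec, quantity)
        if v is not None:
            days.append(rec.day)
            values.append(v)
    return TrajectorySeries(sample_id=tc.sample_id, quantity=quantity,
                            days=tuple(days), values=tuple(values))


@dataclass(frozen=True)
class CohortSummary:
    """Per-day mean/SD/CI and per-day percent-decrease medians with IQR."""

    quantity: str
    per_day: pd.DataFrame      # day, n, mean, sd, ci95_low, ci95_high
    decreases: pd.DataFrame    # day, n, median_pct_decrease, iqr_low, iqr_high


def summarize_cohort(all_series: list[TrajectorySeries],
                     quantity: str) -> CohortSummary:
    """Cohort-level summary of one quantity across samples.

    Per day: mean, SD (n-1 denominator) and the 95% t-interval for the
    mean.  Per day > 0: each sample's percent decrease versus its own
    day-0 baseline, 100*(x0 - xd)/x0, summarised as median and IQR
    (linear-interpolation quartiles).  Samples with a non-positive
    baseline are excluded from the decrease block with a warning.
    """
    series = [s for s in all_series if s.quantity == quantity]
    if len(series) < 2:
        raise ValidationError("need at least 2 samples to summarise")

    by_day: dict[int, list[float]] = {}
    for s in series:
        for d, v in zip(s.days, s.values):
            by_day.setdefault(d, []).append(v)

    rows = []
    for d in sorted(by_day):
        vals = np.asarray(by_day[d], dtype=float)
        n = vals.size
        mean = vals.mean()
        sd = vals.std(ddof=1) if n > 1 else np.nan
        if n > 1 and np.isfinite(sd):
            half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        else:
            half = np.nan
        rows.append({"day": d, "n": n, "mean": mean, "sd": sd,
                     "ci95_low": mean - half, "ci95_high": mean + half})
    per_day = pd.DataFrame(rows)

    dec_by_day: dict[int, list[float]] = {}
    for s in series:
        if 0 not in s.days:
            continue
        x0 = s.values[s.days.index(0)]
        if x0 <= 0:
            warnings.warn(f"sample {s.sample_id}: non-positive baseline, "
                          "excluded from percent-decrease summary")
            continue
        for d, v in zip(s.days, s.values):
            if d == 0:
                continue
            dec_by_day.setdefault(d, []).append(100.0 * (x0 - v) / x0)

    dec_rows = []
    for d in sorted(dec_by_day):
        vals = np.asarray(dec_by_day[d], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        dec_rows.append({"day": d, "n": vals.size, "median_pct_decrease": med,
                         "iqr_low": q1, "iqr_high": q3})
    decreases = pd.DataFrame(
        dec_rows, columns=["day", "n", "median_pct_decrease",
                           "iqr_low", "iqr_high"])
    return CohortSummary(quantity=quantity, per_day=per_day,
                         decreases=decreases)


def counts_to_frame(records: list[TimePointCounts]) -> pd.DataFrame:
    """Tabulate count records in the canonical CSV schema."""
    rows = [{
        "sample_id": r.sample_id, "day": r.day, "marker": r.marker,
        "ocn": r.ocn, "positive_count": r.positive_count,
        "pi_percent": r.pi_percent, "tcn": r.tcn, "stromal": r.stromal,
    } for r in records]
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def counts_from_frame(df: pd.DataFrame) -> list[TimePointCounts]:
    """Parse and validate a counts table back into records."""
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"counts table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        def _opt(v):
            return None if pd.isna(v) else v
        pi = _opt(row.pi_percent)
        tcn = _opt(row.tcn)
        stromal = _opt(row.stromal)
        records.append(TimePointCounts(
            sample_id=str(row.sample_id), day=int(row.day),
            marker=str(row.marker), ocn=int(row.ocn),
            positive_count=int(row.positive_count),
            pi_percent=None if pi is None else float(pi),
            tcn=None if tcn is None else int(tcn),
            stromal=None if stromal is None else int(stromal),
            flags=("pi_undefined",) if (row.marker == "Ki67" and pi is None)
            else (),
        ))
    return records
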