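import numpy as np
import pytest

from evocquant.detection import Nucleus
from evocquant.errors import EmptyRoiError, ValidationError
from evocquant.morphometry import (
    RegionOfInterest,
    TimePointCounts,
    apply_roi,
    assemble_timecourse,
    count_cells,
    counts_from_frame,
    counts_to_frame,
    extract_series,
    roi_from_geojson,
    summarize_cohort,
)
from evocquant.viability import TrajectorySeries


def _nucleus(x, y, marker="Ki67", positive=False, nid=0):
    return Nucleus(id=nid, centroid_um=(x, y), area_um2=100.0,
                   equiv_radius_um=6.0, mean_h_od=0.8,
                   mean_dab_od=0.3 if positive else 0.05,
                   positive=positive, marker=marker)


def _ray_cast_inside(px, py, ring):
    """Independent even-odd point-in-polygon oracle."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


SQUARE = [(0, 0), (10, 0), (10, 10), (0, 10)]


class TestApplyRoi:
    def test_interior_kept(self):
        roi = RegionOfInterest.from_rings([SQUARE])
        assert len(apply_roi([_nucleus(5, 5)], roi)) == 1

    def test_exterior_dropped(self):
        roi = RegionOfInterest.from_rings([SQUARE])
        assert apply_roi([_nucleus(15, 5)], roi) == []

    def test_boundary_counts_inside(self):
        roi = RegionOfInterest.from_rings([SQUARE])
        assert len(apply_roi([_nucleus(10.0, 5.0)], roi)) == 1

    def test_empty_roi_distinct_error(self):
        with pytest.raises(EmptyRoiError):
            RegionOfInterest(polygons=())

    def test_ring_needs_three_vertices(self):
        with pytest.raises(Exception):
            RegionOfInterest.from_rings([[(0, 0), (1, 1)]])

    def test_matches_ray_casting_oracle(self, rng):
        ring = [(0, 0), (64, 0), (64, 128), (0, 128)]  # left half of a tile
        roi = RegionOfInterest.from_rings([ring])
        nuclei = [_nucleus(x, y, nid=i) for i, (x, y) in
                  enumerate(rng.uniform(0, 128, size=(100, 2)))]
        kept = {n.id for n in apply_roi(nuclei, roi)}
        oracle = {n.id for n in nuclei
                  if _ray_cast_inside(*n.centroid_um, ring)}
        # the oracle excludes exact-boundary points, measure-zero for floats
        assert kept == oracle

    def test_multi_polygon_membership(self):
        roi = RegionOfInterest.from_rings(
            [SQUARE, [(20, 20), (30, 20), (30, 30), (20, 30)]])
        kept = apply_roi([_nucleus(5, 5), _nucleus(25, 25),
                          _nucleus(15, 15)], roi)
        assert len(kept) == 2


class TestRoiGeojson:
    def test_feature_collection(self, tmp_path):
        gj = {"type": "FeatureCollection", "features": [{
            "type": "Feature", "properties": {},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[0, 0], [10, 0], [10, 10],
                                          [0, 10], [0, 0]]]}}]}
        path = tmp_path / "roi.geojson"
        import json
        path.write_text(json.dumps(gj))
        roi = roi_from_geojson(path)
        assert len(apply_roi([_nucleus(5, 5)], roi)) == 1

    def test_pixel_coordinates_converted(self):
        gj = {"type": "Polygon",
              "coordinates": [[[0, 0], [20, 0], [20, 20], [0, 20], [0, 0]]]}
        roi = roi_from_geojson(gj, pixel_size_um=0.5)  # 20 px -> 10 µm
        assert len(apply_roi([_nucleus(5, 5)], roi)) == 1
        assert apply_roi([_nucleus(15, 5)], roi) == []

    def test_unsupported_geometry(self):
        with pytest.raises(ValidationError):
            roi_from_geojson({"type": "Point", "coordinates": [0, 0]})


class TestCountCells:
    def test_ki67_pi(self):
        nuclei = [_nucleus(i, 0, positive=(i < 90), nid=i) for i in range(200)]
        rec = count_cells(nuclei, "Ki67", sample_id="s", day=3)
        assert rec.ocn == 200 and rec.positive_count == 90
        assert rec.pi_percent == pytest.approx(45.0)
        assert rec.tcn is None and rec.stromal is None

    def test_plap_tcn_stromal(self):
        nuclei = [_nucleus(i, 0, marker="PLAP", positive=(i < 120), nid=i)
                  for i in range(150)]
        rec = count_cells(nuclei, "PLAP")
        assert rec.tcn == 120 and rec.stromal == 30
        assert rec.pi_percent is None

    def test_zero_nuclei_pi_null_flagged(self):
        rec = count_cells([], "Ki67")
        assert rec.pi_percent is None
        assert "pi_undefined" in rec.flags

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            count_cells([_nucleus(0, 0, marker="PLAP")], "Ki67")

    def test_conservation_invariant(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 300))
            pos = int(rng.integers(0, n + 1))
            nuclei = [_nucleus(i, 0, marker="PLAP", positive=(i < pos), nid=i)
                      for i in range(n)]
            rec = count_cells(nuclei, "PLAP")
            assert rec.tcn + rec.stromal == rec.ocn


class TestAssembleTimecourse:
    @staticmethod
    def _rec(sample, day, marker="Ki67", pi=50.0):
        return TimePointCounts(sample_id=sample, day=day, marker=marker,
                               ocn=100, positive_count=50, pi_percent=pi)

    def test_full_schedule_ordered(self):
        recs = [self._rec("a", d) for d in (7, 0, 10, 3)]
        tc = assemble_timecourse(recs)[("a", "Ki67")]
        assert tc.days == (0, 3, 7, 10)
        assert tc.missing_days == ()

    def test_duplicate_rejected(self):
        recs = [self._rec("a", 7), self._rec("a", 7)]
        with pytest.raises(ValidationError):
            assemble_timecourse(recs)

    def test_missing_days_flagged(self):
        recs = [self._rec("a", 0), self._rec("a", 7)]
        tc = assemble_timecourse(recs)[("a", "Ki67")]
        assert tc.missing_days == (3, 10)


class TestSummarizeCohort:
    @staticmethod
    def _series(sample, values, quantity="OCN", days=(0, 3, 7, 10)):
        return TrajectorySeries(sample_id=sample, quantity=quantity,
                                days=days[:len(values)], values=tuple(values))

    def test_single_sample_decrease_value(self):
        series = [self._series("a", (100.0, 90.0, 67.4, 40.0)),
                  self._series("b", (100.0, 90.0, 67.4, 40.0))]
        s = summarize_cohort(series, "OCN")
        d7 = s.decreases.set_index("day").loc[7]
        assert d7["median_pct_decrease"] == pytest.approx(32.6)

    def test_constant_halving(self):
        series = [self._series(f"s{i}", (2 * v, v, v, v))
                  for i, v in enumerate(np.linspace(50, 500, 12))]
        s = summarize_cohort(series, "OCN")
        d3 = s.decreases.set_index("day").loc[3]
        assert d3["median_pct_decrease"] == pytest.approx(50.0)
        assert d3["iqr_low"] == pytest.approx(50.0)
        assert d3["iqr_high"] == pytest.approx(50.0)

    def test_quartile_interpolation_oracle(self):
        # planted decreases {10,20,30,40,50}% -> median 30, IQR [20, 40]
        series = [self._series(f"s{i}", (100.0, 100.0 - d), days=(0, 7))
                  for i, d in enumerate((10, 20, 30, 40, 50))]
        s = summarize_cohort(series, "OCN")
        d7 = s.decreases.set_index("day").loc[7]
        assert d7["median_pct_decrease"] == pytest.approx(30.0)
        assert d7["iqr_low"] == pytest.approx(20.0)
        assert d7["iqr_high"] == pytest.approx(40.0)

    def test_mean_sd_ci(self):
        from scipy import stats as sps
        vals = [100.0, 110.0, 120.0, 130.0]
        series = [self._series(f"s{i}", (v,), days=(0,)) for i, v in
                  enumerate(vals)]
        s = summarize_cohort(series, "OCN")
        row = s.per_day.set_index("day").loc[0]
        assert row["mean"] == pytest.approx(np.mean(vals))
        assert row["sd"] == pytest.approx(np.std(vals, ddof=1))
        half = sps.t.ppf(0.975, 3) * np.std(vals, ddof=1) / 2.0
        assert row["ci95_high"] - row["mean"] == pytest.approx(half)

    def test_zero_baseline_excluded_with_warning(self):
        series = [self._series("bad", (0.0, 10.0), days=(0, 7)),
                  self._series("a", (100.0, 50.0), days=(0, 7)),
                  self._series("b", (100.0, 60.0), days=(0, 7))]
        with pytest.warns(UserWarning):
            s = summarize_cohort(series, "OCN")
        assert s.decreases.set_index("day").loc[7, "n"] == 2

    def test_survival_fraction_recovered(self):
        # decreasing noise -> median percent decrease -> 100*(1-s)
        surv = 0.7
        series = [self._series(f"s{i}", (v, v * surv), days=(0, 7))
                  for i, v in enumerate(np.linspace(100, 200, 12))]
        s = summarize_cohort(series, "OCN")
        assert s.decreases.set_index("day").loc[7, "median_pct_decrease"] == \
            pytest.approx(100 * (1 - surv))

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            summarize_cohort([self._series("a", (1.0, 2.0), days=(0, 3))],
                             "OCN")


class TestCountsIO:
    def test_round_trip(self):
        recs = [
            TimePointCounts("a", 0, "Ki67", 200, 90, pi_percent=45.0),
            TimePointCounts("a", 0, "PLAP", 150, 120, tcn=120, stromal=30),
        ]
        back = counts_from_frame(counts_to_frame(recs))
        assert back[0].pi_percent == pytest.approx(45.0)
        assert back[1].tcn == 120 and back[1].stromal == 30

    def test_missing_column_rejected(self):
        df = counts_to_frame([]).drop(columns=["ocn"])
        with pytest.raises(ValidationError):
            counts_from_frame(df)

    def test_pi_bounds_validated(self):
        with pytest.raises(ValidationError):
            TimePointCounts("a", 0, "Ki67", 10, 5, pi_percent=150.0)
        with pytest.raises(ValidationError):
            TimePointCounts("a", 0, "Ki67", 10, 11)

    def test_extract_series(self):
        recs = [TimePointCounts("a", d, "PLAP", 100 - d, 80 - d,
                                tcn=80 - d, stromal=20)
                for d in (0, 3, 7, 10)]
        tc = assemble_timecourse(recs)[("a", "PLAP")]
        s = extract_series(tc, "TCN")
        assert s.days == (0, 3, 7, 10)
        assert s.values == (80.0, 77.0, 73.0, 70.0)
        s2 = extract_series(tc, "PI")
        assert s2.days == ()
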