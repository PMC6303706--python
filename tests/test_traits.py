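"""Scalar trait extraction, replicate handling, aggregation, capacity."""

import numpy as np
import pandas as pd
import pytest

from platemorph.geometry import convex_hull, nearest_neighbor_distances, polygon_area
from platemorph.io import PlateRecord, Population, StudyManifest
from platemorph.traits import (
    TraitRecord,
    aggregate_populations,
    average_replicates,
    compute_traits,
    replicate_concordance,
    tactile_pattern_capacity,
)


def _plate(sensilla, outline=None, **kw):
    if outline is None:
        outline = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 20.0], [0.0, 20.0]])
    sensilla = np.asarray(sensilla, dtype=float)
    defaults = dict(
        specimen_id="f1",
        species="E_anna",
        population_id="P1",
        side="right",
        outline=outline,
        sensilla=sensilla,
        replicate_id=1,
    )
    defaults.update(kw)
    return PlateRecord(**defaults)


class TestComputeTraits:
    def test_rectangle_closed_form(self):
        # 4 sensilla at corners of a 20x50 rectangle inside a 2000 um^2 plate
        rec = _plate(
            [[10, 0], [30, 0], [30, 50], [10, 50]],
            outline=np.array([[0.0, 0.0], [40.0, 0.0], [40.0, 50.0], [0.0, 50.0]]),
        )
        tr = compute_traits(rec)
        assert tr.sensilla_count == 4
        assert tr.plate_area == pytest.approx(2000.0)
        assert tr.sensilla_region_area == pytest.approx(1000.0)
        assert tr.coverage_proportion == pytest.approx(0.5)
        assert tr.density == pytest.approx(4.0)
        assert tr.mean_nnd == pytest.approx(20.0)
        assert tr.median_nnd == pytest.approx(20.0)

    def test_two_sensilla_degenerate_policy(self):
        tr = compute_traits(_plate([[10, 10], [40, 10]]))
        assert tr.sensilla_count == 2
        assert tr.mean_nnd == pytest.approx(30.0)
        assert np.isnan(tr.sensilla_region_area)
        assert np.isnan(tr.coverage_proportion)
        assert np.isnan(tr.density)

    def test_collinear_sensilla_degenerate_policy(self):
        tr = compute_traits(_plate([[10, 10], [20, 10], [30, 10], [40, 10]]))
        assert tr.sensilla_count == 4
        assert np.isfinite(tr.mean_nnd)
        assert np.isnan(tr.density)

    def test_broken_sockets_counted(self):
        rec = _plate([[10, 5], [30, 5], [20, 15]], broken=np.array([False, True, False]))
        tr = compute_traits(rec)
        assert tr.sensilla_count == 3
        assert tr.n_broken == 1

    def test_counts_only_plate_gets_count_only(self):
        tr = compute_traits(_plate([[10, 5], [30, 5], [20, 15]], counts_only=True))
        assert tr.sensilla_count == 3
        assert np.isnan(tr.plate_area)

    def test_left_plate_rejected(self):
        with pytest.raises(ValueError, match="mirror"):
            compute_traits(_plate([[10, 5], [30, 5], [20, 15]], side="left"))

    def test_random_plate_matches_geometry_oracles(self, rng):
        theta = np.sort(rng.uniform(0, 2 * np.pi, 60))
        outline = 80 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = rng.uniform(-30, 30, (40, 2))
        tr = compute_traits(_plate(pts, outline=outline))
        assert tr.plate_area == pytest.approx(polygon_area(outline))
        hull_area = polygon_area(convex_hull(pts))
        assert tr.sensilla_region_area == pytest.approx(hull_area)
        assert tr.coverage_proportion == pytest.approx(hull_area / polygon_area(outline))
        assert tr.density == pytest.approx(1000.0 * 40 / hull_area)
        assert tr.mean_nnd == pytest.approx(np.mean(nearest_neighbor_distances(pts)))

    def test_interior_point_raises_density_not_hull(self, rng):
        pts = np.array([[0.0, 0.0], [30.0, 0.0], [30.0, 30.0], [0.0, 30.0]]) + 10
        t1 = compute_traits(_plate(pts))
        t2 = compute_traits(_plate(np.vstack([pts, [[25.0, 25.0]]])))
        assert t2.sensilla_region_area == pytest.approx(t1.sensilla_region_area)
        assert t2.density > t1.density


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        t = compute_traits(_plate([[10, 5], [30, 5], [20, 15]]))
        avg = average_replicates(t, t)
        assert avg.sensilla_count == t.sensilla_count
        assert avg.density == pytest.approx(t.density)

    def test_counts_average_to_real(self):
        a = TraitRecord("f1", sensilla_count=48.0)
        b = TraitRecord("f1", sensilla_count=50.0)
        assert average_replicates(a, b).sensilla_count == pytest.approx(49.0)

    def test_missing_propagates(self):
        a = TraitRecord("f1", sensilla_count=10.0, density=2.0)
        b = TraitRecord("f1", sensilla_count=12.0, density=np.nan)
        out = average_replicates(a, b)
        assert out.sensilla_count == pytest.approx(11.0)
        assert np.isnan(out.density)

    def test_commutes(self):
        a = TraitRecord("f1", sensilla_count=10.0, mean_nnd=3.0)
        b = TraitRecord("f1", sensilla_count=14.0, mean_nnd=5.0)
        ab, ba = average_replicates(a, b), average_replicates(b, a)
        assert ab.sensilla_count == ba.sensilla_count
        assert ab.mean_nnd == ba.mean_nnd

    def test_specimen_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_replicates(TraitRecord("f1"), TraitRecord("f2"))


class TestReplicateConcordance:
    def test_identity_line(self):
        assert replicate_concordance([(1, 1), (2, 2), (3, 3)]) == pytest.approx(1.0)

    def test_perfect_linear(self):
        assert replicate_concordance([(1, 2), (2, 4), (3, 6)]) == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        v1 = rng.normal(50, 10, 50)
        v2 = v1 + rng.normal(0, 3, 50)
        r = replicate_concordance(np.column_stack([v1, v2]))
        cov = np.mean((v1 - v1.mean()) * (v2 - v2.mean()))
        oracle = cov / (v1.std() * v2.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            replicate_concordance([(1, 2), (1, 3), (1, 4)])


class TestAggregatePopulations:
    @pytest.fixture
    def manifest(self):
        return StudyManifest(
            [
                Population("P1", "a", "E_anna", 40, -110, "sympatric", 2015, 2),
                Population("P2", "b", "E_anna", 41, -111, "allopatric", 2015, 1),
            ]
        )

    def test_single_female_population(self, manifest):
        recs = [TraitRecord("f1", "E_anna", "P2", sensilla_count=33.0)]
        out = aggregate_populations(recs, manifest)
        assert out.loc[out.population_id == "P2", "sensilla_count"].item() == 33.0
        assert out.loc[out.population_id == "P2", "n_females"].item() == 1

    def test_mean_of_two_females(self, manifest):
        recs = [
            TraitRecord("f1", "E_anna", "P1", sensilla_count=20.0),
            TraitRecord("f2", "E_anna", "P1", sensilla_count=40.0),
        ]
        out = aggregate_populations(recs, manifest)
        assert out.loc[out.population_id == "P1", "sensilla_count"].item() == 30.0

    def test_patry_attached_and_min_n_filter(self, manifest):
        recs = [
            TraitRecord("f1", "E_anna", "P1", sensilla_count=20.0),
            TraitRecord("f2", "E_anna", "P1", sensilla_count=40.0),
            TraitRecord("f3", "E_anna", "P2", sensilla_count=10.0),
        ]
        out = aggregate_populations(recs, manifest)
        assert set(out.patry) == {"sympatric", "allopatric"}
        filtered = aggregate_populations(recs, manifest, min_n=2)
        assert list(filtered.population_id) == ["P1"]

    def test_unknown_population_rejected(self, manifest):
        with pytest.raises(KeyError):
            aggregate_populations([TraitRecord("fX", "E_anna", "P99")], manifest)

    def test_group_means_match_manual_groupby(self, full_study):
        """Grand means by patry class equal a direct pandas recomputation."""
        from platemorph.io import standardize_plate_orientation

        records = []
        for sid, recs in full_study.records_by_female().items():
            tr = [
                compute_traits(standardize_plate_orientation(r))
                for r in sorted(recs, key=lambda r: r.replicate_id)
            ]
            records.append(average_replicates(tr[0], tr[1]))
        table = aggregate_populations(records, full_study.manifest)
        raw = pd.DataFrame(
            {
                "population_id": [r.population_id for r in records],
                "count": [r.sensilla_count for r in records],
            }
        )
        manual = raw.groupby("population_id")["count"].mean()
        for _, row in table.iterrows():
            assert row["sensilla_count"] == pytest.approx(manual[row["population_id"]])


class TestTactilePatternCapacity:
    def test_reference_values(self):
        exact, sci = tactile_pattern_capacity(25)
        assert exact == 33_554_432
        assert sci == "3.4 x 10^7"
        exact26, sci26 = tactile_pattern_capacity(26)
        assert exact26 == 67_108_864
        assert sci26 == "6.7 x 10^7"

    def test_degenerate_and_ratio(self):
        assert tactile_pattern_capacity(0)[0] == 1
        for n in (1, 5, 30):
            assert (
                tactile_pattern_capacity(n + 1)[0] // tactile_pattern_capacity(n)[0] == 2
            )

    def test_multistate(self):
        assert tactile_pattern_capacity(3, states=4)[0] == 64

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tactile_pattern_capacity(-1)
        with pytest.raises(ValueError):
            tactile_pattern_capacity(5, states=1)
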