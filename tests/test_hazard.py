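import numpy as np
import pandas as pd
import pytest

from aquahazard.grids import GridSpec, ParameterGrid
from aquahazard.hazard import (
    HazardClass,
    classify_hazard,
    exceedance_fraction,
    exceedance_table,
    hazard_by_imputation,
    hazard_by_interpolation,
    hazard_index,
    population_exposure,
)
from aquahazard.standards import INDEX_PARAMETERS
from conftest import make_strip_districts


class TestExceedanceFraction:
    def test_count_over_total(self, who_by_param):
        frac = exceedance_fraction([300.0, 200.0, 100.0], who_by_param["Chloride"])
        assert frac == pytest.approx(1 / 3)

    def test_all_violating(self, who_by_param):
        assert exceedance_fraction([999.0, 999.0], who_by_param["Chloride"]) == 1.0

    def test_iron_reversed(self, who_by_param):
        assert exceedance_fraction([0.1, 0.5], who_by_param["Iron"]) == pytest.approx(0.5)

    def test_empty_rejected(self, who_by_param):
        with pytest.raises(ValueError):
            exceedance_fraction([], who_by_param["Chloride"])

    def test_missing_rejected(self, who_by_param):
        with pytest.raises(ValueError):
            exceedance_fraction([100.0, np.nan], who_by_param["Chloride"])


class TestHazardIndex:
    def test_all_ones(self):
        assert hazard_index({p: 1.0 for p in INDEX_PARAMETERS}, INDEX_PARAMETERS) == 1.0

    def test_single_hot_parameter(self):
        exc = {p: 0.0 for p in INDEX_PARAMETERS}
        exc["Chloride"] = 1.0
        assert hazard_index(exc, INDEX_PARAMETERS) == pytest.approx(0.1)

    def test_matches_direct_mean(self, rng):
        for _ in range(20):
            exc = {p: rng.random() for p in INDEX_PARAMETERS}
            expected = sum(exc.values()) / len(exc)
            assert hazard_index(exc, INDEX_PARAMETERS) == pytest.approx(expected, abs=1e-15)

    def test_missing_parameter_named(self):
        exc = {p: 0.5 for p in INDEX_PARAMETERS if p != "Fluoride"}
        with pytest.raises(ValueError, match="Fluoride"):
            hazard_index(exc, INDEX_PARAMETERS)


class TestClassifyHazard:
    @pytest.mark.parametrize(
        "index,label",
        [
            (0.09, HazardClass.LOW),  # the observed national minimum
            (0.37, HazardClass.VERY_HIGH),  # the observed national maximum
            (0.10, HazardClass.MODERATE),  # boundary joins the upper class
            (0.25, HazardClass.HIGH),
        ],
    )
    def test_default_bins(self, index, label):
        assert classify_hazard(index) == label

    def test_non_ascending_breaks_rejected(self):
        with pytest.raises(ValueError):
            classify_hazard(0.5, (0.3, 0.2, 0.1))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            classify_hazard(1.5)


def constant_grids(spec, levels, who_standards):
    return [
        ParameterGrid(e.parameter, spec, np.full(spec.shape, levels[e.parameter]))
        for e in who_standards
    ]


class TestInterpolatedPathway:
    def test_constant_grids_above_all_limits(self, who_standards):
        districts = make_strip_districts(3)
        spec = GridSpec(0, 0, 40, 60, 2.0)
        levels = {
            e.parameter: (e.limit / 2 if e.parameter == "Iron" else e.limit * 2)
            for e in who_standards
        }
        results = hazard_by_interpolation(
            constant_grids(spec, levels, who_standards), districts, who_standards
        )
        assert len(results) == 3
        for r in results:
            assert r.index == pytest.approx(1.0)
            assert r.hazard_class == HazardClass.VERY_HIGH

    def test_matches_exhaustive_enumeration(self, who_standards, rng):
        """On toy configurations the grid pathway equals direct counting
        of violations cell by cell, exactly."""
        spec = GridSpec(0, 0, 40, 60, 5.0)
        n_d = 4
        districts = make_strip_districts(n_d)
        grids = [
            ParameterGrid(e.parameter, spec,
                          rng.uniform(0, 2 * e.limit, spec.shape))
            for e in who_standards
        ]
        results = {r.district_id: r for r in
                   hazard_by_interpolation(grids, districts, who_standards)}
        gx, gy = spec.center_points()
        strip = np.floor(gx / (40.0 / n_d)).astype(int)
        for d_i in range(n_d):
            sel = strip == d_i
            fracs = []
            for g, e in zip(grids, who_standards):
                vals = g.values.ravel()[sel]
                viol = (vals < e.limit) if e.parameter == "Iron" else (vals > e.limit)
                fracs.append(viol.mean())
            did = f"D{d_i + 1:02d}"
            assert results[did].index == pytest.approx(np.mean(fracs), abs=1e-15)

    def test_district_relabeling_is_equivariant(self, who_standards, rng):
        spec = GridSpec(0, 0, 40, 60, 5.0)
        grids = [
            ParameterGrid(e.parameter, spec, rng.uniform(0, 2 * e.limit, spec.shape))
            for e in who_standards
        ]
        a = make_strip_districts(2)
        b = make_strip_districts(2)
        # swap the ids of the two strips
        b.districts[0].id, b.districts[1].id = "D02", "D01"
        b.__post_init__()
        ra = {r.district_id: r.index for r in hazard_by_interpolation(grids, a, who_standards)}
        rb = {r.district_id: r.index for r in hazard_by_interpolation(grids, b, who_standards)}
        assert ra["D01"] == rb["D02"]
        assert ra["D02"] == rb["D01"]


class TestImputedPathway:
    def _wells(self, who_standards, chloride=(300.0, 100.0)):
        rows = []
        for i, c in enumerate(chloride):
            row = {"well_id": f"W{i}", "district_id": "D01"}
            row.update({
                e.parameter: (e.limit * 2 if e.parameter == "Iron" else e.limit / 2)
                for e in who_standards
            })
            row["Chloride"] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def test_hand_arithmetic(self, who_standards):
        wells = self._wells(who_standards)
        districts = make_strip_districts(1)
        results = hazard_by_imputation(wells, districts, who_standards)
        (r,) = results
        assert r.exceedance["Chloride"] == pytest.approx(0.5)
        assert r.index == pytest.approx(0.05)
        assert r.flagged_small_n  # only 2 wells

    def test_adding_compliant_value_never_raises_fractions(self, who_standards):
        wells = self._wells(who_standards)
        more = self._wells(who_standards, chloride=(300.0, 100.0, 50.0))
        districts = make_strip_districts(1)
        (r1,) = hazard_by_imputation(wells, districts, who_standards)
        (r2,) = hazard_by_imputation(more, districts, who_standards)
        for p in r1.exceedance:
            assert r2.exceedance[p] <= r1.exceedance[p] + 1e-12

    def test_empty_table_rejected(self, who_standards):
        with pytest.raises(ValueError):
            hazard_by_imputation(pd.DataFrame(columns=["district_id"]),
                                 make_strip_districts(1), who_standards)


class TestExceedanceTable:
    def test_scaling_sorting_and_shape(self, who_standards, rng):
        spec = GridSpec(0, 0, 40, 60, 5.0)
        districts = make_strip_districts(4)
        grids = [
            ParameterGrid(e.parameter, spec, rng.uniform(0, 2 * e.limit, spec.shape))
            for e in who_standards
        ]
        results = hazard_by_interpolation(grids, districts, who_standards)
        table = exceedance_table(results)
        assert table.shape == (4, 10)
        assert table.to_numpy().min() >= 0 and table.to_numpy().max() <= 100
        by_id = {r.district_id: r for r in results}
        indices = [by_id[d].index for d in table.index]
        assert all(a >= b for a, b in zip(indices, indices[1:]))
        first = table.index[0]
        assert table.loc[first, "Chloride"] == pytest.approx(
            100 * by_id[first].exceedance["Chloride"]
        )


class TestExposure:
    def _results(self, who_standards, indices):
        spec = GridSpec(0, 0, 40, 60, 5.0)
        out = []
        districts = make_strip_districts(len(indices))
        from aquahazard.hazard import HazardResult, classify_hazard

        for i, idx in enumerate(indices):
            out.append(
                HazardResult(
                    district_id=f"D{i + 1:02d}", method="imputed",
                    exceedance={p: idx for p in INDEX_PARAMETERS}, index=idx,
                    hazard_class=classify_hazard(idx), n_units=10,
                )
            )
        return out, districts

    def test_national_percent_formula(self, who_standards):
        results, _ = self._results(who_standards, [0.3, 0.05])
        districts = make_strip_districts(2, populations=[3_600_000, 18_400_000])
        rows, summary = population_exposure(results, districts, exposure_threshold=0.2)
        assert summary["national_total"] == 22_000_000
        assert summary["national_exposed"] == 3_600_000
        assert round(summary["national_percent"], 1) == 16.4

    def test_threshold_one_exposes_nobody(self, who_standards):
        results, districts = self._results(who_standards, [0.5, 0.9])
        rows, summary = population_exposure(results, districts, exposure_threshold=1.0)
        assert summary["national_exposed"] == 0

    def test_threshold_zero_exposes_any_positive_index(self, who_standards):
        results, _ = self._results(who_standards, [0.01, 0.0])
        districts = make_strip_districts(2, populations=[100, 900])
        rows, summary = population_exposure(results, districts, exposure_threshold=0.0)
        assert summary["national_exposed"] == 100
        assert summary["national_percent"] == pytest.approx(10.0)

    def test_exposure_all_or_nothing_and_conserved(self, who_standards):
        results, districts = self._results(who_standards, [0.25, 0.15, 0.35])
        rows, summary = population_exposure(results, districts, exposure_threshold=0.2)
        for r in rows:
            assert r.exposed in (0, r.population)
        assert summary["national_exposed"] == sum(r.exposed for r in rows)
        assert summary["national_exposed"] <= summary["national_total"]

    def test_invalid_threshold_rejected(self, who_standards):
        results, districts = self._results(who_standards, [0.5])
        with pytest.raises(ValueError):
            population_exposure(results, districts, exposure_threshold=1.5)
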