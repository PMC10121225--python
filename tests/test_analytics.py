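"""Screen analytics: QC filters, normalization identities, hit calling."""

import numpy as np
import pandas as pd
import pytest

from synaptoscreen import (
    EffectMap,
    HitRules,
    PlateLayout,
    ScreenLayout,
    analyze_screen,
    call_hits,
    density,
    filter_fields,
    filter_wells_and_conditions,
    library_fractions,
    pattern_correct,
    percent_of_control,
    simulate_field_records,
    triplicate_screen_layout,
    zscore,
)
from synaptoscreen.analytics import AREA_COL, COUNT_COL, NUCLEI_COL, SYN_AREA_COL


def make_records(rows):
    return pd.DataFrame(rows, columns=["plate_id", "well", "field",
                                       AREA_COL, COUNT_COL, NUCLEI_COL, SYN_AREA_COL])


class TestDensity:
    def test_direct_formula(self):
        assert density(50, 1000) == 0.05

    def test_zero_count(self):
        assert density(0, 123.0) == 0

    def test_homogeneity(self):
        assert density(100, 2000) == density(50, 1000)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            density(5, 0)


class TestFilterFields:
    def test_band_matches_brute_force_loop(self):
        areas = [100.0] * 10 + [500.0, 2.0]
        rows = [("P1", "B02", i + 1, a, 10, 100, 40) for i, a in enumerate(areas)]
        records = make_records(rows)
        kept, rej = filter_fields(records)
        mu = np.mean(areas)
        sd = np.std(areas, ddof=1)
        want = [i for i, a in enumerate(areas) if mu - sd <= a <= mu + sd]
        assert list(kept["field"]) == [i + 1 for i in want]
        assert len(rej) == len(areas) - len(want)

    def test_identical_areas_all_kept(self):
        records = make_records([("P1", "B02", i, 50.0, 1, 1, 1) for i in range(6)])
        kept, rej = filter_fields(records)
        assert len(kept) == 6 and len(rej) == 0

    def test_boundary_field_kept_inclusive(self):
        # construct areas whose mean+sd hits one field exactly
        areas = [10.0, 20.0, 30.0]   # mu=20, sd=10 -> band [10, 30], all inside
        records = make_records([("P1", "B02", i, a, 1, 1, 1) for i, a in enumerate(areas)])
        kept, _ = filter_fields(records)
        assert len(kept) == 3

    def test_single_field_scope_warns_and_keeps(self):
        records = make_records([("P1", "B02", 1, 5.0, 1, 1, 1)])
        with pytest.warns(UserWarning):
            kept, _ = filter_fields(records)
        assert len(kept) == 1


def single_plate_layout(treat=None):
    return ScreenLayout(plates={"P1": PlateLayout(plate_id="P1",
                                                  treatments=treat or {})})


class TestWellConditionFilters:
    def test_well_with_four_fields_excluded(self):
        rows = [("P1", "B03", i, 100.0, 10, 50, 40) for i in range(1, 5)]
        rows += [("P1", "B04", i, 100.0, 10, 50, 40) for i in range(1, 6)]
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1), "B04": ("cmpB", 3.0, 1)})
        wells, _, rej = filter_wells_and_conditions(make_records(rows), layout)
        assert "B03" not in set(wells["well"])
        assert "B04" in set(wells["well"])
        assert "fewer_than_min_fields" in set(rej["reason"])

    def test_condition_with_two_of_three_wells_retained(self):
        layout = ScreenLayout(plates={
            pid: PlateLayout(plate_id=pid, treatments={"B03": ("cmpA", 3.0, r)})
            for r, pid in enumerate(["P1", "P2", "P3"], start=1)
        })
        rows = []
        for pid, nf in [("P1", 6), ("P2", 6), ("P3", 3)]:   # P3 well fails
            rows += [(pid, "B03", i, 100.0, 10, 50, 40) for i in range(1, nf + 1)]
        _, conditions, _ = filter_wells_and_conditions(make_records(rows), layout)
        row = conditions[conditions["condition"] == "cmpA"].iloc[0]
        assert row["n_wells_used"] == 2
        assert not row["qc_fail"]

    def test_condition_with_one_well_is_qc_fail(self):
        layout = ScreenLayout(plates={
            pid: PlateLayout(plate_id=pid, treatments={"B03": ("cmpA", 3.0, r)})
            for r, pid in enumerate(["P1", "P2", "P3"], start=1)
        })
        rows = [("P1", "B03", i, 100.0, 10, 50, 40) for i in range(1, 7)]
        _, conditions, _ = filter_wells_and_conditions(make_records(rows), layout)
        assert bool(conditions.iloc[0]["qc_fail"])


def well_table(layout, values, metric="density"):
    """Small helper: well table with a single metric of interest filled."""
    rows = []
    plate = layout.plates["P1"]
    for well, v in values.items():
        rows.append({
            "plate_id": "P1", "well": well, "batch_id": "b", "role": plate.role(well),
            "condition": plate.condition_of(well), "n_fields": 6,
            "map2_area": v, "count": v, "nuclei": v, "syn_area": v, "density": v,
            "qc_fail": False,
        })
    return pd.DataFrame(rows)


class TestNormalization:
    def test_percent_of_control_hand_oracle(self):
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1)})
        plate = layout.plates["P1"]
        ctrl = plate.control_wells()
        vals = {w: (8.0 if i % 2 == 0 else 12.0) for i, w in enumerate(ctrl)}
        vals["B03"] = 15.0
        wells = percent_of_control(well_table(layout, vals))
        row = wells[wells["well"] == "B03"].iloc[0]
        assert row["pct_density"] == pytest.approx(150.0)
        ctrl_row = wells[wells["well"] == ctrl[0]].iloc[0]
        assert ctrl_row["pct_density"] == pytest.approx(80.0)

    def test_control_mean_zero_flags_plate(self):
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1)})
        vals = {w: 0.0 for w in layout.plates["P1"].control_wells()}
        vals["B03"] = 5.0
        wells = percent_of_control(well_table(layout, vals))
        assert wells["qc_fail"].all()

    def test_zscore_hand_oracle_and_control_mean_zero(self):
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1)})
        ctrl = layout.plates["P1"].control_wells()
        rng = np.random.default_rng(1)
        vals = {w: float(v) for w, v in zip(ctrl, rng.normal(20, 10, len(ctrl)))}
        vals["B03"] = 40.0
        wells = zscore(well_table(layout, vals))
        cvals = np.array([vals[w] for w in ctrl])
        want = (40.0 - cvals.mean()) / cvals.std(ddof=1)
        row = wells[wells["well"] == "B03"].iloc[0]
        assert row["z_density"] == pytest.approx(want)
        assert wells[wells["role"] == "control"]["z_density"].mean() == \
            pytest.approx(0.0, abs=1e-9)

    def test_zscore_affine_invariance(self):
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1)})
        ctrl = layout.plates["P1"].control_wells()
        rng = np.random.default_rng(2)
        vals = {w: float(v) for w, v in zip(ctrl, rng.normal(50, 5, len(ctrl)))}
        vals["B03"] = 70.0
        z1 = zscore(well_table(layout, vals))
        vals2 = {w: 3.0 * v + 11.0 for w, v in vals.items()}
        z2 = zscore(well_table(layout, vals2))
        pd.testing.assert_series_equal(z1["z_density"], z2["z_density"])

    def test_constant_controls_sd_zero_qc_fail(self):
        layout = single_plate_layout({"B03": ("cmpA", 3.0, 1)})
        vals = {w: 10.0 for w in layout.plates["P1"].control_wells()}
        vals["B03"] = 12.0
        wells = zscore(well_table(layout, vals))
        assert wells["qc_fail"].all()


class TestPatternCorrect:
    def _screen(self, n_assay=2, gradient=0.0, spike=None):
        compounds = [f"c{i:02d}" for i in range(48)]
        layout = triplicate_screen_layout(compounds, n_replicates=n_assay, n_sentinels=2)
        rng = np.random.default_rng(3)
        rows = []
        for pid, plate in layout.plates.items():
            for well in plate.inner_wells():
                row_idx = "BCDEFG".index(well[0])
                v = 100.0 + rng.normal(0, 0.5) + gradient * row_idx
                if spike and (pid, well) == spike:
                    v += 50.0
                rows.append({
                    "plate_id": pid, "well": well, "batch_id": "b",
                    "role": plate.role(well), "condition": plate.condition_of(well),
                    "n_fields": 6, "map2_area": v, "count": v, "nuclei": v,
                    "syn_area": v, "density": v, "qc_fail": False,
                })
        return layout, pd.DataFrame(rows)

    def test_pattern_free_plate_nearly_unchanged(self):
        layout, wells = self._screen(gradient=0.0)
        out = pattern_correct(wells, layout)
        sd = wells["density"].std()
        assert np.abs(out["density"] - wells["density"]).max() < 0.05 * max(sd, 1.0) + 0.5

    def test_planted_row_gradient_removed(self):
        layout, wells = self._screen(gradient=2.0)   # +10 over 6 rows (~10%)
        out = pattern_correct(wells, layout)

        def slope(df):
            rows_idx = df["well"].str[0].map(lambda r: "BCDEFG".index(r))
            return np.polyfit(rows_idx, df["density"], 1)[0]

        s_before = slope(wells[wells["plate_id"] == "P01"])
        s_after = slope(out[out["plate_id"] == "P01"])
        assert abs(s_after) <= 0.2 * abs(s_before)

    def test_single_well_spike_preserved(self):
        spike_key = ("P01", "B05")
        layout, wells = self._screen(gradient=0.0, spike=spike_key)
        out = pattern_correct(wells, layout)
        before = wells.set_index(["plate_id", "well"]).loc[spike_key, "density"]
        after = out.set_index(["plate_id", "well"]).loc[spike_key, "density"]
        others = wells[wells["plate_id"] == "P01"]["density"].median()
        assert after - others > 0.9 * (before - others)


class TestHitCalling:
    @pytest.mark.parametrize("zd,zm,want", [
        (-3.5, -2.4, "toxic"),
        (0.0, 0.0, "inactive"),
        (-3.5, 0.0, "inactive"),     # second conjunct fails
        (-2.9, -2.5, "inactive"),    # first conjunct fails
        (2.5, 0.0, "enhancer_candidate"),
        (2.5, -2.5, "inactive"),     # neurite loss blocks enhancer call
    ])
    def test_rule_conjunctions(self, zd, zm, want):
        df = pd.DataFrame([{"condition": "x", "qc_fail": False,
                            "z_density": zd, "z_map2": zm}])
        assert call_hits(df).iloc[0]["hit_class"] == want

    def test_qc_fail_propagates(self):
        df = pd.DataFrame([{"condition": "x", "qc_fail": True,
                            "z_density": -5.0, "z_map2": -5.0}])
        assert call_hits(df).iloc[0]["hit_class"] == "qc_fail"

    def test_library_fraction_arithmetic(self):
        classes = ["qc_fail"] * 13 + ["toxic"] * 7 + ["inactive"] * 356
        df = pd.DataFrame({"hit_class": classes})
        frac = library_fractions(df, 376).set_index("hit_class")
        assert frac.loc["qc_fail", "percent"] == 3.46
        assert frac.loc["toxic", "percent"] == 1.86
        assert frac.loc["enhancer_candidate", "percent"] == 0.00


class TestScreenEndToEnd:
    def test_null_screen_mostly_within_two_z(self):
        """All-vehicle-effect screen over 8+ plates: >= 90% of conditions have
        |z_density| <= 2."""
        compounds = [f"c{i:03d}" for i in range(96)]
        layout = triplicate_screen_layout(compounds, n_replicates=3, n_sentinels=2)
        assert len(layout.plates) >= 8
        records = simulate_field_records(list(layout.plates.values()), seed=11)
        result = analyze_screen(records, layout)
        cond = result["conditions"]
        ok = cond[~cond["qc_fail"]]
        frac = (ok["z_density"].abs() <= 2).mean()
        assert frac >= 0.90

    def test_planted_enhancers_recovered_without_toxic_calls(self):
        """2x density enhancers are called enhancer_candidate in >= 90% of
        conditions, with zero toxic misclassifications."""
        compounds = [f"c{i:03d}" for i in range(48)]
        layout = triplicate_screen_layout(compounds, n_replicates=3, n_sentinels=1)
        enhancer = {"c005", "c017", "c029", "c041"}
        effects = {}
        for pid, plate in layout.plates.items():
            mult = {w: 2.0 for w, (c, _, _) in plate.treatments.items() if c in enhancer}
            effects[pid] = EffectMap(density_multipliers=mult)
        records = simulate_field_records(
            list(layout.plates.values()), effects_by_plate=effects, seed=7
        )
        result = analyze_screen(records, layout)
        cond = result["conditions"].set_index("condition")
        called = [cond.loc[c, "hit_class"] for c in sorted(enhancer)]
        assert sum(h == "enhancer_candidate" for h in called) >= 0.9 * len(enhancer)
        assert (cond["hit_class"] == "toxic").sum() == 0

    def test_filters_match_single_pass_brute_force(self):
        """Field-then-well filtering equals one brute-force pass applying both
        rules."""
        compounds = [f"c{i:02d}" for i in range(10)]
        layout = triplicate_screen_layout(compounds, n_replicates=3, n_sentinels=0)
        rng = np.random.default_rng(4)
        records = simulate_field_records(list(layout.plates.values()),
                                         fields_per_well=6, seed=4)
        # plant some outlier fields
        out_idx = rng.choice(len(records), 40, replace=False)
        records.loc[records.index[out_idx], AREA_COL] *= rng.choice(
            [0.1, 3.0], size=40
        )
        kept, _ = filter_fields(records)
        wells, _, _ = filter_wells_and_conditions(kept, layout)
        # brute force
        mu = records[AREA_COL].mean()
        sd = records[AREA_COL].std(ddof=1)
        surv = records[(records[AREA_COL] >= mu - sd) & (records[AREA_COL] <= mu + sd)]
        brute_wells = {
            k for k, g in surv.groupby(["plate_id", "well"]) if len(g) >= 5
        }
        assert set(map(tuple, wells[["plate_id", "well"]].values)) == brute_wells
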