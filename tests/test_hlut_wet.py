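import numpy as np
import pytest

from pction.hlut_wet import (DEFAULT_GROUPING, DEFAULT_HLUT, Hlut,
                             TissueGrouping, delta_wet, hu_to_wepl,
                             me_per_tissue_group, range_error_map,
                             shift_experiment, trace_wet, wepl_volume)
from pction.volio import Volume


class TestHuToWepl:
    def test_control_points_reproduced(self):
        for hu, w in zip(DEFAULT_HLUT.hu, DEFAULT_HLUT.wepl):
            assert hu_to_wepl(hu) == pytest.approx(w)

    def test_midpoint_linearity(self):
        hlut = Hlut(hu=(0.0, 100.0), wepl=(1.0, 1.1))
        assert hu_to_wepl(50.0, hlut) == pytest.approx(1.05)

    def test_extrapolation_is_floored_at_zero(self):
        hlut = Hlut(hu=(0.0, 100.0), wepl=(0.5, 1.0))
        assert hu_to_wepl(-500.0, hlut) == 0.0
        # above range extrapolates linearly
        assert hu_to_wepl(200.0, hlut) == pytest.approx(1.5)

    def test_monotone_for_nondecreasing_control_points(self):
        grid = np.linspace(-2000, 4000, 2001)
        w = hu_to_wepl(grid, DEFAULT_HLUT)
        assert (np.diff(w) >= -1e-12).all()

    def test_rejects_unsorted_or_negative(self):
        with pytest.raises(ValueError):
            Hlut(hu=(0.0, 0.0), wepl=(1.0, 1.1))
        with pytest.raises(ValueError):
            Hlut(hu=(0.0, 10.0), wepl=(-0.1, 1.0))

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "hlut.csv"
        DEFAULT_HLUT.to_csv(path)
        back = Hlut.from_csv(path)
        assert back.hu == DEFAULT_HLUT.hu and back.wepl == DEFAULT_HLUT.wepl


class TestDeltaWet:
    def test_zero_me_gives_zero_everywhere(self):
        rep = delta_wet({"soft_tissue": 0.0})
        row = rep.table.iloc[0]
        for d in (1, 5, 10):
            assert row[f"dwet_{d}cm_mm"] == 0.0

    def test_linear_in_thickness(self):
        rep = delta_wet({"bone": -223.1}, thicknesses_cm=(1.0, 5.0, 10.0))
        row = rep.table.iloc[0]
        assert row["dwet_10cm_mm"] == pytest.approx(10 * row["dwet_1cm_mm"])
        assert row["dwet_5cm_mm"] == pytest.approx(5 * row["dwet_1cm_mm"])

    def test_closed_form_on_linear_segment(self):
        # HLUT slope s per HU over a segment; ME of m HU at 1 cm -> s*m*10 mm
        hlut = Hlut(hu=(-1000.0, 1000.0), wepl=(0.0, 2.0))  # slope 0.001/HU
        grouping = TissueGrouping({"soft_tissue": (-100.0, 100.0)})
        rep = delta_wet({"soft_tissue": 50.0}, hlut=hlut, thicknesses_cm=(1.0,),
                        grouping=grouping)
        assert rep.table.iloc[0]["dwet_1cm_mm"] == pytest.approx(0.001 * 50 * 10)

    def test_se_modes(self):
        kw = dict(error_sd_per_voxel=0.02, voxel_size_mm=0.5,
                  thicknesses_cm=(1.0, 4.0))
        sqrt_rep = delta_wet({"soft_tissue": 0.0}, se_mode="sqrt", **kw)
        lin_rep = delta_wet({"soft_tissue": 0.0}, se_mode="linear", **kw)
        # sqrt mode: sd * voxel * sqrt(d / voxel); quadruple depth doubles SE
        r = sqrt_rep.table.iloc[0]
        assert r["se_4cm_mm"] == pytest.approx(2 * r["se_1cm_mm"])
        assert r["se_1cm_mm"] == pytest.approx(0.02 * 0.5 * np.sqrt(10 / 0.5))
        assert lin_rep.table.iloc[0]["se_4cm_mm"] == pytest.approx(0.02 * 40)

    def test_rejects_nonpositive_thickness(self):
        with pytest.raises(ValueError):
            delta_wet({"bone": 1.0}, thicknesses_cm=(0.0,))

    def test_grouping_must_tile_scale(self):
        with pytest.raises(ValueError):
            TissueGrouping({"a": (0.0, 10.0), "b": (20.0, 30.0)})


class TestTraceWet:
    def test_uniform_water_ten_cm(self):
        vol = Volume(np.ones((100, 3, 3)), role="wepl")
        res = trace_wet(vol, (0, 1, 1), axis=0, stop_depth_mm=100.0)
        assert res["wet_mm"][-1] == pytest.approx(100.0)

    def test_doubling_wepl_halves_crossing_depth(self):
        base = Volume(np.full((80, 1, 1), 1.0), role="wepl")
        double = Volume(np.full((80, 1, 1), 2.0), role="wepl")
        t1 = trace_wet(base, (0, 0, 0), axis=0, wet_target_mm=40.0)
        t2 = trace_wet(double, (0, 0, 0), axis=0, wet_target_mm=40.0)
        assert t1["crossed"] and t2["crossed"]
        assert t2["crossing_depth_mm"] == pytest.approx(t1["crossing_depth_mm"] / 2)

    def test_two_slab_phantom_matches_hand_sum(self):
        vals = np.concatenate([np.full(30, 1.0), np.full(30, 1.65)])
        vol = Volume(vals.reshape(60, 1, 1), spacing=(0.5, 1, 1), role="wepl")
        res = trace_wet(vol, (0, 0, 0), axis=0)
        # 15 mm of water-equivalent 1.0 then 15 mm at 1.65
        assert res["wet_mm"][-1] == pytest.approx(30 * 0.5 * 1.0 + 30 * 0.5 * 1.65)

    def test_additive_over_consecutive_segments(self, rng):
        vals = rng.uniform(0.5, 2.0, size=(40, 1, 1))
        vol = Volume(vals, role="wepl")
        full = trace_wet(vol, (0, 0, 0), axis=0)["wet_mm"][-1]
        first = trace_wet(vol, (0, 0, 0), axis=0)["wet_mm"][19]
        second = trace_wet(vol, (20, 0, 0), axis=0)["wet_mm"][-1]
        assert full == pytest.approx(first + second)

    def test_non_crossing_reported(self):
        vol = Volume(np.full((10, 1, 1), 0.1), role="wepl")
        res = trace_wet(vol, (0, 0, 0), axis=0, wet_target_mm=100.0)
        assert res["crossed"] is False


def make_ptv(shape, sl):
    vals = np.zeros(shape, dtype=np.uint8)
    vals[sl] = 1
    return Volume(vals, role="mask")


class TestRangeErrorMap:
    def test_identical_cts_give_zero(self, rng):
        ct = Volume(rng.uniform(-500, 1000, size=(20, 8, 8)), role="ct")
        ptv = make_ptv((20, 8, 8), (slice(10, 14), slice(2, 6), slice(2, 6)))
        res = range_error_map(ct.with_values(ct.values, "pct"), ct,
                              DEFAULT_HLUT, 0, ptv)
        assert res["max_abs_mm"] == pytest.approx(0.0)

    def test_upstream_slab_closed_form(self):
        # +100 HU over a 10-voxel (10 mm) slab upstream of the PTV on a
        # linear HLUT of slope 0.001/HU -> every ray shifts by 1 mm
        hlut = Hlut(hu=(-1000.0, 1000.0), wepl=(0.0, 2.0))
        rct = Volume(np.zeros((30, 6, 6)), role="ct")
        pv = np.zeros((30, 6, 6))
        pv[2:12] += 100.0
        pct = Volume(pv, role="pct")
        ptv = make_ptv((30, 6, 6), (slice(18, 24), slice(1, 5), slice(1, 5)))
        res = range_error_map(pct, rct, hlut, 0, ptv)
        assert res["mean_mm"] == pytest.approx(0.001 * 100 * 10)
        assert res["max_abs_mm"] == pytest.approx(res["mean_abs_mm"])

    def test_invariant_to_changes_distal_of_ptv(self, rng):
        rv = rng.uniform(-200, 200, size=(30, 5, 5))
        rct = Volume(rv, role="ct")
        pv = rv.copy()
        pv[28:] += 500.0  # strictly distal of the PTV along +x
        pct = Volume(pv, role="pct")
        ptv = make_ptv((30, 5, 5), (slice(10, 20), slice(1, 4), slice(1, 4)))
        res = range_error_map(pct, rct, DEFAULT_HLUT, 0, ptv)
        assert res["max_abs_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_ptv_raises(self, rng):
        ct = Volume(rng.normal(size=(10, 4, 4)), role="ct")
        with pytest.raises(ValueError, match="empty"):
            range_error_map(ct.with_values(ct.values, "pct"), ct, DEFAULT_HLUT,
                            0, make_ptv((10, 4, 4), (slice(0, 0),)))


class TestShiftExperiment:
    def test_zero_shift_identical_cts_all_zero(self, rng):
        rv = rng.uniform(-500, 500, size=(24, 10, 10))
        rct = Volume(rv, role="ct")
        pct = Volume(rv.copy(), role="pct")
        ptv = make_ptv((24, 10, 10), (slice(12, 16), slice(3, 7), slice(3, 7)))
        res = shift_experiment(pct, rct, DEFAULT_HLUT, ptv, (0, 0, 0), axis=0)
        assert res["adapted"]["mean_abs_mm"] == pytest.approx(0.0)
        assert res["non_adapted"]["mean_abs_mm"] == pytest.approx(0.0)

    def test_zero_shift_decomposition_isolates_classifier_error(self, rng):
        rv = rng.uniform(-500, 500, size=(24, 10, 10))
        rct = Volume(rv, role="ct")
        pct = Volume(rv + rng.normal(0, 50, size=rv.shape), role="pct")
        ptv = make_ptv((24, 10, 10), (slice(12, 16), slice(3, 7), slice(3, 7)))
        res = shift_experiment(pct, rct, DEFAULT_HLUT, ptv, (0, 0, 0), axis=0)
        plain = range_error_map(pct, rct, DEFAULT_HLUT, 0, ptv)
        assert res["non_adapted"]["mean_abs_mm"] == pytest.approx(0.0)
        assert res["adapted"]["mean_abs_mm"] == pytest.approx(plain["mean_abs_mm"])

    def test_integer_shift_moves_target(self, rng):
        rv = rng.uniform(-500, 500, size=(24, 10, 10))
        rct = Volume(rv, role="ct")
        pct = Volume(rv.copy(), role="pct")
        ptv = make_ptv((24, 10, 10), (slice(12, 16), slice(3, 7), slice(3, 7)))
        res = shift_experiment(pct, rct, DEFAULT_HLUT, ptv, (2.0, 2.0, 0.0), axis=2)
        # beam along z: a 2 mm in-plane shift changes which rays hit but the
        # adapted plan still has zero error (pct == rct)
        assert res["adapted"]["mean_abs_mm"] == pytest.approx(0.0)
        assert res["non_adapted"]["n_rays"] > 0

    def test_shift_off_grid_raises(self, rng):
        rct = Volume(rng.normal(size=(10, 10, 10)), role="ct")
        ptv = make_ptv((10, 10, 10), (slice(4, 6), slice(4, 6), slice(4, 6)))
        with pytest.raises(ValueError):
            shift_experiment(rct.with_values(rct.values, "pct"), rct,
                             DEFAULT_HLUT, ptv, (50.0, 0.0, 0.0), axis=0)


def test_me_per_tissue_group_assigns_by_reference(rng):
    rv = np.array([-900.0, -400.0, 0.0, 300.0, 1500.0]).reshape(5, 1, 1)
    pv = rv + 10.0
    rct = Volume(rv, role="ct")
    pct = Volume(pv, role="pct")
    mask = Volume(np.ones((5, 1, 1), np.uint8), role="mask")
    tab = me_per_tissue_group(pct, rct, mask)
    assert set(tab["tissue"]) == {"air", "partial_volume", "soft_tissue",
                                  "soft_bone", "bone"}
    assert np.allclose(tab["me_hu"], 10.0)


def test_wepl_volume_matches_scalar_conversion(rng):
    ct = Volume(rng.uniform(-1000, 2000, size=(4, 4, 4)), role="ct")
    w = wepl_volume(ct)
    assert w.values[2, 2, 2] == pytest.approx(hu_to_wepl(ct.values[2, 2, 2]))
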