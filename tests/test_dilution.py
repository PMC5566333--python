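import numpy as np
import pytest

from swathbench.design import build_design
from swathbench.dilution import (
    CurvePoint,
    ResponseCurve,
    averaged_response_curve,
    build_response_curves,
    determine_lloq,
    dynamic_range,
    fit_response_curve,
    percent_detected,
    step_fold_changes,
)
from swathbench.simulate import SiteProfile, quiet_profile, simulate_study


def _curve(points, peptide="p", site="s", ms="MS2"):
    return ResponseCurve(
        peptide_id=peptide,
        site_id=site,
        ms_level=ms,
        points=tuple(CurvePoint(nominal_fmol=x, areas=tuple(a), sn=tuple(sn)) for x, a, sn in points),
    )


class TestFit:
    def test_exact_line_recovered(self):
        x = np.array([1, 3, 9, 27.0])
        fit = fit_response_curve(x, 7.0 * x)
        assert fit.slope == pytest.approx(7.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 1.0

    def test_two_points_always_perfect(self):
        fit = fit_response_curve([1.0, 3.0], [5.0, 2.0])
        assert fit.r_squared == 1.0

    def test_weighting_down_weights_top_point(self):
        x = np.array([1, 3, 9, 27, 81.0])
        y = 2.0 * x
        y[-1] *= 0.5  # saturated top
        fw = fit_response_curve(x, y, "1/x")
        fu = fit_response_curve(x, y, "none")
        assert abs(fw.slope - 2.0) < abs(fu.slope - 2.0)

    def test_saturated_top_point_removal_improves_r2(self):
        d = build_design(n_sites=1)
        profile = quiet_profile("site01", saturation_level=5000.0)
        ds = simulate_study(d, {"site01": profile}, seed=0, n_proteins=3, absent_fraction=0.0)
        curve = [c for c in build_response_curves(ds.sis, "MS2") if c.peptide_id == "SIS_E1"][0]
        x = [p.nominal_fmol for p in curve.points]
        y = [p.mean_area for p in curve.points]
        full = fit_response_curve(x, y)
        trimmed = fit_response_curve(x[:-1], y[:-1])
        assert trimmed.r_squared > full.r_squared

    def test_single_concentration_raises(self):
        with pytest.raises(ValueError):
            fit_response_curve([2.0, 2.0], [1.0, 1.1])


class TestLLOQ:
    def test_clean_curve_lloq_is_lowest_point(self):
        pts = [(x, [10 * x] * 3, [100.0] * 3) for x in (1, 3, 9, 27, 81.0)]
        res = determine_lloq(_curve(pts))
        assert res.lloq == 1.0
        assert res.dynamic_range_orders == pytest.approx(np.log10(81))

    def test_noisy_lowest_point_dropped(self):
        low = (1.0, [6.0, 10.0, 16.0], [100.0] * 3)  # replicate CV ~ 47%
        rest = [(x, [10 * x] * 3, [100.0] * 3) for x in (3, 9, 27, 81.0)]
        res = determine_lloq(_curve([low] + rest))
        assert res.lloq == 3.0

    def test_low_sn_point_dropped(self):
        pts = [(1.0, [10.0] * 3, [5.0] * 3)] + [(x, [10 * x] * 3, [100.0] * 3) for x in (3, 9, 27.0)]
        res = determine_lloq(_curve(pts))
        assert res.lloq == 3.0

    def test_all_points_failing_is_undetermined(self):
        pts = [(x, [10 * x] * 3, [1.0] * 3) for x in (1, 3, 9.0)]
        res = determine_lloq(_curve(pts))
        assert res.lloq is None
        assert res.dynamic_range_orders is None

    def test_point_insertion_order_irrelevant(self):
        pts = [(x, [10 * x] * 3, [100.0] * 3) for x in (9, 1, 81, 3, 27.0)]
        res = determine_lloq(_curve(pts))
        assert res.lloq == 1.0

    def test_added_noise_never_lowers_lloq(self):
        d = build_design(n_sites=1)
        lloqs = {}
        for cv in (0.02, 0.30):
            profile = SiteProfile("site01", cv_intraday=cv, detection_floor=0.1)
            ds = simulate_study(d, {"site01": profile}, seed=42, n_proteins=3, absent_fraction=0.0)
            res = [determine_lloq(c) for c in build_response_curves(ds.sis, "MS2")]
            lloqs[cv] = np.nanmedian([r.lloq if r.lloq else np.nan for r in res])
        assert lloqs[0.30] >= lloqs[0.02]


class TestDynamicRange:
    def test_four_orders(self):
        assert dynamic_range(1.0, 10_000.0) == pytest.approx(4.0)

    def test_lloq_at_max_is_zero(self):
        assert dynamic_range(50.0, 50.0) == 0.0

    def test_identity_with_log_lloq(self):
        assert dynamic_range(0.3, 81.0) + np.log10(0.3) == pytest.approx(np.log10(81.0))

    def test_undetermined_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range(None, 100.0)


class TestAveragedCurve:
    def test_identical_peptides_average_to_themselves(self):
        d = build_design(n_sites=1)
        curves = [
            _curve([(x, [5 * x], [99.0]) for x in (1, 3, 9.0)], peptide=p, site="site01")
            for p in d.groups[0].peptide_ids
        ]
        avg = averaged_response_curve(curves, d)
        assert (avg["n_peptides"] == 6).all()
        assert np.allclose(avg["mean_area"], 5 * avg["nominal_fmol"])

    def test_permutation_invariant(self):
        d = build_design(n_sites=1)
        curves = [
            _curve([(x, [k * x], [99.0]) for x in (1, 3, 9.0)], peptide=p, site="site01")
            for k, p in enumerate(d.groups[0].peptide_ids, start=1)
        ]
        a = averaged_response_curve(curves, d)
        b = averaged_response_curve(curves[::-1], d)
        assert a.equals(b)

    def test_global_offset_sites_parallel_then_overlaid_after_normalization(self):
        d = build_design(n_sites=2)
        profiles = {
            "site01": quiet_profile("site01", response_offset=1.0),
            "site02": quiet_profile("site02", response_offset=4.0),
        }
        ds = simulate_study(d, profiles, seed=0, n_proteins=3, absent_fraction=0.0)
        avg = averaged_response_curve(build_response_curves(ds.sis, "MS2"), d)
        piv = avg.pivot_table(index=["group_id", "nominal_fmol"], columns="site_id", values="mean_area")
        ratio = piv["site02"] / piv["site01"]
        assert np.allclose(ratio, 4.0)  # parallel on log scale
        normed = ds.sis.copy()
        normed.loc[normed["site_id"] == "site02", "area"] /= 4.0
        avg_n = averaged_response_curve(build_response_curves(normed, "MS2"), d)
        piv_n = avg_n.pivot_table(index=["group_id", "nominal_fmol"], columns="site_id", values="mean_area")
        assert np.allclose(piv_n["site02"], piv_n["site01"])


class TestFoldChanges:
    def test_noiseless_design_ratios(self):
        pts = [(x, [2.0 * x], [99.0]) for x in (1, 3, 9, 27.0)]
        fc = step_fold_changes([_curve(pts)])
        assert fc["fold_3x"] == pytest.approx(3.0)
        assert fc["fold_9x"] == pytest.approx(9.0)
        assert fc["fold_27x"] == pytest.approx(27.0)

    def test_two_point_ratio(self):
        fc = step_fold_changes([_curve([(1.0, [10.0], [99.0]), (3.0, [30.0], [99.0])])])
        assert fc["fold_3x"] == pytest.approx(3.0)

    def test_saturation_compresses_mean_adjacent_ratio(self):
        d = build_design(n_sites=1)
        profile = quiet_profile("site01", saturation_level=1000.0)
        ds = simulate_study(d, {"site01": profile}, seed=0, n_proteins=3, absent_fraction=0.0)
        fc = step_fold_changes(build_response_curves(ds.sis, "MS2"))
        assert fc["fold_3x"] < 3.0


class TestPercentDetected:
    def test_all_lloq_at_minimum_gives_full_detection(self):
        d = build_design(n_sites=1)
        results = []
        for p in d.peptide_ids:
            g = d.group_of_peptide(p)
            noms = sorted(
                d.concentrations().loc[lambda t: t["group_id"] == g.group_id, "nominal_fmol"]
            )
            pts = [(x, [x] * 3, [99.0] * 3) for x in noms]
            results.append(determine_lloq(_curve(pts, peptide=p, site="site01")))
        pct = percent_detected(results, d)
        site = pct[pct["site_id"] == "site01"]
        top = site.loc[site["nominal_fmol"] == site["nominal_fmol"].max(), "percent_detected"]
        assert (top == 100.0).all()

    def test_step_arithmetic_with_lloq_at_start_amounts(self):
        d = build_design(n_sites=1)
        results = []
        for p in d.peptide_ids:
            g = d.group_of_peptide(p)
            noms = sorted(
                d.concentrations().loc[lambda t: t["group_id"] == g.group_id, "nominal_fmol"]
            )
            # only the top two points of each group have adequate S/N
            pts = [(x, [x] * 3, [99.0 if x >= g.start_fmol / 3 else 1.0] * 3) for x in noms]
            results.append(determine_lloq(_curve(pts, peptide=p, site="site01")))
        pct = percent_detected(results, d)
        site = pct[pct["site_id"] == "site01"].set_index("nominal_fmol")["percent_detected"]
        # LLOQ lands one step below each group's start: 20-point steps per decade
        assert site[1.0] == pytest.approx(20.0)
        assert site[10.0] == pytest.approx(40.0)
        assert site[10_000.0] == pytest.approx(100.0)
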