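import itertools

import numpy as np
import pytest

from decyto import (
    ChannelGeometry,
    boxplot_summary,
    confinement_gate,
    density_contour,
    dose_response_cmin,
    manifold_qc,
    mann_whitney_one_tailed,
    pressure_response_fit,
    significance_tier,
)
from decyto.stats import SOFTENING, STIFFENING
from decyto.validation import population_from_di


def pop_from_diameters(diameters, sample_id="s"):
    from decyto.summarize import CellRecord, SamplePopulation

    dh = ChannelGeometry().hydraulic_diameter_um
    recs = [
        CellRecord(cell_id=i, sample_id=sample_id, dc_um=d, confinement=d / dh, di_max=0.1)
        for i, d in enumerate(diameters)
    ]
    return SamplePopulation(sample_id=sample_id, records=recs)


class TestConfinementGate:
    def test_gate_bounds_for_default_duct(self):
        # D_h = 18.857 um -> gate admits D_c in (16.029, 17.914) um
        dh = ChannelGeometry().hydraulic_diameter_um
        lo, hi = 0.85 * dh, 0.95 * dh
        assert lo == pytest.approx(16.03, abs=0.005)
        assert hi == pytest.approx(17.91, abs=0.005)

    def test_boundary_straddling_table(self):
        dh = ChannelGeometry().hydraulic_diameter_um
        diameters = [15.9, 16.02, 0.85 * dh, 16.05, 17.0, 17.90, 0.95 * dh, 17.92, 19.0]
        pop = pop_from_diameters(diameters)
        gated = confinement_gate(pop, 0.85, 0.95)
        kept = sorted(r.dc_um for r in gated.accepted)
        # strictly inside only: records exactly at 0.85/0.95 D_h are excluded
        assert kept == [16.05, 17.0, 17.90]

    def test_exact_boundary_excluded(self):
        dh = ChannelGeometry().hydraulic_diameter_um
        gated = confinement_gate(pop_from_diameters([0.85 * dh]))
        assert gated.n == 0

    def test_all_below_gate_empty(self):
        dh = ChannelGeometry().hydraulic_diameter_um
        gated = confinement_gate(pop_from_diameters([0.5 * dh] * 10))
        assert gated.n == 0

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        pop = pop_from_diameters(rng.uniform(14, 19, 200))
        once = confinement_gate(pop)
        twice = confinement_gate(once)
        assert [r.cell_id for r in twice.accepted] == [r.cell_id for r in once.accepted]

    def test_gate_recorded_in_metadata(self):
        gated = confinement_gate(pop_from_diameters([17.0]), 0.85, 0.95)
        assert gated.metadata["confinement_gate"] == (0.85, 0.95)


def exact_mw_enumeration_p(a, b):
    """Brute-force one-tailed p: P(U_a <= u_obs) over all labelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        if r <= u_obs:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        # oracle: enumeration over all C(6,3)=20 labelings gives p = 1/20
        res = mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.05, abs=1e-12)
        assert res.n1 == res.n2 == 3

    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        res = mann_whitney_one_tailed(x, x.copy(), alternative="greater")
        assert res.tier == "ns"
        assert 0.4 < res.p_value <= 1.0

    def test_u_statistic_within_bounds(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(size=20)
        res = mann_whitney_one_tailed(a, b, "greater")
        assert 0 <= res.u_statistic <= res.n1 * res.n2

    def test_asymptotic_agrees_with_enumeration_at_n10(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.5, 1.0, 10)
        from scipy.stats import mannwhitneyu

        p_asym = mannwhitneyu(a, b, alternative="less", method="asymptotic").pvalue
        p_enum = exact_mw_enumeration_p(a, b)
        assert p_asym == pytest.approx(p_enum, abs=0.01)
        # and the packaged test picks the exact path for this size
        res = mann_whitney_one_tailed(a, b, "less")
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_power_at_planted_median_shift(self):
        # log-normal samples, 1.5x median shift, n=150: detected almost always
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            a = np.exp(np.log(0.10) + 0.3 * rng.standard_normal(150))
            b = np.exp(np.log(0.15) + 0.3 * rng.standard_normal(150))
            res = mann_whitney_one_tailed(b, a, "greater")
            hits += res.tier != "ns"
        assert hits >= 95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0], "greater")


class TestSignificanceTiers:
    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.5, "ns"),
            (0.011, "ns"),
            (0.01, "ns"),
            (0.009, "*"),
            (0.0009, "**"),
            (0.00009, "***"),
            (0.000009, "****"),
        ],
    )
    def test_ladder(self, p, tier):
        assert significance_tier(p) == tier


def lognormal_pop(median, n, rng, sample_id="s"):
    return population_from_di(
        np.exp(np.log(median) + 0.3 * rng.standard_normal(n)), sample_id
    )


class TestDoseResponse:
    def test_softening_detected_at_planted_cmin(self):
        rng = np.random.default_rng(17)
        control = lognormal_pop(0.10, 150, rng, "ctrl")
        doses = [
            (0.1, lognormal_pop(0.10, 150, rng, "d1")),
            (1.0, lognormal_pop(0.15, 150, rng, "d2")),
            (10.0, lognormal_pop(0.15, 150, rng, "d3")),
            (50.0, lognormal_pop(0.15, 150, rng, "d4")),
        ]
        res = dose_response_cmin(control, doses)
        assert res.cmin == 1.0
        assert res.direction == SOFTENING
        assert res.pattern == "No change"

    def test_null_yields_no_cmin(self):
        rng = np.random.default_rng(23)
        control = lognormal_pop(0.10, 150, rng, "ctrl")
        doses = [(d, lognormal_pop(0.10, 150, rng, f"d{d}")) for d in (0.1, 1, 10, 50)]
        res = dose_response_cmin(control, doses)
        assert res.cmin is None
        assert res.direction == "No change"
        assert res.pattern == "No change"

    def test_stiffening_at_lowest_dose_only(self):
        rng = np.random.default_rng(29)
        control = lognormal_pop(0.10, 200, rng, "ctrl")
        doses = [
            (0.1, lognormal_pop(0.06, 200, rng, "d1")),
            (1.0, lognormal_pop(0.06, 200, rng, "d2")),
            (10.0, lognormal_pop(0.06, 200, rng, "d3")),
        ]
        res = dose_response_cmin(control, doses)
        assert res.cmin == 0.1
        assert res.direction == STIFFENING
        assert res.pattern == "No change"

    def test_monotone_increase_pattern(self):
        rng = np.random.default_rng(31)
        control = lognormal_pop(0.08, 300, rng, "ctrl")
        doses = [
            (0.1, lognormal_pop(0.12, 300, rng, "d1")),
            (1.0, lognormal_pop(0.18, 300, rng, "d2")),
            (10.0, lognormal_pop(0.27, 300, rng, "d3")),
        ]
        res = dose_response_cmin(control, doses)
        assert res.cmin == 0.1
        assert res.pattern == "Monotonic increase"

    def test_non_monotonic_pattern(self):
        rng = np.random.default_rng(37)
        control = lognormal_pop(0.08, 300, rng, "ctrl")
        doses = [
            (0.1, lognormal_pop(0.16, 300, rng, "d1")),
            (1.0, lognormal_pop(0.08, 300, rng, "d2")),
        ]
        res = dose_response_cmin(control, doses)
        assert res.cmin == 0.1
        assert res.direction == SOFTENING
        assert res.pattern == "Non-monotonic"

    def test_requires_at_least_one_dose(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            dose_response_cmin(lognormal_pop(0.1, 50, rng), [])


class TestPressureResponse:
    def test_collinear_points_r2_one(self):
        pts = [(p, 0.002 * p + 0.01) for p in (3, 5, 7, 10, 15, 25, 30)]
        fit = pressure_response_fit(pts)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.002)

    def test_constant_di_zero_slope(self):
        fit = pressure_response_fit([(3, 0.05), (10, 0.05), (30, 0.05)])
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_noisy_planted_slope_within_two_se(self):
        rng = np.random.default_rng(41)
        pressures = np.array([3, 5, 7, 10, 15, 25, 30], dtype=float)
        slope_true, icpt, sigma = 0.004, 0.02, 0.005
        ok = 0
        for _ in range(50):
            di = slope_true * pressures + icpt + rng.normal(0, sigma, len(pressures))
            fit = pressure_response_fit(list(zip(pressures, di)))
            sxx = ((pressures - pressures.mean()) ** 2).sum()
            resid = di - (fit.slope * pressures + fit.intercept)
            se = np.sqrt((resid**2).sum() / (len(pressures) - 2) / sxx)
            ok += abs(fit.slope - slope_true) <= 2 * se
        assert ok >= 40  # ~95% coverage, wide margin

    def test_fewer_than_three_pressures_rejected(self):
        with pytest.raises(ValueError):
            pressure_response_fit([(3, 0.1), (5, 0.2)])


class TestDensityContour:
    def test_single_gaussian_one_closed_contour_containing_mean(self):
        rng = np.random.default_rng(43)
        pts = rng.multivariate_normal([0.9, 0.1], [[1e-3, 0], [0, 4e-4]], 2000)
        contours = density_contour(pts, 0.5)
        assert len(contours) == 1
        from matplotlib.path import Path

        assert Path(contours[0]).contains_point((0.9, 0.1))

    def test_two_separated_clusters_two_contours(self):
        rng = np.random.default_rng(47)
        a = rng.normal([0, 0], 0.05, (500, 2))
        b = rng.normal([5, 0], 0.05, (500, 2))
        contours = density_contour(np.vstack([a, b]), 0.5)
        assert len(contours) == 2

    def test_area_matches_analytic_half_peak_ellipse(self):
        # for N(0, diag(s1^2, s2^2)) the 50%-of-peak contour encloses
        # pi * s1 * s2 * 2 ln 2; KDE bandwidth inflates it by ~(1+h^2)
        rng = np.random.default_rng(53)
        s1, s2 = 0.04, 0.02
        pts = rng.multivariate_normal([0, 0], np.diag([s1**2, s2**2]), 5000)
        (c,) = density_contour(pts, 0.5)
        x, y = c[:, 0], c[:, 1]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area == pytest.approx(np.pi * s1 * s2 * 2 * np.log(2), rel=0.10)

    def test_enclosed_region_shrinks_with_level(self):
        rng = np.random.default_rng(59)
        pts = rng.normal(0, 1, (1000, 2))
        areas = []
        for frac in (0.3, 0.5, 0.7):
            cs = density_contour(pts, frac)
            x, y = cs[0][:, 0], cs[0][:, 1]
            areas.append(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
        assert areas[0] > areas[1] > areas[2]

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError):
            density_contour(np.tile([1.0, 2.0], (100, 1)), 0.5)


class TestManifoldQC:
    def test_identical_channels_pass(self):
        v = {f"ch{i}": [0.3] * 25 for i in range(10)}
        report = manifold_qc(v)
        assert report.passed
        assert report.max_rel_deviation <= 1e-12

    def test_five_percent_outlier_fails_at_3pct(self):
        v = {f"ch{i}": [0.3] * 25 for i in range(9)}
        v["ch9"] = [0.3 * 1.05] * 25
        report = manifold_qc(v, 0.03)
        assert not report.passed

    def test_measurement_noise_passes_mostly(self):
        rng = np.random.default_rng(61)
        hits = 0
        for _ in range(40):
            v = {f"ch{i}": 0.3 * (1 + 0.01 * rng.standard_normal(30)) for i in range(10)}
            hits += manifold_qc(v).passed
        assert hits >= 38

    def test_empty_channel_reported_not_crash(self):
        v = {"a": [0.3] * 25, "b": []}
        report = manifold_qc(v)
        empty = [c for c in report.channels if c.channel == "b"][0]
        assert not empty.coverage_ok
        assert not report.passed

    def test_under_twenty_beads_warns(self):
        with pytest.warns(UserWarning, match="<20"):
            manifold_qc({"a": [0.3] * 5, "b": [0.3] * 25})


class TestBoxplotSummary:
    def test_interpolated_quantiles_one_to_nine(self):
        with pytest.warns(UserWarning):
            s = boxplot_summary(np.arange(1.0, 10.0))
        assert s["median"] == 5
        assert s["q25"] == 3
        assert s["q75"] == 7
        assert s["n"] == 9

    def test_single_value_collapses(self):
        with pytest.warns(UserWarning):
            s = boxplot_summary([0.07])
        assert {s["median"], s["q25"], s["q75"], s["p10"], s["p90"]} == {0.07}

    def test_no_warning_at_publication_n(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            boxplot_summary(np.linspace(0, 1, 150))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])
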