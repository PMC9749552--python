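"""DPV peak extraction, replicate statistics, calibration, LOD, surface area."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from probesense import (
    CalibrationSeries,
    RedoxConstants,
    ScanRateSeries,
    Voltammogram,
    VoltammetryError,
    effective_surface_area,
    fit_calibration,
    limit_of_detection,
    linear_range,
    peak_current,
    randles_sevcik_current,
    read_calibration,
    read_voltammogram,
    replicate_stats,
    rsd_from_summary,
    selectivity_summary,
)

CONSTANTS = RedoxConstants(n=1, D=6.7e-6, C=2e-6)


def gaussian_trace(amplitude, center=-0.25, width=0.04, slope=0.0, intercept=0.0,
                   n=200):
    E = np.linspace(-0.5, 0.0, n)
    I = intercept + slope * E + amplitude * np.exp(-0.5 * ((E - center) / width) ** 2)
    return Voltammogram(E, I)


class TestVoltammogram:
    def test_validation(self):
        with pytest.raises(VoltammetryError, match=">= 10"):
            Voltammogram(np.arange(5.0), np.arange(5.0))
        p = np.arange(12.0)
        p[6] = p[5]  # duplicate potential
        with pytest.raises(VoltammetryError, match="monotone"):
            Voltammogram(p, np.arange(12.0))

    def test_descending_sweep_accepted(self):
        v = Voltammogram(np.linspace(0, -0.5, 20), np.zeros(20))
        assert v.metadata["direction"] == "descending"

    @pytest.mark.parametrize("sep,suffix", [(",", ".csv"), ("\t", ".tsv")])
    @pytest.mark.parametrize("header", [True, False])
    def test_read_table_variants(self, tmp_path, sep, suffix, header):
        E = np.linspace(-0.5, 0.0, 50)
        I = np.sin(E)
        lines = [f"{e}{sep}{i}" for e, i in zip(E, I)]
        if header:
            lines.insert(0, f"potential_V{sep}current_uA")
        p = tmp_path / f"trace{suffix}"
        p.write_text("\n".join(lines) + "\n")
        v = read_voltammogram(p)
        assert len(v) == 50
        np.testing.assert_allclose(v.currents, I)

    def test_non_numeric_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("potential_V,current_uA\n0.1,1.0\nxx,2.0\n" + "0.3,3.0\n" * 10)
        with pytest.raises(VoltammetryError):
            read_voltammogram(p)


class TestPeakCurrent:
    def test_recovers_gaussian_amplitude_on_linear_baseline(self):
        """Chord-mode peak height recovers a 5 uA Gaussian planted on a
        sloped linear baseline to within discretisation error."""
        v = gaussian_trace(5.0, slope=-3.0, intercept=2.0, n=400)
        res = peak_current(v, (-0.45, -0.05))
        assert res.ip == pytest.approx(5.0, abs=0.05)
        assert res.ep == pytest.approx(-0.25, abs=0.01)
        assert not res.no_peak

    @pytest.mark.parametrize("amp", [1.0, 2.0, 4.0, 8.0])
    def test_linearity_in_amplitude(self, amp):
        v = gaussian_trace(amp, n=400)
        res = peak_current(v, (-0.45, -0.05))
        assert res.ip == pytest.approx(amp, rel=0.01)

    def test_flat_zero_trace_flags_no_peak(self):
        v = Voltammogram(np.linspace(-0.5, 0, 50), np.zeros(50))
        res = peak_current(v, (-0.45, -0.05), baseline="flat")
        assert res.ip == 0.0 and res.no_peak

    def test_window_validation(self):
        v = gaussian_trace(1.0)
        with pytest.raises(VoltammetryError, match="outside sweep"):
            peak_current(v, (-0.9, -0.6))
        with pytest.raises(VoltammetryError, match="points inside"):
            peak_current(v, (-0.251, -0.249))

    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_chord_absorbs_any_linear_baseline(self, slope, intercept):
        """Adding an arbitrary linear function of potential to the trace
        leaves the chord-mode peak height unchanged."""
        base = gaussian_trace(3.0, n=150)
        tilted = Voltammogram(
            base.potentials, base.currents + intercept + slope * base.potentials
        )
        r0 = peak_current(base, (-0.45, -0.05))
        r1 = peak_current(tilted, (-0.45, -0.05))
        assert r1.ip == pytest.approx(r0.ip, rel=1e-9, abs=1e-9)


class TestReplicateStats:
    def test_published_replicate_mean(self, replicate_currents):
        st_ = replicate_stats(replicate_currents)
        assert st_.mean == pytest.approx(19.935)
        assert st_.rounded()[0] == 19.9  # 3 significant figures
        assert st_.mean == pytest.approx(19.94, abs=0.0051)  # printed precision

    def test_rsd_identity_on_published_summary(self):
        """RSD = sigma*100/mu applied to the published summary values
        (mu=19.94, sigma=0.468) gives 2.34% at the printed precision."""
        assert rsd_from_summary(19.94, 0.468) == pytest.approx(2.34, abs=0.01)

    def test_ddof_choices(self, replicate_currents):
        s1 = replicate_stats(replicate_currents, ddof=1)
        s0 = replicate_stats(replicate_currents, ddof=0)
        assert s1.sd == pytest.approx(0.4903, abs=1e-4)
        assert s0.sd == pytest.approx(0.4246, abs=1e-4)

    def test_degenerate_and_invalid(self):
        s = replicate_stats([5.0, 5.0, 5.0])
        assert s.sd == 0.0 and s.rsd == 0.0
        with pytest.raises(VoltammetryError):
            replicate_stats([1.0])
        with pytest.raises(VoltammetryError):
            replicate_stats([-2.0, -1.0])

    @given(st.floats(0.1, 100), st.lists(st.floats(1, 50), min_size=2, max_size=8))
    def test_rsd_scale_invariance(self, factor, values):
        """RSD is invariant under uniform scaling of all replicate values."""
        a = replicate_stats(values)
        b = replicate_stats([v * factor for v in values])
        assert b.rsd == pytest.approx(a.rsd, rel=1e-9, abs=1e-9)


class TestCalibrationFit:
    def test_noiseless_recovery_to_machine_precision(self):
        concs = np.logspace(-11, -6, 6)
        series = CalibrationSeries(concs, 2.0 * np.log10(concs) + 30.0)
        fit = fit_calibration(series)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(30.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_seeded_noise_recovery(self):
        rng = np.random.default_rng(21)
        concs = np.logspace(-11, -6, 6)
        series = CalibrationSeries(
            concs, 2.0 * np.log10(concs) + 30.0 + rng.normal(0, 0.01, 6)
        )
        assert fit_calibration(series).slope == pytest.approx(2.0, rel=0.01)

    def test_three_collinear_points(self):
        concs = np.array([1e-9, 1e-8, 1e-7])
        series = CalibrationSeries(concs, np.array([1.0, 2.0, 3.0]))
        assert fit_calibration(series).r_squared == pytest.approx(1.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(VoltammetryError):
            fit_calibration(CalibrationSeries([1e-9, 1e-8], [1.0, 2.0]))
        with pytest.raises(VoltammetryError):
            CalibrationSeries([1e-9, 1e-9, 1e-8], [1.0, 2.0, 3.0])

    def test_read_calibration(self, tmp_path):
        p = tmp_path / "cal.csv"
        p.write_text(
            "concentration_M,peak_current_uA\n"
            + "".join(f"{c},{i}\n" for c, i in zip([1e-9, 1e-8, 1e-7], [1, 2, 3]))
        )
        s = read_calibration(p)
        assert len(s) == 3


def brute_force_linear_range(series, r2_min, min_points):
    """Independent enumeration of all contiguous runs (<=12-point series)."""
    s = series.sorted()
    x, y = np.log10(s.concentrations), s.peak_currents
    best = None
    for i, j in itertools.combinations(range(len(x) + 1), 2):
        if j - i < min_points:
            continue
        r2 = sps.linregress(x[i:j], y[i:j]).rvalue ** 2
        if r2 >= r2_min and (best is None or (j - i, r2) > best[0]):
            best = ((j - i, r2), (i, j))
    return best


class TestLinearRange:
    def piecewise_series(self):
        """Floor below 1e-11, linear 1e-11..5e-6, plateau above."""
        concs = sorted([10.0 ** e for e in range(-15, -5)] + [5e-6, 1e-5])
        def amp(c):
            if c < 1e-11:
                return 1.0
            if c > 5e-6:
                return 44.0
            return 80.0 + 6.0 * np.log10(c)
        return CalibrationSeries(np.array(concs), np.array([amp(c) for c in concs]))

    def test_recovers_planted_decades(self):
        """On a floor/linear/plateau sweep spanning 1e-15..1e-5 M the
        returned range is exactly the planted linear span 1e-11..5e-6 M."""
        lr = linear_range(self.piecewise_series())
        assert lr.found
        assert lr.low == pytest.approx(1e-11)
        assert lr.high == pytest.approx(5e-6)

    def test_fully_linear_series_returns_whole_span(self):
        concs = np.logspace(-11, -6, 8)
        s = CalibrationSeries(concs, 6.0 * np.log10(concs) + 80.0)
        lr = linear_range(s)
        assert lr.found and len(lr.indices) == 8
        assert (lr.low, lr.high) == (pytest.approx(1e-11), pytest.approx(1e-6))

    def test_no_qualifying_run(self):
        rng = np.random.default_rng(4)
        concs = np.logspace(-11, -6, 6)
        s = CalibrationSeries(concs, rng.normal(10, 5, 6))
        lr = linear_range(s, r2_min=0.9999)
        assert not lr.found

    def test_agrees_with_brute_force_enumeration(self):
        """The returned run matches exhaustive enumeration of contiguous
        runs on noisy <=12-point series, including the boundary rule that
        no admissible extension is refused."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = rng.integers(4, 13)
            concs = np.sort(10.0 ** rng.uniform(-14, -4, n))
            while len(np.unique(concs)) < n:
                concs = np.sort(10.0 ** rng.uniform(-14, -4, n))
            y = 5.0 * np.log10(concs) + 70 + rng.normal(0, rng.uniform(0.01, 2.0), n)
            s = CalibrationSeries(concs, y)
            got = linear_range(s, r2_min=0.98, min_points=4)
            exp = brute_force_linear_range(s, 0.98, 4)
            if exp is None:
                assert not got.found
            else:
                (_, (i, j)) = exp
                assert got.found
                assert got.indices == tuple(range(i, j))


class TestLimitOfDetection:
    def test_monotone_in_blank_sigma(self):
        lods = [
            limit_of_detection(6.0, s, reference_concentration=1e-13)
            for s in (0.05, 0.1, 0.2, 0.4)
        ]
        assert all(a < b for a, b in zip(lods, lods[1:]))

    def test_rule_ordering(self):
        lo3 = limit_of_detection(6.0, 0.1, rule="three_sigma",
                                 reference_concentration=1e-13)
        lo33 = limit_of_detection(6.0, 0.1, rule="three_point_three_sigma",
                                  reference_concentration=1e-13)
        assert lo3 < lo33

    def test_intercept_anchoring_matches_reference(self):
        # fitted line I = 80 + 6*log10(C); blank mean 10 -> C_ref = 10^(-70/6)
        via_intercept = limit_of_detection(6.0, 0.1, intercept=80.0, blank_mean=10.0)
        cref = 10.0 ** ((10.0 - 80.0) / 6.0)
        via_cref = limit_of_detection(6.0, 0.1, reference_concentration=cref)
        assert via_intercept == pytest.approx(via_cref, rel=1e-12)

    def test_planted_crossing_recovered(self):
        """A seeded noisy calibration built so the true 3.3-sigma crossing
        sits at 1e-12 M yields a recovered LOD within 20%."""
        from probesense.synthetic import AmplitudeModel, DpvSpec, generate_calibration

        k, sigma_true, b_true = 3.3, 0.05, 6.0
        target_lod = 1e-12
        cref = target_lod / 10.0 ** (k * sigma_true / b_true)
        spec = DpvSpec(noise_sigma=sigma_true, seed=8)
        concs = [10.0 ** e for e in range(-11, -5)]
        series, truth = generate_calibration(spec, concs, replicates=2)
        fit = fit_calibration(series)
        lod = limit_of_detection(fit.slope, sigma_true,
                                 reference_concentration=cref)
        assert lod == pytest.approx(target_lod, rel=0.2)

    def test_validation(self):
        with pytest.raises(VoltammetryError):
            limit_of_detection(0.0, 0.1, reference_concentration=1e-12)
        with pytest.raises(VoltammetryError):
            limit_of_detection(6.0, -0.1, reference_concentration=1e-12)
        with pytest.raises(VoltammetryError):
            limit_of_detection(6.0, 0.1)  # no anchor


class TestSurfaceArea:
    @pytest.mark.parametrize("area", [0.05, 0.11, 0.204, 0.5])
    def test_forward_inverse_identity(self, area):
        """Noiseless Randles-Sevcik forward simulation followed by the
        area estimator returns the generating area (bare- and
        modified-electrode magnitudes included)."""
        v = np.linspace(0.04, 0.15, 12)
        series = ScanRateSeries(v, randles_sevcik_current(area, CONSTANTS, v),
                                CONSTANTS)
        assert effective_surface_area(series) == pytest.approx(area, rel=1e-9)

    def test_linearity_in_current(self):
        v = np.linspace(0.04, 0.15, 12)
        ip = randles_sevcik_current(0.11, CONSTANTS, v)
        a1 = effective_surface_area(ScanRateSeries(v, ip, CONSTANTS))
        a2 = effective_surface_area(ScanRateSeries(v, 2 * ip, CONSTANTS))
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_inverse_proportionality_to_concentration(self):
        v = np.linspace(0.04, 0.15, 12)
        ip = randles_sevcik_current(0.11, CONSTANTS, v)
        halved = RedoxConstants(CONSTANTS.n, CONSTANTS.D, CONSTANTS.C / 2)
        a = effective_surface_area(ScanRateSeries(v, ip, CONSTANTS))
        a_halved = effective_surface_area(ScanRateSeries(v, ip, halved))
        assert a_halved == pytest.approx(2 * a, rel=1e-9)

    def test_non_diffusive_response_rejected(self):
        v = np.linspace(0.04, 0.15, 12)
        series = ScanRateSeries(v, np.linspace(5, 1, 12), CONSTANTS)
        with pytest.raises(VoltammetryError, match="non-diffusive"):
            effective_surface_area(series)


# Published peak-current panel (uA) from the selectivity experiment: the
# fully complementary target vs mismatch, control and nontarget oligos.
SELECTIVITY_PANEL = [
    ("RC", 20.06), ("1MN", 6.42), ("3MN", 4.11), ("NC", 3.69),
    ("CW", 4.61), ("BF", 4.81), ("HS", 4.69), ("DK", 4.31), ("probe", 3.61),
]


class TestSelectivitySummary:
    def test_published_panel(self):
        summ = selectivity_summary(SELECTIVITY_PANEL, "RC")
        assert summ.discriminates
        assert summ.max_nontarget == pytest.approx(6.42)
        # ratios verified by direct division
        for label, ip in SELECTIVITY_PANEL:
            row = summ.table[summ.table["label"] == label].iloc[0]
            assert row["ratio_to_target"] == pytest.approx(ip / 20.06)

    def test_nontarget_equal_to_target_fails_discrimination(self):
        summ = selectivity_summary([("t", 5.0), ("n", 5.0)], "t")
        assert not summ.discriminates

    def test_missing_target_label(self):
        with pytest.raises(VoltammetryError):
            selectivity_summary([("a", 1.0), ("b", 2.0)], "zz")
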