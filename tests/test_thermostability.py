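import numpy as np
import pytest

from switchscope.errors import (
    AggregationError,
    ConfigurationError,
    InputError,
    NoTransitionError,
)
from switchscope.synthetic import MeltGenSpec, generate_melting_curves
from switchscope.thermostability import (
    MeltingCurve,
    MeltingFit,
    ThermalCategory,
    TmSummary,
    boltzmann,
    classify_thermal_phenotype,
    fit_melting_curve,
    read_curves_csv,
    summarize_tm,
    write_curves_csv,
)

from oracles import grid_search_tm

TEMPS = np.arange(25.0, 90.0, 1.0)


def _fit(v50=50.0, slope=2.0, top=1.0, bottom=0.0, sse=0.0, converged=True):
    return MeltingFit(v50, slope, top, bottom, sse, converged)


class TestFitMeltingCurve:
    def test_noiseless_selfconsistency_6sf(self):
        y = boltzmann(TEMPS, 50.0, 2.0, 1.0, 0.0)
        fit = fit_melting_curve(MeltingCurve(TEMPS, y))
        assert fit.converged
        assert fit.v50 == pytest.approx(50.0, abs=5e-6)
        assert fit.slope == pytest.approx(2.0, rel=1e-6)
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)

    def test_fix_normalization_exact(self):
        y = boltzmann(TEMPS, 61.5, 3.0)
        fit = fit_melting_curve(MeltingCurve(TEMPS, y), fix_normalization=True)
        assert fit.v50 == pytest.approx(61.5, abs=1e-6)
        assert (fit.top, fit.bottom) == (1.0, 0.0)

    def test_mirrored_curve_rejected(self):
        # temperature-mirrored sigmoid runs unfolded -> folded: slope < 0
        y = boltzmann(TEMPS, 50.0, 2.0)[::-1]
        fit = fit_melting_curve(MeltingCurve(TEMPS, y))
        assert not fit.converged

    def test_too_few_points(self):
        with pytest.raises(InputError):
            MeltingCurve(np.arange(5.0), np.arange(5.0))

    def test_flat_signal_no_transition(self):
        rng = np.random.default_rng(0)
        y = 0.5 + rng.normal(0, 0.01, size=TEMPS.shape)
        with pytest.raises(NoTransitionError):
            fit_melting_curve(MeltingCurve(TEMPS, y))

    def test_decreasing_temperature_rejected(self):
        with pytest.raises(InputError):
            MeltingCurve(TEMPS[::-1], boltzmann(TEMPS, 50.0, 2.0))

    def test_tm_invariant_under_affine_signal_rescale(self):
        y = boltzmann(TEMPS, 57.3, 2.5)
        fit_raw = fit_melting_curve(MeltingCurve(TEMPS, y))
        fit_scaled = fit_melting_curve(MeltingCurve(TEMPS, -3200.0 * y + 150.0))
        assert fit_scaled.v50 == pytest.approx(fit_raw.v50, abs=1e-6)

    def test_synthetic_recovery_vs_grid_oracle(self):
        # derived oracle: exhaustive grid search over (v50, slope)
        spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02,
                           replicates=3, seed=11)
        for curve in generate_melting_curves(spec):
            fit = fit_melting_curve(curve)
            assert fit.converged
            assert abs(fit.v50 - 55.0) < 0.5
            v50_oracle, _ = grid_search_tm(curve.temperature, curve.signal)
            assert fit.v50 == pytest.approx(v50_oracle, abs=0.02)


class TestSummarizeTm:
    def test_identical_replicates(self):
        s = summarize_tm([_fit(60.0)] * 3)
        assert (s.tm_mean, s.tm_sd, s.n_replicates) == (60.0, 0.0, 3)

    def test_hand_arithmetic(self):
        s = summarize_tm([_fit(59.0), _fit(60.0), _fit(61.0)])
        assert s.tm_mean == pytest.approx(60.0)
        assert s.tm_sd == pytest.approx(1.0)

    def test_single_replicate_sd_absent(self):
        s = summarize_tm([_fit(60.0)])
        assert s.tm_sd is None and s.n_replicates == 1

    def test_nonconverged_excluded(self):
        s = summarize_tm([_fit(60.0), _fit(99.0, converged=False)])
        assert s.tm_mean == 60.0 and s.n_replicates == 1

    def test_no_converged_fits(self):
        with pytest.raises(AggregationError):
            summarize_tm([_fit(60.0, converged=False)])

    def test_replicate_sd_within_monte_carlo_envelope(self):
        # simulation oracle: distribution of the 3-replicate sample SD
        spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02,
                           replicates=3, seed=101)
        observed = summarize_tm(
            [fit_melting_curve(c) for c in generate_melting_curves(spec)]).tm_sd
        sds = []
        for seed in range(200):
            s = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02,
                            replicates=3, seed=5000 + seed)
            sds.append(summarize_tm(
                [fit_melting_curve(c) for c in generate_melting_curves(s)]).tm_sd)
        lo, hi = np.quantile(sds, [0.005, 0.995])
        assert lo <= observed <= hi


class TestClassification:
    WT_GDP = TmSummary(56.0, 0.5, 3)
    WT_GTP = TmSummary(65.0, 0.5, 3)

    def test_responsive(self):
        p = classify_thermal_phenotype(TmSummary(56.0, 0.5, 3), TmSummary(65.0, 0.5, 3),
                                       self.WT_GDP, self.WT_GTP, threshold=3.0)
        assert p.category is ThermalCategory.NUCLEOTIDE_RESPONSIVE
        assert p.delta_tm == pytest.approx(9.0)

    def test_coincident_with_gdp_reference(self):
        p = classify_thermal_phenotype(self.WT_GDP, self.WT_GDP,
                                       self.WT_GDP, self.WT_GTP, threshold=3.0)
        assert p.category is ThermalCategory.GDP_LIKE

    def test_gtp_like(self):
        near_gtp = TmSummary(64.5, 0.5, 3)
        p = classify_thermal_phenotype(near_gtp, near_gtp,
                                       self.WT_GDP, self.WT_GTP, threshold=3.0)
        assert p.category is ThermalCategory.GTP_LIKE

    def test_midpoint_tie_indeterminate(self):
        mid = TmSummary(60.5, 0.5, 3)
        p = classify_thermal_phenotype(mid, mid, self.WT_GDP, self.WT_GTP,
                                       threshold=0.1)
        assert p.category is ThermalCategory.INDETERMINATE

    def test_inverted_references_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_thermal_phenotype(self.WT_GDP, self.WT_GTP,
                                       self.WT_GTP, self.WT_GDP)

    def test_monotone_in_delta_tm(self):
        # once responsive, larger delta_tm can never leave the category
        responsive = False
        for delta in np.linspace(0.0, 15.0, 61):
            p = classify_thermal_phenotype(
                TmSummary(56.0, 0.5, 3), TmSummary(56.0 + delta, 0.5, 3),
                self.WT_GDP, self.WT_GTP, threshold=3.0)
            if responsive:
                assert p.category is ThermalCategory.NUCLEOTIDE_RESPONSIVE
            responsive = p.category is ThermalCategory.NUCLEOTIDE_RESPONSIVE


def test_curves_csv_round_trip(tmp_path):
    spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02,
                       replicates=2, seed=3, variant="WT", nucleotide="GDP")
    curves = generate_melting_curves(spec)
    path = tmp_path / "curves.csv"
    write_curves_csv(curves, path)
    back = read_curves_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].signal, curves[0].signal)
    assert back[0].variant == "WT" and back[0].nucleotide == "GDP"
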