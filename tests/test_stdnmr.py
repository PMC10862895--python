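import numpy as np
import pytest

from switchscope.errors import InputError, NormalizationError, SpecValidationError
from switchscope.stdnmr import (
    FingerprintBin,
    STDIntegralRecord,
    SampleContext,
    bin_fingerprint_value,
    compute_std_af,
    compute_std_table,
    normalize_fingerprint,
    select_saturation_time,
    read_std_csv,
    write_std_csv,
)
from switchscope.synthetic import STDGenSpec, generate_std_table

CTX = SampleContext(ligand_conc=2000.0, protein_conc=40.0)


class TestAmplificationFactor:
    def test_analytic_case(self):
        af = compute_std_af(STDIntegralRecord("a", 2.0, 1.0, 50.0), CTX)
        assert af.a_std == pytest.approx(25.0)
        assert af.sigma == pytest.approx(0.5)

    def test_no_transfer(self):
        af = compute_std_af(STDIntegralRecord("a", 2.0, 2.0, 50.0), CTX)
        assert af.a_std == 0.0 and af.sigma == 0.0

    def test_negative_a_std_preserved_with_warning(self):
        with pytest.warns(UserWarning, match="artifact"):
            af = compute_std_af(STDIntegralRecord("a", 1.0, 1.1, 50.0), CTX)
        assert af.a_std == pytest.approx(-5.0)

    def test_unusable_record_rejected(self):
        rec = STDIntegralRecord("c", 1.0, 0.5, 10.0, usable=False)
        with pytest.raises(InputError):
            compute_std_af(rec, CTX)

    def test_table_skips_unusable(self):
        recs = [STDIntegralRecord("a", 1.0, 0.5, 10.0),
                STDIntegralRecord("c", 1.0, 0.5, 10.0, usable=False)]
        afs = compute_std_table(recs, CTX)
        assert [a.proton_label for a in afs] == ["a"]

    def test_gain_invariance(self):
        af1 = compute_std_af(STDIntegralRecord("a", 2.0, 1.2, 50.0), CTX)
        af2 = compute_std_af(STDIntegralRecord("a", 200.0, 120.0, 50.0), CTX)
        assert af1.a_std == pytest.approx(af2.a_std)
        assert af1.sigma == pytest.approx(af2.sigma)


class TestNormalization:
    def _af(self, label, a_std, sigma=0.0):
        from switchscope.stdnmr import STDAmplification
        return STDAmplification(label, a_std, sigma)

    def test_all_equal_gives_unit_ratios(self):
        fp = normalize_fingerprint([self._af("a", 5.0), self._af("b", 5.0)])
        assert fp.ratios() == {"a": 1.0, "b": 1.0}

    def test_double_is_strong(self):
        fp = normalize_fingerprint([self._af("a", 5.0), self._af("b", 10.0)])
        entry = {e.proton_label: e for e in fp.entries}["b"]
        assert entry.ratio == pytest.approx(2.0)
        assert entry.bin is FingerprintBin.STRONG

    def test_quadrature_error_propagation(self):
        fp = normalize_fingerprint(
            [self._af("a", 10.0, 1.0), self._af("b", 20.0, 1.0)])
        entry = {e.proton_label: e for e in fp.entries}["b"]
        assert entry.sigma == pytest.approx(2.0 * np.hypot(0.05, 0.1))

    def test_scale_invariance(self):
        afs1 = [self._af("a", 5.0, 0.5), self._af("b", 7.5, 0.3)]
        afs2 = [self._af("a", 50.0, 5.0), self._af("b", 75.0, 3.0)]
        r1 = normalize_fingerprint(afs1).ratios()
        r2 = normalize_fingerprint(afs2).ratios()
        assert r1 == pytest.approx(r2)

    def test_idempotent(self):
        fp = normalize_fingerprint([self._af("a", 5.0), self._af("b", 7.5)])
        again = normalize_fingerprint(
            [self._af(e.proton_label, e.ratio) for e in fp.entries])
        assert again.ratios() == pytest.approx(fp.ratios())

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_fingerprint([self._af("a", 0.0), self._af("b", 5.0)])

    def test_excluded_labels_reported(self):
        fp = normalize_fingerprint([self._af("a", 5.0)], excluded=["c", "d"])
        bins = {e.proton_label: e.bin for e in fp.entries}
        assert bins["c"] is FingerprintBin.EXCLUDED
        assert bins["d"] is FingerprintBin.EXCLUDED

    def test_forward_simulated_ratio_recovery(self):
        # derived oracle: 1000-seed forward simulation, empirical mean of
        # the normalized ratio for a half-weight epitope
        ratios = []
        for seed in range(1000):
            spec = STDGenSpec(epitope_weights={"a": 0.02, "b": 0.01},
                              i0={"a": 1.0, "b": 1.0},
                              snr={"a": 2000.0, "b": 2000.0}, seed=seed)
            table = generate_std_table(spec)
            afs = compute_std_table(list(table.records), table.context)
            ratios.append(normalize_fingerprint(afs).ratios()["b"])
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
        assert abs(mean - 0.5) < max(3 * sem, 0.01)


class TestBinning:
    @pytest.mark.parametrize("ratio,expected", [
        (0.0, FingerprintBin.WEAK),
        (0.49, FingerprintBin.WEAK),
        (0.50, FingerprintBin.WEAK_MODERATE),
        (0.99, FingerprintBin.REFERENCE),   # inside the +/-2% reference band
        (0.97, FingerprintBin.WEAK_MODERATE),
        (1.00, FingerprintBin.REFERENCE),
        (1.03, FingerprintBin.MODERATE),
        (1.25, FingerprintBin.MODERATE),
        (1.50, FingerprintBin.MODERATE),
        (1.51, FingerprintBin.STRONG),
        (-0.1, FingerprintBin.ARTIFACT),
    ])
    def test_bins(self, ratio, expected):
        assert bin_fingerprint_value(ratio) is expected

    def test_order_preserving(self):
        order = [FingerprintBin.WEAK, FingerprintBin.WEAK_MODERATE,
                 FingerprintBin.REFERENCE, FingerprintBin.MODERATE,
                 FingerprintBin.STRONG]
        ratios = np.linspace(0.0, 2.0, 401)
        ranks = [order.index(bin_fingerprint_value(float(r))) for r in ratios]
        assert ranks == sorted(ranks)

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            bin_fingerprint_value(float("nan"))


class TestSaturationTime:
    def test_plateau_selection(self):
        assert select_saturation_time({0.5: 10.0, 1.0: 16.0, 2.0: 19.0,
                                       3.0: 19.5}) == 2.0

    def test_flat_pair(self):
        assert select_saturation_time({1.0: 5.0, 2.0: 5.0}) == 1.0

    def test_single_point_rejected(self):
        with pytest.raises(InputError):
            select_saturation_time({2.0: 5.0})


def test_spec_validation_weight_bounds():
    with pytest.raises(SpecValidationError) as exc:
        STDGenSpec(epitope_weights={"a": 1.5}, i0={"a": 1.0}, snr={"a": 10.0})
    assert exc.value.field == "epitope_weights"


def test_std_csv_round_trip(tmp_path):
    spec = STDGenSpec(epitope_weights={"a": 0.02, "b": 0.03},
                      i0={"a": 1.0, "b": 1.2}, snr={"a": 50.0, "b": 50.0},
                      seed=9, variant="WT")
    table = generate_std_table(spec)
    path = tmp_path / "std.csv"
    write_std_csv(list(table.records), table.context, path)
    [(records, ctx)] = read_std_csv(path)
    assert ctx.excess == pytest.approx(50.0)
    assert [r.proton_label for r in records] == ["a", "b"]
    assert records[0].isat == pytest.approx(table.records[0].isat)
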