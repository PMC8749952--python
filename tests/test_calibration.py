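import logging

import numpy as np
import pytest

from mbaq.calibration import (
    calibrate_all_runs,
    estimate_standard_amount,
    median_calibrant,
    near_median_fraction,
    normalized_median_abundance,
)
from mbaq.errors import CalibrationError, ValidationError
from mbaq.io_tables import StandardSpec
from mbaq.quantify import quantify_run

from conftest import make_table, std_rows


def three_pair_spec():
    scrambled = ["GGATTLK", "GGDTTLK", "GGETTLK"]
    natives = ["GGATTLR", "GGDTTLR", "GGETTLR"]
    return StandardSpec(
        standard_peptides=["AAGLLK", "TTSSPK", "VVNNQK"] + scrambled,
        reference_pairs=list(zip(natives, scrambled)),
        reference_amount=2e-12,
        standard_protein_id="STD",
        reference_protein_id="REF",
    )


class TestStandardAmount:
    def test_identity_ratios_recover_reference(self, toy_spec):
        spec = three_pair_spec()
        spec.reference_amount = 1e-12
        rows = [("r1", "STD", s, 100.0) for _, s in spec.reference_pairs]
        rows += [("r1", "REF", n, 100.0) for n, _ in spec.reference_pairs]
        amount, ratios = estimate_standard_amount(make_table(rows), spec, "r1")
        assert amount == pytest.approx(1e-12)
        assert ratios == [1.0, 1.0, 1.0]

    def test_median_over_pair_ratios(self):
        spec = three_pair_spec()  # 2 pmol reference
        areas = {0: (80.0, 100.0), 1: (100.0, 100.0), 2: (120.0, 100.0)}
        rows = []
        for i, (native, scrambled) in enumerate(spec.reference_pairs):
            scr, nat = areas[i]
            rows += [("r1", "STD", scrambled, scr), ("r1", "REF", native, nat)]
        amount, ratios = estimate_standard_amount(make_table(rows), spec, "r1")
        assert sorted(ratios) == [0.8, 1.0, 1.2]
        assert amount == pytest.approx(2e-12)

    def test_all_native_zero_is_calibration_error(self):
        spec = three_pair_spec()
        rows = [("r1", "STD", s, 50.0) for _, s in spec.reference_pairs]
        rows += [("r1", "REF", n, 0.0) for n, _ in spec.reference_pairs]
        with pytest.raises(CalibrationError):
            estimate_standard_amount(make_table(rows), spec, "r1")


class TestMedianCalibrant:
    def test_median_and_response_factor(self, toy_spec):
        # standard amount comes out at 300 fmol: scrambled/native = 0.3 of 1 pmol
        table = make_table(std_rows("r1", [2.0, 4.0, 6.0], scr_area=30.0, nat_area=100.0))
        cal = median_calibrant(table, toy_spec, "r1")
        assert cal.standard_amount == pytest.approx(300e-15)
        assert cal.median_area == 4.0
        assert cal.response_factor == pytest.approx(75e-15)  # 75 fmol per area unit

    def test_single_peptide_low_count_warning(self, toy_spec, caplog):
        table = make_table(
            [("r1", "STD", "AAGLLK", 8.0)]
            + std_rows("r1", [0.0, 0.0, 0.0], 30.0, 100.0)[3:]
        )
        with caplog.at_level(logging.WARNING, logger="mbaq"):
            cal = median_calibrant(table, toy_spec, "r1")
        assert cal.median_area == 8.0
        assert cal.response_factor == pytest.approx(cal.standard_amount / 8.0)
        assert any("plateau" in r.message for r in caplog.records)

    def test_equal_areas_give_that_median(self, toy_spec):
        table = make_table(std_rows("r1", [7.0, 7.0, 7.0], 30.0, 100.0))
        assert median_calibrant(table, toy_spec, "r1").median_area == 7.0

    def test_no_standard_peptide_detected(self, toy_spec):
        table = make_table(std_rows("r1", [0.0, 0.0, 0.0], 30.0, 100.0))
        with pytest.raises(CalibrationError):
            median_calibrant(table, toy_spec, "r1")


class TestNMA:
    def test_unbiased_standard_gives_unity(self, toy_spec):
        # expected area = scrambled area (single pair); standard areas equal it
        table = make_table(std_rows("r1", [30.0, 30.0, 30.0], 30.0, 100.0))
        assert normalized_median_abundance(table, toy_spec, "r1") == pytest.approx(1.0)

    def test_global_suppression_scales_linearly(self, toy_spec):
        base = std_rows("r1", [30.0, 30.0, 30.0], 30.0, 100.0)
        suppressed = [
            (r, p, s, a * 0.45 if p == "STD" and s != "NATIMEK" else a)
            for r, p, s, a in base
        ]
        nma = normalized_median_abundance(make_table(suppressed), toy_spec, "r1")
        assert nma == pytest.approx(0.45)

    def test_median_ignores_outliers(self, toy_spec):
        spec = StandardSpec(
            standard_peptides=["AAGLLK", "TTSSPK", "VVNNQK", "LLPPGGK", "HHWWFFK", "NATIMEK"],
            reference_pairs=[("NATIVEK", "NATIMEK")],
            reference_amount=1e-12,
            standard_protein_id="STD",
            reference_protein_id="REF",
        )
        rows = [("r1", "STD", p, a) for p, a in zip(
            ["AAGLLK", "TTSSPK", "VVNNQK", "LLPPGGK", "HHWWFFK"],
            [90.0, 100.0, 110.0, 200.0, 30.0],
        )]
        rows += [("r1", "STD", "NATIMEK", 100.0), ("r1", "REF", "NATIVEK", 250.0)]
        assert normalized_median_abundance(make_table(rows), spec, "r1") == pytest.approx(1.0)

    def test_symmetric_response_converges_to_unity(self, toy_spec):
        # 1000 simulated runs with symmetric multiplicative perturbations
        rng = np.random.default_rng(20240917)
        nmas = []
        for i in range(1000):
            run = f"r{i}"
            factors = np.exp(rng.normal(0.0, 0.2, 3))
            rows = std_rows(run, list(30.0 * factors), 30.0, 100.0)
            nmas.append(normalized_median_abundance(make_table(rows), toy_spec, run))
        assert np.mean(nmas) == pytest.approx(1.0, abs=0.05)


class TestNearMedianFraction:
    def test_hand_enumeration(self):
        assert near_median_fraction([0.9, 1.0, 1.1, 2.0, 0.3]) == pytest.approx(0.6)

    def test_all_equal(self):
        assert near_median_fraction([5.0] * 9) == 1.0

    def test_zero_band_keeps_only_the_median(self):
        assert near_median_fraction([1.0, 2.0, 3.0, 4.0, 5.0], band=0.0) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            near_median_fraction([])


class TestScaleInvariance:
    def test_rescaled_run_yields_same_amounts(self):
        from mbaq.synthetic import simulate_dataset

        table, spec, _ = simulate_dataset(
            n_proteins=8, peptides_per_protein=4, n_runs=1, seed=5, n_standard_peptides=11
        )
        scaled = table.scaled(37.5)
        cal_a = median_calibrant(table, spec, "run1")
        cal_b = median_calibrant(scaled, spec, "run1")
        assert cal_b.response_factor == pytest.approx(cal_a.response_factor / 37.5)
        assert cal_b.standard_amount == pytest.approx(cal_a.standard_amount)
        assert cal_b.nma == pytest.approx(cal_a.nma)
        assert cal_b.nm_fraction == cal_a.nm_fraction
        qa, _ = quantify_run(table, spec, cal_a)
        qb, _ = quantify_run(scaled, spec, cal_b)
        for a, b in zip(qa, qb):
            assert b.amount == pytest.approx(a.amount, rel=1e-9)

    def test_median_robust_to_single_outlier(self, toy_spec):
        # replacing one area by an arbitrarily large value moves the median
        # at most to the next order statistic (brute-force sort oracle)
        base = [2.0, 4.0, 6.0]
        table = make_table(std_rows("r1", base, 30.0, 100.0))
        m0 = median_calibrant(table, toy_spec, "r1").median_area
        spiked = make_table(std_rows("r1", [2.0, 4.0, 1e9], 30.0, 100.0))
        m1 = median_calibrant(spiked, toy_spec, "r1").median_area
        order = sorted(base)
        gap = order[2] - order[1]
        assert abs(m1 - m0) <= gap + 1e-12


def test_pooled_mode_shares_one_factor(toy_spec):
    rows = std_rows("r1", [2.0, 4.0, 6.0], 30.0, 100.0) + std_rows(
        "r2", [3.0, 5.0, 7.0], 33.0, 100.0
    )
    cals = calibrate_all_runs(make_table(rows), toy_spec, pooled=True)
    factors = {c.response_factor for c in cals.values()}
    assert len(factors) == 1
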