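"""Standard curves, percent input, enrichment factors, delta-Ct copy
numbers, densitometry normalization and the t-test conventions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rasikit.wetlab_quant import (analyze_chip, densitometry_normalize,
                                  enrichment_factor, fit_standard_curve,
                                  genomic_copy_estimate, percent_input,
                                  quantity_from_ct, relative_copies_delta_ct,
                                  students_t_test)


def _perfect_series(slope=-3.3219280948873623, intercept=34.0):
    return [(10.0 ** k, intercept + slope * k) for k in range(5)]


class TestStandardCurve:
    def test_perfect_doubling_series(self):
        curve = fit_standard_curve(_perfect_series())
        assert curve.slope == pytest.approx(-1 / math.log10(2), rel=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_closed_form(self):
        curve = fit_standard_curve([(10.0 ** k, 30 - 3.5 * k) for k in range(4)])
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5) - 1, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(1, 30), (10, 27)])

    def test_degenerate_quantities(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(1, 30), (1, 29), (1, 31)])

    def test_quantity_roundtrip_and_monotonicity(self):
        curve = fit_standard_curve(_perfect_series())
        assert quantity_from_ct(curve.intercept, curve) == pytest.approx(1.0)
        assert quantity_from_ct(curve.intercept + curve.slope, curve) == \
            pytest.approx(10.0)
        grid = [quantity_from_ct(ct, curve) for ct in np.linspace(20, 40, 21)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_noisy_efficiency_recovery_within_003(self):
        """Simulated dilution series at sigma=0.1 recover the true efficiency."""
        from rasikit.synthetic_data import QpcrDesign, simulate_dilution_series

        for seed, e_true in ((101, 0.85), (102, 0.95), (103, 1.0)):
            rng = np.random.default_rng(seed)
            design = QpcrDesign(primer_efficiencies={"P": e_true}, ct_noise_sd=0.1)
            curve = fit_standard_curve(
                list(zip(*(simulate_dilution_series(rng, design)[c]
                           for c in ("quantity", "ct")))), "P")
            assert abs(curve.efficiency - e_true) <= 0.03


class TestPercentInputAndEnrichment:
    @pytest.mark.parametrize("ip,inp,frac,expected", [
        (5.0, 5.0, 1.0, 100.0),
        (0.5, 5.0, 1.0, 10.0),
        (5.0, 5.0, 0.1, 10.0),
    ])
    def test_percent_input(self, ip, inp, frac, expected):
        assert percent_input(ip, inp, frac) == pytest.approx(expected)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            percent_input(1.0, 0.0, 1.0)

    def test_enrichment(self):
        assert enrichment_factor(4.0, 4.0) == 1.0
        assert enrichment_factor(8.0, 4.0) == 2.0
        with pytest.raises(ValueError):
            enrichment_factor(1.0, 0.0)


class TestDeltaCt:
    @pytest.mark.parametrize("ref,target,expected", [
        (25.0, 25.0, 1.0),
        (27.0, 25.0, 4.0),
        (24.0, 25.0, 0.5),
    ])
    def test_two_power_delta(self, ref, target, expected):
        assert relative_copies_delta_ct(ref, target) == pytest.approx(expected)

    def test_multiplicative_in_delta(self):
        f = relative_copies_delta_ct
        assert f(30.0, 25.0) == pytest.approx(f(30.0, 27.5) * f(27.5, 25.0))

    def test_efficiency_corrected_variant(self):
        assert relative_copies_delta_ct(26.0, 25.0, efficiency=0.9) == \
            pytest.approx(1.9)

    def test_copy_estimate_closed_form(self):
        mean, (lo, hi) = genomic_copy_estimate([(35.7, 25.0)])
        assert mean == pytest.approx(2 ** 10.7, rel=1e-12)
        assert lo == hi == mean

    def test_copy_estimate_interval_contains_truth(self):
        from rasikit.synthetic_data import QpcrDesign, simulate_genomic_qpcr

        rng = np.random.default_rng(77)
        design = QpcrDesign(ct_noise_sd=0.1, genomic_copies=1800.0,
                            genomic_replicates=6)
        df = simulate_genomic_qpcr(rng, design)
        mean, (lo, hi) = genomic_copy_estimate(
            list(zip(df["ct_reference"], df["ct_target"])))
        assert lo <= 1800.0 <= hi

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            genomic_copy_estimate([])


class TestChipAnalysis:
    def test_noiseless_round_trip_recovers_planted_enrichment(self):
        from rasikit.synthetic_data import (QpcrDesign, simulate_chip_samples,
                                            simulate_dilution_series)

        rng = np.random.default_rng(13)
        design = QpcrDesign(ct_noise_sd=0.0)
        dil = simulate_dilution_series(rng, design)
        samples = simulate_chip_samples(rng, design)
        result = analyze_chip(dil, samples, control_primer="Sf_L37",
                              input_fraction=design.input_fraction)
        control = result[result.locus == "Sf_L37"]
        assert (control.enrichment_factor == 1.0).all()
        for _, row in result[result.locus != "Sf_L37"].iterrows():
            truth = design.true_enrichment[(row.locus, row.antibody, row.stage)]
            assert row.enrichment_factor == pytest.approx(truth, rel=1e-9)

    def test_missing_curve_rejected(self):
        dil = pd.DataFrame({"primer_set": ["A"] * 3, "quantity": [1, 10, 100],
                            "ct": [30, 27, 24]})
        samples = pd.DataFrame({"primer_set": ["B"], "antibody": ["H3"],
                                "stage": ["eggs"], "replicate": [1], "ct": [25.0]})
        with pytest.raises(ValueError):
            analyze_chip(dil, samples)


class TestDensitometry:
    def test_uniform_table_normalizes_to_ones(self):
        table = pd.DataFrame({"H3": [3.0, 3.0], "H3K9me2": [3.0, 3.0]},
                             index=["E1", "L2"])
        norm = densitometry_normalize(table, "H3", "E1")
        assert np.allclose(norm.to_numpy(), 1.0)

    def test_doubling_h3_halves_the_mark_ratio(self):
        table = pd.DataFrame({"H3": [1.0, 2.0], "H3K9me2": [1.0, 1.0]},
                             index=["E1", "L2"])
        norm = densitometry_normalize(table, "H3", "E1")
        assert norm.at["L2", "H3K9me2"] == pytest.approx(0.5)
        assert norm.at["L2", "H3"] == pytest.approx(2.0)

    def test_reference_cells_are_one(self):
        rng = np.random.default_rng(23)
        table = pd.DataFrame(rng.uniform(0.5, 3.0, size=(4, 3)),
                             index=["E1", "E2", "L1", "L2"],
                             columns=["H3", "H3K9me2", "H3K4me2"])
        norm = densitometry_normalize(table, "H3", "E1")
        assert np.allclose(norm.loc["E1"].to_numpy(), 1.0)

    def test_ratio_algebra(self):
        rng = np.random.default_rng(29)
        table = pd.DataFrame(rng.uniform(0.5, 3.0, size=(3, 2)),
                             index=["E1", "L1", "P"], columns=["H3", "H3K4me2"])
        norm = densitometry_normalize(table, "H3", "E1")
        for stage in table.index:
            expected = (table.at[stage, "H3K4me2"] / table.at[stage, "H3"]) / \
                (table.at["E1", "H3K4me2"] / table.at["E1", "H3"])
            assert norm.at[stage, "H3K4me2"] == pytest.approx(expected)

    def test_missing_reference_rejected(self):
        table = pd.DataFrame({"H3K9me2": [1.0]}, index=["E1"])
        with pytest.raises(ValueError):
            densitometry_normalize(table, "H3", "E1")


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_flagged(self):
        res = students_t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.p_value == 0.0 and res.degenerate

    def test_paired_constant_difference_flagged(self):
        res = students_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)
        assert res.degenerate and res.p_value == 0.0

    def test_matches_closed_form_t(self):
        a = [4.2, 4.8, 5.1, 4.9]
        b = [5.6, 5.9, 6.1, 6.3]
        res = students_t_test(a, b)
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        t = (np.mean(a) - np.mean(b)) / (sp * math.sqrt(1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [1.0, 2.0])
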