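"""Forward simulators: exactness, determinism, and convolution oracles."""

import numpy as np
import pandas as pd
import pytest

from isofodder.calendar import DAYS_PER_YEAR
from isofodder.seasonal import assign_julian_days, fit_seasonal_cosine
from isofodder.sources import SpacingTable, tissue_to_diet
from isofodder.synthetic import (
    DEFAULT_C3,
    DEFAULT_C4,
    FodderSchedule,
    GrowthModel,
    NoiseModel,
    SeasonalEnvironment,
    default_collagen_spec,
    default_reference_spec,
    simulate_collagen_population,
    simulate_mtdna_reads,
    simulate_reference_fauna,
    simulate_tooth_cohort,
    simulate_tooth_series,
)

NO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


def schedule_window_mean_oracle(schedule, t, window):
    """Analytic centred-window mean of the rectangular-pulse schedule.

    Independent of the simulator's discrete convolution: the overlap of
    [t - w/2, t + w/2] with the (wrapped) pulse interval is computed in
    closed form.
    """
    lo, hi = t - window / 2.0, t + window / 2.0
    # integrate the indicator of the pulse over [lo, hi], unwrapped
    start = schedule.pulse_start
    length = schedule.pulse_length

    def pulse_time_below(u):
        """Total pulse time in [0, u) for u >= 0, by whole cycles + remainder."""
        cycles, rem = divmod(u, DAYS_PER_YEAR)
        # pulse occupies [start, start+length) mod 365
        rem_overlap = max(0.0, min(rem, start + length) - start)
        if start + length > DAYS_PER_YEAR:  # wrapped tail at cycle start
            rem_overlap += min(rem, start + length - DAYS_PER_YEAR)
        return cycles * length + rem_overlap

    shift = np.ceil(max(0.0, -lo) / DAYS_PER_YEAR) * DAYS_PER_YEAR
    overlap = pulse_time_below(hi + shift) - pulse_time_below(lo + shift)
    frac = overlap / window
    return schedule.baseline + (schedule.pulse_fraction - schedule.baseline) * frac


def band_value_oracle(schedule, growth, t0, band_index, n_sub=2001):
    """Brute-force double average: maturation window x band formation span."""
    band_days = growth.band_width / growth.growth_rate
    ta = t0 + band_index * band_days
    u = np.linspace(ta, ta + band_days, n_sub)
    s = [schedule_window_mean_oracle(schedule, ui, growth.maturation_window)
         for ui in u]
    return float(np.trapezoid(s, u) / band_days)


class TestToothSeries:
    def test_constant_diet_zero_noise_is_exact(self):
        series, truth = simulate_tooth_series(
            FodderSchedule(pulse_fraction=0.0), noise=NO_NOISE, seed=0
        )
        np.testing.assert_allclose(series["d13C_apa"], -9.9, atol=1e-9)

    def test_zero_noise_d18O_is_exact_sampled_cosine(self):
        series, _ = simulate_tooth_series(
            FodderSchedule(pulse_fraction=0.0), noise=NO_NOISE, seed=0
        )
        fit = fit_seasonal_cosine(series)
        assert fit.rmse < 1e-8  # smoothing attenuates but preserves the form
        assert fit.period == pytest.approx(0.065 * 365, abs=1e-4)

    def test_band_count_conservation(self):
        for crown, width in [(30.0, 1.0), (33.5, 1.0), (30.0, 1.5)]:
            growth = GrowthModel(crown_length=crown, band_width=width)
            series, _ = simulate_tooth_series(
                FodderSchedule(), growth=growth, seed=0
            )
            assert len(series) == int(np.floor(crown / width))

    def test_bands_ordered_crown_to_cervix(self):
        series, truth = simulate_tooth_series(FodderSchedule(), seed=0)
        pos = series["position_mm"].to_numpy()
        assert np.all(np.diff(pos) < 0)
        # deposition time advances as position decreases
        days = np.unwrap(truth["true_day"].to_numpy(), period=365)
        assert np.all(np.diff(days) > 0)

    def test_winter_pulse_band_values_match_convolution_oracle(self):
        schedule = FodderSchedule(pulse_fraction=0.6)
        growth = GrowthModel()
        t0 = 120.0
        series, truth = simulate_tooth_series(
            schedule, growth=growth, noise=NO_NOISE, seed=0, crown_init_day=t0
        )
        span = DEFAULT_C4.mean - DEFAULT_C3.mean
        for idx in (0, 7, 14, 21, 29):
            expected = (
                DEFAULT_C3.mean
                + span * band_value_oracle(schedule, growth, t0, idx)
                + 14.1
            )
            assert series["d13C_apa"].iloc[idx] == pytest.approx(
                expected, abs=0.05
            )
        # winter bands exceed summer bands by the oracle-predicted amount
        winter = truth["true_bimonth"].isin(["Jan-Feb", "Nov-Dec"])
        summer = truth["true_bimonth"] == "Jul-Aug"
        assert (
            series["d13C_apa"][winter].mean() - series["d13C_apa"][summer].mean()
            > 2.0
        )

    def test_truth_kept_separate_from_analysis_table(self):
        series, truth = simulate_tooth_series(FodderSchedule(), seed=0)
        assert "true_day" not in series.columns
        assert "d13C_apa" not in truth.columns
        assert {"true_day", "true_c4_smoothed", "true_c4_instant"} <= set(
            truth.columns
        )

    def test_noise_at_stated_precisions(self):
        """Residual scatter about the noiseless series matches the sds."""
        clean, _ = simulate_tooth_series(FodderSchedule(), noise=NO_NOISE, seed=0)
        resid_c, resid_o = [], []
        for seed in range(40):
            noisy, _ = simulate_tooth_series(
                FodderSchedule(), noise=NoiseModel(), seed=seed
            )
            resid_c.append(noisy["d13C_apa"] - clean["d13C_apa"])
            resid_o.append(noisy["d18O_apa"] - clean["d18O_apa"])
        assert np.concatenate(resid_c).std() == pytest.approx(0.05, rel=0.15)
        assert np.concatenate(resid_o).std() == pytest.approx(0.07, rel=0.15)

    def test_determinism_byte_identical(self):
        a_series, a_truth = simulate_tooth_series(FodderSchedule(), seed=42)
        b_series, b_truth = simulate_tooth_series(FodderSchedule(), seed=42)
        assert a_series.to_csv() == b_series.to_csv()
        assert a_truth.to_csv() == b_truth.to_csv()

    def test_short_crown_rejected(self):
        with pytest.raises(ValueError, match="one year"):
            simulate_tooth_series(
                FodderSchedule(), growth=GrowthModel(crown_length=10.0), seed=0
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GrowthModel(growth_rate=-0.1)

    def test_identical_source_means_rejected(self):
        from isofodder.sources import DietSource

        same = (DietSource("C3_steppe", -18.0, 1.0), DietSource("C4_millet", -18.0, 1.0))
        with pytest.raises(ValueError, match="distinct"):
            simulate_tooth_series(FodderSchedule(), sources=same, seed=0)


class TestSchedule:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            FodderSchedule(pulse_fraction=1.2)

    def test_periodicity(self):
        schedule = FodderSchedule()
        days = np.linspace(0, 365, 50)
        np.testing.assert_array_equal(
            schedule(days), schedule(days + 365)
        )

    def test_default_pulse_covers_midwinter(self):
        schedule = FodderSchedule()
        assert schedule(0.0) == 0.5  # model day 0 = Jan 15
        assert schedule(182.0) == 0.0  # mid-July


class TestCollagenPopulation:
    def test_no_manuring_null_effect(self):
        table = simulate_collagen_population(
            default_collagen_spec(), manure_shift=0.0, seed=1
        )
        livestock = table[table["status"] == "livestock"]["d15N_col"]
        wild = table[table["status"] == "wild"]["d15N_col"]
        se = np.sqrt(
            livestock.var(ddof=1) / len(livestock) + wild.var(ddof=1) / len(wild)
        )
        assert abs(livestock.mean() - wild.mean()) < 3 * se

    def test_manure_shift_recovered(self):
        spec = [
            {"site": "S", "period": "P", "taxon": "Ovis aries",
             "status": "livestock", "diet_d13C": -22.0, "d15N": 6.0, "n": 150},
            {"site": "S", "period": "P", "taxon": "Cervus elaphus",
             "status": "wild", "diet_d13C": -24.0, "d15N": 6.0, "n": 20},
        ]
        table = simulate_collagen_population(spec, manure_shift=4.0, seed=7)
        livestock = table[table["status"] == "livestock"]["d15N_col"]
        wild = table[table["status"] == "wild"]["d15N_col"]
        se = np.sqrt(
            livestock.var(ddof=1) / len(livestock) + wild.var(ddof=1) / len(wild)
        )
        assert livestock.mean() - wild.mean() == pytest.approx(4.0, abs=3 * se)

    def test_collagen_equals_diet_plus_spacing_in_expectation(self):
        table = simulate_collagen_population(default_collagen_spec(), seed=3)
        resid = table["d13C_col"] - table["true_diet_d13C"] - 5.0
        assert abs(resid.mean()) < 0.05
        assert resid.std() == pytest.approx(0.1, rel=0.2)

    def test_bad_cn_fraction_exercises_qc(self):
        from isofodder.collagen import qc_filter

        table = simulate_collagen_population(
            default_collagen_spec(), bad_cn_fraction=0.2, seed=5
        )
        report = qc_filter(table)
        assert report.n_rejected == pytest.approx(0.2 * len(table), abs=3)
        assert set(report.rejected["reason"]) <= {"CN_low", "CN_high"}

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_collagen_population([], seed=0)

    def test_determinism(self):
        a = simulate_collagen_population(default_collagen_spec(), seed=9)
        b = simulate_collagen_population(default_collagen_spec(), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestReferenceFauna:
    def test_zero_noise_tissue_equals_diet_plus_spacing(self):
        spec = [{"taxon": "t", "tissue": "enamel", "diet_mean": -24.0,
                 "diet_sd": 1e-12, "n": 4}]
        table = simulate_reference_fauna(spec, noise=NO_NOISE, seed=0)
        np.testing.assert_allclose(table["d13C_tissue"], -9.9, atol=1e-6)

    def test_inversion_equals_rowwise_subtraction_oracle(self, spacing):
        table = simulate_reference_fauna(default_reference_spec(), seed=2)
        diet = tissue_to_diet(
            table["d13C_tissue"].to_numpy(), table["tissue_kind"], spacing
        )
        expected = np.array(
            [v - spacing.get(k)
             for v, k in zip(table["d13C_tissue"], table["tissue_kind"])]
        )
        np.testing.assert_allclose(diet, expected)

    def test_roundtrip_recovers_dietary_distribution(self, spacing):
        table = simulate_reference_fauna(default_reference_spec(), seed=4)
        diet = tissue_to_diet(
            table["d13C_tissue"].to_numpy(), table["tissue_kind"], spacing
        )
        resid = diet - table["true_diet_d13C"].to_numpy()
        assert abs(resid.mean()) < 0.05  # only analytical noise remains
        # generating dietary means are inside the regional C3 window
        assert table["true_diet_d13C"].mean() == pytest.approx(-24.0, abs=0.5)

    def test_unknown_tissue_rejected(self):
        spec = [{"taxon": "t", "tissue": "antler", "diet_mean": -24.0,
                 "diet_sd": 0.5, "n": 2}]
        with pytest.raises(ValueError, match="unknown tissue"):
            simulate_reference_fauna(spec, seed=0)


class TestMtdnaReads:
    def test_zero_mutation_reads_classify_to_truth(self, panel):
        from isofodder.mtdna import assign_taxon, trim_primers

        reads, truth = simulate_mtdna_reads(
            panel, {e.taxon: 3 for e in panel}, n_mutations=0, seed=0
        )
        for (rid, seq), (_, row) in zip(reads, truth.iterrows()):
            res = assign_taxon(trim_primers(seq), panel)
            assert res.taxon == row["true_taxon"]
            assert res.identical

    def test_read_structure_is_primer_insert_primer(self, panel):
        from isofodder.mtdna import FORWARD_PRIMER, REVERSE_PRIMER

        reads, _ = simulate_mtdna_reads(panel, {"Ovis aries": 1}, seed=1)
        read = reads[0][1]
        assert read.startswith(FORWARD_PRIMER)
        rc = REVERSE_PRIMER.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert read.endswith(rc)
        assert len(read) == len(FORWARD_PRIMER) + panel.length + len(REVERSE_PRIMER)

    def test_mutation_count_bounded(self, panel):
        with pytest.raises(ValueError, match="below the fragment length"):
            simulate_mtdna_reads(
                panel, {"Ovis aries": 1}, n_mutations=panel.length, seed=0
            )

    def test_diagnostic_site_mutation_matches_distance_oracle(self):
        """A mutation at the single diagnostic site between two haplotypes
        makes the query equidistant -> flagged ambiguous, exactly as
        exhaustive distances predict."""
        from isofodder.mtdna import HaplotypePanel, PanelEntry, assign_taxon

        a = "ACGTACGTAC"
        b = "ACGTACGTAG"  # differs from a at the last site only
        panel = HaplotypePanel(
            [
                PanelEntry("a", a, "Ovis aries", "domestic"),
                PanelEntry("b", b, "Ovis ammon", "wild"),
            ]
        )
        query = a[:-1] + "T"  # mutate the diagnostic site to a third base
        res = assign_taxon(query, panel)
        assert res.mismatches == 1 and res.margin == 0 and res.ambiguous


class TestEndToEndRecovery:
    def test_winter_c4_recovered_within_credible_interval(self, sources):
        """Pipeline on simulated teeth covers the generator's smoothed
        winter truth in most replicates (calibration with MC slack)."""
        from isofodder.mixing import run_mixing_by_group
        from isofodder.seasonal import process_tooth_table

        schedule = FodderSchedule(pulse_fraction=0.5)
        hits = trials = 0
        for seed in range(10):
            series, truth = simulate_tooth_cohort(
                6, schedule, sources=sources, seed=seed
            )
            bands, bins, fits = process_tooth_table(series)
            bins = bins.dropna(subset=["mean_d13C_apa"]).assign(
                dietary_d13C=lambda d: d["mean_d13C_apa"] - 14.1
            )
            results = run_mixing_by_group(bins, sources, engine="grid")
            true_by_bin = truth.groupby("true_bimonth")["true_c4_smoothed"].mean()
            for res in results:
                bm = res.group["bimonth"]
                if bm in ("Jan-Feb", "Nov-Dec") and bm in true_by_bin:
                    trials += 1
                    hits += res.p_lo90 <= true_by_bin[bm] <= res.p_hi90
        assert trials >= 15
        assert hits / trials >= 0.8
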