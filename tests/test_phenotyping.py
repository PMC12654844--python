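import math

import numpy as np
import pytest

from spotlag.phenotyping import (
    Lag,
    PairingError,
    PhenotypeRecord,
    attach_normalized_lags,
    classify_profile,
    curves_to_records,
    extract_amax,
    extract_lag,
    normalize_lag,
    summarize_lag_distribution,
    summarize_replicates,
)
from spotlag.quantification import GrowthCurve


def curve(areas_by_day, density="high", **meta):
    days = sorted(areas_by_day)
    meta = {"density_class": density, **meta}
    return GrowthCurve(
        meta.get("drop_id", "d0"),
        days,
        [areas_by_day[d] for d in days],
        metadata=meta,
    )


class TestExtractLag:
    def test_high_density_crossing_at_day8(self):
        c = curve({3.0: 0, 6.0: 210, 8.0: 640, 10.0: 900})
        assert extract_lag(c) == Lag(8.0)

    def test_never_crossing_is_censored_at_last_day(self):
        c = curve({d: 100 for d in (3.0, 6.0, 8.0, 10.0, 14.0, 17.0, 20.0)})
        lag = extract_lag(c)
        assert lag.censored and lag.day == 20.0
        assert str(lag) == ">20"

    def test_threshold_must_be_strictly_exceeded(self):
        c = curve({6.0: 500, 8.0: 700})
        assert extract_lag(c) == Lag(8.0)

    def test_lowest_density_uses_low_threshold(self):
        c = curve({6.0: 300, 8.0: 700}, density="low")
        assert extract_lag(c) == Lag(6.0)
        assert extract_lag(curve({6.0: 300, 8.0: 700})) == Lag(8.0)

    def test_logistic_crossing_matches_dense_grid_oracle(self):
        """The discrete lag equals the first imaging day after the continuous
        crossing found by brute-force evaluation at dt = 0.01 d."""
        from spotlag.synthetic_data import drop_area_curve, sample_strain_models

        days = [3.0, 6.0, 8.0, 10.0, 14.0, 17.0, 20.0]
        for m in sample_strain_models(10, seed=5):
            for dose in (0.0, 0.1, 0.5):
                areas = drop_area_curve(m, dose, "high", np.asarray(days))
                c = curve(dict(zip(days, areas.astype(int))))
                lag = extract_lag(c)
                dense_t = np.arange(0.0, 20.0, 0.01)
                dense = drop_area_curve(m, dose, "high", dense_t)
                above = dense_t[dense > 500]
                if above.size == 0:
                    assert lag.censored
                else:
                    crossing = above[0]
                    expected = next((d for d in days if d > crossing), None)
                    if expected is None:
                        assert lag.censored
                    else:
                        assert lag.day == expected


class TestExtractAmax:
    def test_max_over_series(self):
        assert extract_amax(curve({3.0: 0, 6.0: 120, 8.0: 800})) == 800

    def test_all_zero(self):
        assert extract_amax(curve({3.0: 0, 6.0: 0})) == 0

    def test_plateau_recovered_from_rendered_truth(self, small_experiment):
        from spotlag.quantification import assemble_kinetics

        _, design, series, truth = small_experiment
        plate = design.plates[0]
        curves = assemble_kinetics(series[plate.plate_id], plate, design)
        tr = truth.drops.set_index("drop_id")
        for c in curves:
            expected = tr.loc[c.drop_id, "true_amax_px"]
            if expected > 0:
                assert extract_amax(c) == pytest.approx(expected, rel=0.05)


def record(strain="s", dose=0.05, lag=Lag(8.0), **kw):
    defaults = dict(
        drop_id="x", density_class="low", replicate=1, amax_px=1000
    )
    defaults.update(kw)
    return PhenotypeRecord(strain=strain, dose=dose, lag=lag, **defaults)


class TestNormalizeLag:
    def test_dose_delay_of_five_days(self):
        r = record(dose=0.05, lag=Lag(8.0))
        ctrl = record(dose=0.0, lag=Lag(3.0))
        assert normalize_lag(r, ctrl) == Lag(5.0)

    def test_self_normalization_is_zero(self):
        r = record(dose=0.0, lag=Lag(4.0))
        assert normalize_lag(r, r) == Lag(0.0)

    def test_censored_record_stays_censored(self):
        r = record(lag=Lag(20.0, censored=True))
        ctrl = record(dose=0.0, lag=Lag(4.0))
        out = normalize_lag(r, ctrl)
        assert out.censored and out.day == 16.0
        assert str(out) == ">16"

    def test_censored_control_is_undefined(self):
        r = record(lag=Lag(8.0))
        ctrl = record(dose=0.0, lag=Lag(20.0, censored=True))
        assert normalize_lag(r, ctrl) is None

    def test_mismatched_strain_raises(self):
        with pytest.raises(PairingError):
            normalize_lag(record(strain="a"), record(strain="b", dose=0.0))

    def test_nonzero_dose_control_raises(self):
        with pytest.raises(PairingError):
            normalize_lag(record(), record(dose=0.01))

    def test_wine_mode_requires_matching_residence_time(self):
        r = record(modality="ethanol14.5", residence_time_days=7)
        ctrl = record(dose=0.0, modality="original", residence_time_days=14)
        with pytest.raises(PairingError, match="residence"):
            normalize_lag(r, ctrl)


class TestClassifyProfile:
    def _curves(self, lag_by_dose, amax_by_dose):
        days = [3.0, 6.0, 8.0, 10.0, 14.0, 17.0, 20.0]
        out = {}
        for dose, lag in lag_by_dose.items():
            amax = amax_by_dose[dose]
            areas = {
                d: (amax if lag is not None and d >= lag else 0) for d in days
            }
            out[dose] = curve(areas, drop_id=f"dose{dose}")
        return out

    def test_inhibited_at_high_doses_is_low_tolerance(self):
        curves = self._curves(
            {0.0: 3.0, 0.1: 8.0, 0.25: None, 0.5: None},
            {0.0: 2000, 0.1: 1500, 0.25: 0, 0.5: 0},
        )
        assert classify_profile(curves) == "low_tolerance"

    def test_delayed_growth_everywhere_is_intermediate(self):
        curves = self._curves(
            {0.0: 3.0, 0.1: 6.0, 0.5: 10.0},
            {0.0: 2000, 0.1: 1800, 0.5: 1400},
        )
        assert classify_profile(curves) == "intermediate"

    def test_unchanged_growth_is_resistant(self):
        curves = self._curves(
            {0.0: 6.0, 0.1: 6.0, 0.5: 8.0},
            {0.0: 2000, 0.1: 2000, 0.5: 1900},
        )
        assert classify_profile(curves) == "resistant"

    def test_missing_dose_zero_raises(self):
        curves = self._curves(
            {0.1: 6.0, 0.25: 6.0, 0.5: 8.0},
            {0.1: 2000, 0.25: 2000, 0.5: 1900},
        )
        with pytest.raises(PairingError):
            classify_profile(curves)


class TestLagDistribution:
    def test_single_bin(self):
        recs = [record(drop_id=f"r{i}", lag=Lag(3.0)) for i in range(10)]
        dist = summarize_lag_distribution(recs, [3.0, 6.0, 9.0])
        assert dist.table["count"].sum() == 10
        assert len(dist.table) == 1

    def test_censored_records_get_their_own_bin(self):
        recs = [record(drop_id=f"o{i}", lag=Lag(6.0)) for i in range(4)] + [
            record(drop_id=f"c{i}", lag=Lag(20.0, censored=True)) for i in range(3)
        ]
        dist = summarize_lag_distribution(recs, [3.0, 6.0, 9.0])
        t = dist.table
        assert int(t.loc[t.lag_class == "censored", "count"].iloc[0]) == 3

    def test_fractions_sum_to_one_per_group_dose(self, rng):
        recs = [
            record(
                drop_id=f"r{i}",
                lag=Lag(float(rng.choice([3, 6, 8, 10]))),
                genetic_group=str(rng.choice(["A1", "D1"])),
                dose=float(rng.choice([0.0, 0.5])),
            )
            for i in range(60)
        ]
        t = summarize_lag_distribution(recs, [4.0, 7.0, 11.0]).table
        sums = t.groupby(["genetic_group", "dose"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_known_distribution_recovered_within_binomial_bounds(self, rng):
        """Class fractions from a known lag distribution stay inside the
        binomial 95% envelope."""
        p_fast = 0.7
        n = 400
        lags = rng.choice([3.0, 8.0], size=n, p=[p_fast, 1 - p_fast])
        recs = [record(drop_id=f"r{i}", lag=Lag(l)) for i, l in enumerate(lags)]
        t = summarize_lag_distribution(recs, [6.0]).table
        frac = float(t.loc[t.lag_class == "<6", "fraction"].iloc[0])
        se = math.sqrt(p_fast * (1 - p_fast) / n)
        assert abs(frac - p_fast) < 1.96 * se + 1e-9


class TestPipelineHelpers:
    def test_attach_normalized_lags_ypd_pairing(self):
        recs = [
            record(drop_id="c", dose=0.0, lag=Lag(3.0)),
            record(drop_id="t", dose=0.5, lag=Lag(10.0)),
        ]
        out = attach_normalized_lags(recs)
        by_id = {r.drop_id: r for r in out}
        assert by_id["t"].normalized_lag == Lag(7.0)
        assert by_id["c"].normalized_lag == Lag(0.0)

    def test_replicate_summary_takes_median(self):
        recs = [
            record(drop_id=f"r{i}", replicate=i + 1, lag=Lag(l), amax_px=a)
            for i, (l, a) in enumerate([(6.0, 900), (8.0, 1000), (8.0, 1200)])
        ]
        out = summarize_replicates(recs)
        assert len(out) == 1
        assert out[0].lag == Lag(8.0)
        assert out[0].amax_px == 1000

    def test_curves_to_records_carries_metadata(self):
        c = curve({3.0: 0, 6.0: 900}, strain="sX", dose=0.1, genetic_group="D2")
        r = curves_to_records([c])[0]
        assert (r.strain, r.dose, r.genetic_group) == ("sX", 0.1, "D2")
        assert r.lag == Lag(6.0) and r.amax_px == 900

    def test_dose_monotone_lag_on_clean_generator(self):
        """With a dose-monotone lag-extension law, extracted lags never
        decrease with dose on noise-free synthetic curves."""
        from spotlag.synthetic_data import drop_area_curve, sample_strain_models

        days = np.array([3.0, 6.0, 8.0, 10.0, 14.0, 17.0, 20.0])
        for m in sample_strain_models(8, seed=9):
            prev = -math.inf
            for dose in (0.0, 0.01, 0.1, 0.5):
                areas = drop_area_curve(m, dose, "low", days)
                c = curve(dict(zip(days, areas.astype(int))), density="low")
                lag = extract_lag(c)
                val = math.inf if lag.censored else lag.day
                assert val >= prev
                prev = val
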