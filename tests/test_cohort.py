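"""Cohort generator: schema fidelity, sampling calibration, trajectories,
labels, missingness and round-trip persistence."""

import logging
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import nfabt
from nfabt.cohort import (
    PatientRecord,
    RiskParams,
    assign_daily_labels,
    inject_missingness,
    read_cohort,
    risk_score,
    sample_cohort,
    sample_trajectories,
    write_cohort,
)
from nfabt.schema import HIGH_MISSINGNESS_FEATURES, CohortSchema, FeatureSpec


class TestSchema:
    def test_default_schema_counts(self, default_schema):
        assert len(default_schema.features) == 61
        assert default_schema.n_default == 98
        high = [f.name for f in default_schema.features if f.missing_rate > 0.9]
        assert sorted(high) == sorted(HIGH_MISSINGNESS_FEATURES)
        assert len(high) == 8

    def test_hemoglobin_parameters(self, default_schema):
        hgb = default_schema["hgb"]
        assert hgb.mean == 8.93 and hgb.sd == 2.50

    def test_unique_names_enforced(self, default_schema):
        f = default_schema["hgb"]
        with pytest.raises(ValueError, match="unique"):
            CohortSchema(features=default_schema.features + (f,))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("x", "lab1", "continuous", mean=1.0, sd=-1.0)
        with pytest.raises(ValueError):
            FeatureSpec("x", "lab1", "continuous", mean=1.0, sd=1.0, missing_rate=1.5)
        with pytest.raises(ValueError):
            FeatureSpec("x", "lab1", "binary")  # no category counts


class TestSampling:
    def test_cohort_size_and_determinism(self, default_schema):
        a = sample_cohort(default_schema, n=98, seed=1)
        b = sample_cohort(default_schema, n=98, seed=1)
        assert len(a) == 98
        for ra, rb in zip(a.records, b.records):
            assert ra.static == rb.static
            for k in ra.series:
                np.testing.assert_array_equal(ra.series[k], rb.series[k])

    def test_quota_mode_reproduces_demographic_counts(self, default_schema):
        c = sample_cohort(default_schema, n=98, seed=5)
        for spec in default_schema.by_group("demographic"):
            counts = Counter(r.static[spec.name] for r in c.records)
            assert dict(counts) == dict(spec.category_counts), spec.name

    def test_invalid_n(self, default_schema):
        with pytest.raises(ValueError):
            sample_cohort(default_schema, n=0, seed=1)

    def test_continuous_moments_match_generating_distribution(self, default_schema):
        """At n=10,000, sample mean/SD of every continuous feature sit
        within 3 standard errors of its generating distribution's moments
        (truncated-normal moments; plain moments for the coupled Hct)."""
        n = 10_000
        c = sample_cohort(default_schema, n=n, seed=2)
        base = c.baseline_frame()
        for spec in default_schema.continuous():
            vals = base[spec.name].to_numpy(dtype=float)
            if spec.couple_to is None:
                lo, hi = spec.range
                a, b = (lo - spec.mean) / spec.sd, (hi - spec.mean) / spec.sd
                m, v = stats.truncnorm.stats(a, b, loc=spec.mean, scale=spec.sd, moments="mv")
                m, sd = float(m), float(np.sqrt(v))
            else:
                m, sd = spec.mean, spec.sd
            se_mean = sd / np.sqrt(n)
            se_sd = sd / np.sqrt(2 * n)
            assert abs(vals.mean() - m) < 3 * se_mean, spec.name
            assert abs(vals.std(ddof=1) - sd) < 3.5 * se_sd, spec.name

    def test_values_respect_plausible_ranges(self, default_schema):
        c = sample_cohort(default_schema, n=500, seed=3)
        for spec in default_schema.continuous():
            lo, hi = spec.range
            vals = np.array([r.series[spec.name][0] for r in c.records])
            assert vals.min() >= lo and vals.max() <= hi, spec.name

    def test_hct_tracks_hgb(self, default_schema):
        c = sample_cohort(default_schema, n=2000, seed=4)
        hgb = np.array([r.series["hgb"][0] for r in c.records])
        hct = np.array([r.series["hct"][0] for r in c.records])
        assert np.corrcoef(hgb, hct)[0, 1] > 0.8


class TestTrajectories:
    def test_single_day_equals_baseline(self, default_schema):
        c = sample_cohort(default_schema, n=5, seed=1)
        t = sample_trajectories(c, horizon=1, seed=2)
        for r0, r1 in zip(c.records, t.records):
            for k in r0.series:
                np.testing.assert_array_equal(r0.series[k], r1.series[k])

    @pytest.mark.parametrize("autocorr", [0.0, 0.8])
    def test_lag1_autocorrelation(self, default_schema, autocorr):
        c = sample_cohort(default_schema, n=5, seed=1)
        t = sample_trajectories(c, horizon=500, autocorr=autocorr, seed=2)
        rs = []
        for r in t.records:
            x = r.series["hgb"]
            x = x - x.mean()
            rs.append(np.dot(x[1:], x[:-1]) / np.dot(x, x))
        mean_r = np.mean(rs)
        assert abs(mean_r - autocorr) < 0.1

    def test_invalid_autocorr(self, default_schema):
        c = sample_cohort(default_schema, n=2, seed=1)
        with pytest.raises(ValueError):
            sample_trajectories(c, horizon=5, autocorr=1.0)


def _record_with(hgb, pao2, ph, T=1):
    r = PatientRecord(id="X")
    r.series = {
        "hgb": np.full(T, float(hgb)),
        "pao2": np.full(T, float(pao2)),
        "ph": np.full(T, float(ph)),
    }
    return r


class TestLabels:
    def _tiny(self, hgb, pao2, ph):
        schema = nfabt.build_default_schema()
        return nfabt.Cohort(schema=schema, records=[_record_with(hgb, pao2, ph)], seed=0)

    def test_threshold_mode_healthy_and_sick_extremes(self):
        p = RiskParams(mode="threshold")
        healthy = assign_daily_labels(self._tiny(16.0, 75.0, 7.40), p)
        sick = assign_daily_labels(self._tiny(7.2, 42.0, 7.25), p)
        assert healthy.records[0].labels[0] == 0
        assert sick.records[0].labels[0] == 1

    def test_threshold_mode_matches_score_oracle(self):
        """The documented oracle: label 1 iff the intercept-free linear
        risk score exceeds the threshold."""
        p = RiskParams(mode="threshold")
        for hgb, pao2, ph in [(7.2, 42, 7.25), (10, 50, 7.38), (8.93, 34.54, 7.40)]:
            s = float(risk_score(np.array([hgb]), np.array([pao2]), np.array([ph]))[0])
            got = assign_daily_labels(self._tiny(hgb, pao2, ph), p).records[0].labels[0]
            assert got == int(s > p.threshold)

    def test_risk_monotone_in_hgb(self):
        hgbs = np.linspace(4, 18, 50)
        s = risk_score(hgbs, np.full(50, 34.54), np.full(50, 7.35))
        assert np.all(np.diff(s) < 0)  # lower Hgb -> higher risk

    def test_daily_prevalence_near_seven_percent(self):
        c = nfabt.make_cohort(n=2000, horizon=7, seed=13, missingness=False)
        labs = np.concatenate([r.labels for r in c.records])
        assert abs(labs.mean() - 0.07) < 0.02

    def test_missing_required_feature_raises(self):
        schema = nfabt.build_default_schema()
        r = PatientRecord(id="X", series={"hgb": np.ones(3)})
        c = nfabt.Cohort(schema=schema, records=[r], seed=0)
        with pytest.raises(ValueError, match="pao2"):
            assign_daily_labels(c, RiskParams(mode="threshold"))

    def test_trend_mode_flags_hgb_drops(self):
        schema = nfabt.build_default_schema()
        r = PatientRecord(id="X")
        r.series = {"hgb": np.array([10.0, 8.5, 8.4, 6.9])}
        c = nfabt.Cohort(schema=schema, records=[r], seed=0)
        out = assign_daily_labels(c, RiskParams(mode="trend", trend_drop=1.0))
        np.testing.assert_array_equal(out.records[0].labels, [0, 1, 0, 1])


class TestMissingness:
    def test_zero_rate_identity(self, default_schema):
        schema = CohortSchema(
            features=tuple(
                FeatureSpec(**{**f.to_dict(), "missing_rate": 0.0}) for f in default_schema.features
            ),
            n_default=98,
        )
        c = sample_trajectories(sample_cohort(schema, n=5, seed=1), horizon=3, seed=2)
        m = inject_missingness(c, seed=3)
        for r0, r1 in zip(c.records, m.records):
            for k in r0.series:
                np.testing.assert_array_equal(r0.series[k], r1.series[k])

    @pytest.mark.parametrize("rate,tol", [(1.0, 0.0), (0.95, 0.01)])
    def test_observed_missing_fraction(self, rate, tol):
        spec = FeatureSpec("x", "lab1", "continuous", mean=0.0, sd=1.0,
                           missing_rate=rate, time_varying=True)
        schema = CohortSchema(features=(spec,), n_default=10)
        c = sample_trajectories(sample_cohort(schema, n=100, seed=1), horizon=100, seed=2)
        m = inject_missingness(c, seed=3)
        vals = np.concatenate([r.series["x"] for r in m.records])
        frac = np.isnan(vals).mean()
        assert abs(frac - rate) <= tol


class TestPersistence:
    def test_round_trip_identity(self, tmp_path, missing_cohort):
        sub = nfabt.Cohort(
            schema=missing_cohort.schema, records=missing_cohort.records[:5], seed=11
        )
        path = tmp_path / "cohort.csv"
        write_cohort(sub, str(path))
        back = read_cohort(str(path))
        assert len(back) == 5
        for r0, r1 in zip(sub.records, back.records):
            assert r0.static == r1.static
            for k in r0.series:
                np.testing.assert_allclose(r0.series[k], r1.series[k], equal_nan=True)
            np.testing.assert_array_equal(r0.labels, r1.labels)

    def test_duplicate_rows_rejected(self, tmp_path, small_cohort):
        path = tmp_path / "c.csv"
        sub = nfabt.Cohort(schema=small_cohort.schema, records=small_cohort.records[:2], seed=7)
        write_cohort(sub, str(path))
        text = path.read_text().splitlines()
        text.append(text[1])
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(str(path))

    def test_out_of_range_value_logged(self, tmp_path, small_cohort, caplog):
        path = tmp_path / "c.csv"
        sub = nfabt.Cohort(schema=small_cohort.schema, records=small_cohort.records[:1], seed=7)
        sub = sub.copy()
        sub.records[0].series["ph"][0] = 9.9  # outside any plausible pH
        write_cohort(sub, str(path))
        with caplog.at_level(logging.WARNING, logger="nfabt.cohort"):
            read_cohort(str(path))
        assert any("plausible range" in m for m in caplog.messages)
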