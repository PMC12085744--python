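"""Generator behavior: determinism, parameter recovery, control knobs, IO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import temprhythm as tr
from temprhythm import ConfigurationError, SimulationConfig


def _noiseless(seed=1, n_days=7, **kw):
    base = dict(
        n_days=n_days, frag_noise_sd=0.0, phase_jitter_sd=0.0, nonwear_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tmp_path):
        cfg = SimulationConfig(mesor=30, amplitude=2, acrophase=-1.45, n_days=7, seed=1)
        a = tr.generate_subject(cfg)
        b = tr.generate_subject(cfg)
        np.testing.assert_array_equal(a.temperature.values, b.temperature.values)
        np.testing.assert_array_equal(a.temperature.wear, b.temperature.wear)
        np.testing.assert_array_equal(a.activity.values, b.activity.values)
        tr.write_subject_csvs(a, tmp_path / "a")
        tr.write_subject_csvs(b, tmp_path / "b")
        for name in ("S0001_temperature.csv", "S0001_activity.csv", "S0001_sleep.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = tr.generate_subject(SimulationConfig(n_days=5, seed=1))
        b = tr.generate_subject(SimulationConfig(n_days=5, seed=2))
        assert not np.array_equal(a.temperature.values, b.temperature.values)


@pytest.mark.parametrize(
    "field,value",
    [
        ("amplitude", -0.5),
        ("sleep_frag_prob", 1.5),
        ("n_days", 0),
        ("quantization", 0.0),
        ("nonwear_rate", -1.0),
        ("sleep_duration", 25.0),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(SimulationConfig(), **{field: value})
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        tr.generate_subject(cfg)


def test_noiseless_roundtrip_recovers_parameters():
    """Zero noise/jitter/non-wear: the full processing chain recovers mesor,
    amplitude and acrophase to within half the sensor quantization."""
    cfg = _noiseless(mesor=30.0, amplitude=2.0, acrophase=-1.45)
    rec = tr.generate_subject(cfg)
    # quantized to the 0.25 °C grid
    assert np.allclose(rec.temperature.values / 0.25,
                       np.round(rec.temperature.values / 0.25))
    clean = tr.exclude_nonwear_days(tr.aggregate_to_bins(rec.temperature, 15))
    fit = tr.fit_cosinor(tr.fold_average_profile(clean, 15))
    tol = 0.5 * cfg.quantization
    assert abs(fit.mesor - 30.0) < tol
    assert abs(fit.amplitude - 2.0) < tol
    assert abs(fit.acrophase - (-1.45)) < tol


class TestControlKnobs:
    """Monte-Carlo ordering: each generator knob moves its target metric."""

    N_SEEDS = 200

    def test_phase_jitter_lowers_is(self):
        vals = {0.0: [], 0.5: []}
        for seed in range(self.N_SEEDS):
            for jit in vals:
                rec = tr.generate_subject(
                    _noiseless(seed=seed, n_days=6, phase_jitter_sd=jit,
                               frag_noise_sd=0.5)
                )
                s = tr.aggregate_to_bins(rec.temperature, 15)
                vals[jit].append(tr.interdaily_stability(s))
        assert np.mean(vals[0.5]) < np.mean(vals[0.0])

    def test_frag_noise_raises_iv(self):
        vals = {0.5: [], 4.0: []}
        for seed in range(self.N_SEEDS):
            for sd in vals:
                rec = tr.generate_subject(
                    _noiseless(seed=seed, n_days=6, frag_noise_sd=sd)
                )
                s = tr.aggregate_to_bins(rec.temperature, 15)
                vals[sd].append(tr.intradaily_variability(s))
        assert np.mean(vals[4.0]) > np.mean(vals[0.5])

    def test_sleep_jitter_lowers_sri(self):
        vals = {0.0: [], 2.0: []}
        for seed in range(self.N_SEEDS):
            for jit in vals:
                rec = tr.generate_subject(
                    _noiseless(seed=seed, n_days=6, sleep_jitter_sd=jit)
                )
                vals[jit].append(tr.sleep_regularity_index(rec.sleep_state))
        assert np.mean(vals[2.0]) < np.mean(vals[0.0])


class TestInjectNonwear:
    def test_rate_zero_is_identity(self, make_series):
        s = make_series(np.full(96, 30.0), epoch_s=900)
        out = tr.inject_nonwear(s, rate=0.0, dropout=3.0, seed=1)
        np.testing.assert_array_equal(out.values, s.values)
        np.testing.assert_array_equal(out.wear, s.wear)

    def test_flags_consistent_with_day_exclusion(self, make_series):
        s = make_series(np.full(7 * 96, 30.0), epoch_s=900)
        out = tr.inject_nonwear(s, rate=1.0, dropout=3.0, seed=3)
        flagged_days = set(np.unique(out.day_index[~out.wear]))
        assert flagged_days  # at least one day carries a non-wear flag
        clean = tr.exclude_nonwear_days(out)
        assert set(np.unique(clean.day_index)) == (
            set(np.unique(out.day_index)) - flagged_days
        )
        assert len(clean) % clean.epochs_per_day == 0

    def test_post_rewear_depression_matches_dropout(self, make_series):
        diffs = []
        for seed in range(100):
            s = make_series(np.full(5 * 96, 30.0), epoch_s=900)
            out = tr.inject_nonwear(s, rate=0.5, dropout=3.0, seed=seed)
            depressed = out.values[out.wear & (out.values < 30.0)]
            if len(depressed):
                diffs.append(30.0 - depressed.mean())
        assert diffs, "expected at least some recovery windows over 100 seeds"
        assert abs(np.mean(diffs) - 3.0) < 0.2


class TestCohort:
    def test_minimal_cohort(self):
        preset = tr.mood_cohort_preset(n_control=1, n_case=1, n_days=5)
        records, meta = tr.generate_cohort(preset, seed=1)
        assert len(records) == 2 and len(meta) == 2
        assert set(meta["cohort"]) == {"control", "case"}
        case = meta[meta.cohort == "case"].iloc[0]
        assert case["subtype"] != "" and case["stage"] != ""
        ctrl = meta[meta.cohort == "control"].iloc[0]
        assert ctrl["subtype"] == "" and ctrl["stage"] == ""

    def test_empty_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            tr.generate_cohort(tr.CohortPreset(groups=[]), seed=0)

    def test_case_mesor_lower_in_most_seeds(self):
        """Injected -1.1 °C mesor delta: case group mean below control in
        (almost) every replicate at modest n."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            records, meta = tr.generate_cohort(
                tr.mood_cohort_preset(12, 12, n_days=5), seed=seed
            )
            means = {"control": [], "case": []}
            for rec in records:
                w = rec.temperature.wear
                means[rec.metadata["cohort"]].append(rec.temperature.values[w].mean())
            wins += np.mean(means["case"]) < np.mean(means["control"])
        assert wins >= n_seeds - 1

    def test_null_cohort_type1_error_near_nominal(self):
        """Zero-delta preset: downstream ANCOVA on the mesor rejects at about
        the nominal 5% rate."""
        rej = 0
        n_seeds = 80
        for seed in range(n_seeds):
            records, meta = tr.generate_cohort(
                tr.null_cohort_preset(12, n_days=5), seed=seed
            )
            rows = []
            for rec in records:
                fit = tr.fit_cosinor(tr.aggregate_to_bins(rec.temperature, 15))
                rows.append({**rec.metadata, "mesor": fit.mesor})
            gc = tr.ancova_compare(pd.DataFrame(rows), "mesor", group="cohort",
                                   boxcox=False)
            rej += gc.p_value < 0.05
        assert 0 <= rej / n_seeds <= 0.125


def test_subject_csv_roundtrip(tmp_path):
    rec = tr.generate_subject(SimulationConfig(n_days=5, seed=9))
    tr.write_subject_csvs(rec, tmp_path)
    back = tr.read_subject_csvs(tmp_path, rec.subject_id)
    np.testing.assert_allclose(back.temperature.values, rec.temperature.values)
    np.testing.assert_array_equal(back.temperature.wear, rec.temperature.wear)
    np.testing.assert_allclose(back.activity.values, rec.activity.values)
    assert len(back.sleep_windows) == len(rec.sleep_windows)
    assert back.sleep_windows[0].onset == rec.sleep_windows[0].onset
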