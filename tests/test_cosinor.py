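"""Cosinor fitting: exactness, conventions, recovery, group mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import temprhythm as tr
from temprhythm import RankDeficiencyError, SimulationConfig


def _cosine(t, M=30.0, A=2.0, phi=-1.45):
    return M + A * np.cos(2 * np.pi * t / 24 + phi)


class TestFitCosinor:
    def test_exact_on_noiseless_model(self):
        t = np.arange(0, 24, 0.25)
        fit = tr.fit_cosinor((t, _cosine(t)))
        assert abs(fit.mesor - 30.0) / 30.0 < 1e-12
        assert abs(fit.amplitude - 2.0) / 2.0 < 1e-12
        assert abs(fit.acrophase - (-1.45)) / 1.45 < 1e-12
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_phase_peak_at_midnight(self):
        t = np.arange(0, 24, 0.25)
        fit = tr.fit_cosinor((t, _cosine(t, phi=0.0)))
        assert fit.acrophase == pytest.approx(0.0, abs=1e-12)
        assert fit.acrotime == pytest.approx(0.0, abs=1e-10)

    def test_constant_signal(self):
        t = np.arange(0, 24, 0.25)
        fit = tr.fit_cosinor((t, np.full_like(t, 30.0)))
        assert fit.mesor == pytest.approx(30.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(fit.acrophase) and np.isnan(fit.acrotime)

    def test_degenerate_times_raise(self):
        with pytest.raises(RankDeficiencyError):
            tr.fit_cosinor((np.zeros(10), np.arange(10.0)))

    def test_monte_carlo_recovery_unbiased(self, rng):
        """With unit Gaussian noise over 7 days the mean estimates are
        essentially unbiased."""
        t = np.arange(0, 7 * 24, 0.25)
        est = []
        for _ in range(150):
            y = _cosine(t) + rng.normal(0, 1, len(t))
            fit = tr.fit_cosinor((t, y))
            est.append([fit.mesor, fit.amplitude, fit.acrophase])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 30.0) < 0.03
        assert abs(mean[1] - 2.0) < 0.03
        assert abs(mean[2] - (-1.45)) < 0.03

    def test_time_shift_equivariance(self, make_series, rng):
        vals = _cosine(np.arange(96) * 0.25, phi=-1.0) + rng.normal(0, 0.3, 96)
        a = make_series(vals, epoch_s=900)
        b = make_series(vals, epoch_s=900, start="2024-01-01 03:00:00")
        fa, fb = tr.fit_cosinor(a), tr.fit_cosinor(b)
        assert fb.mesor == pytest.approx(fa.mesor)
        assert fb.amplitude == pytest.approx(fa.amplitude)
        expected = fa.acrophase - 2 * np.pi * 3 / 24
        diff = (fb.acrophase - expected) % (2 * np.pi)
        assert min(diff, 2 * np.pi - diff) < 1e-9

    def test_mesor_invariance_under_offset(self, rng):
        t = np.arange(0, 48, 0.25)
        y = _cosine(t) + rng.normal(0, 0.5, len(t))
        fa = tr.fit_cosinor((t, y))
        fb = tr.fit_cosinor((t, y + 5.0))
        assert fb.mesor == pytest.approx(fa.mesor + 5.0)
        assert fb.amplitude == pytest.approx(fa.amplitude)
        assert fb.acrophase == pytest.approx(fa.acrophase)


class TestAcrotime:
    @pytest.mark.parametrize("phi,hours", [(0.0, 0.0), (-np.pi, 12.0)])
    def test_reference_phases(self, phi, hours):
        assert tr.acrophase_to_acrotime(phi) == pytest.approx(hours)

    def test_early_morning_peak(self):
        # -1.45 rad pairs with a ~05:33 peak clock time
        minutes = tr.acrophase_to_acrotime(-1.45) * 60
        assert abs(minutes - (5 * 60 + 33)) <= 2

    def test_undefined_propagates(self):
        assert np.isnan(tr.acrophase_to_acrotime(float("nan")))

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-10, 10))
    def test_range_and_periodicity(self, phi):
        h = tr.acrophase_to_acrotime(phi)
        assert 0 <= h < 24
        assert tr.acrophase_to_acrotime(phi - 2 * np.pi) == pytest.approx(h, abs=1e-9)


class TestGoodness:
    def test_perfect_fit(self):
        t = np.arange(0, 24, 0.25)
        fit = tr.fit_cosinor((t, _cosine(t)))
        r2, rmse, mae = tr.fit_goodness(fit, (t, _cosine(t)))
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert mae == pytest.approx(0.0, abs=1e-9)

    def test_null_signal_r2_near_zero(self, rng):
        t = np.arange(0, 24 * 21, 0.25)
        r2s = [
            tr.fit_cosinor((t, rng.normal(30, 1, len(t)))).r2 for _ in range(20)
        ]
        assert 0 <= np.mean(r2s) < 0.01  # E[R2] ~ 2/n under the null

    def test_rmse_matches_noise_sd(self, rng):
        t = np.arange(0, 24 * 30, 0.25)
        y = _cosine(t) + rng.normal(0, 0.7, len(t))
        fit = tr.fit_cosinor((t, y))
        assert fit.rmse == pytest.approx(0.7, rel=0.03)


def _profile_frame(records, label_of):
    parts = []
    for rec in records:
        prof = tr.fold_average_profile(
            tr.aggregate_to_bins(rec.temperature, 15), 15
        )
        parts.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "group": label_of[rec.subject_id],
            "t_hours": prof.bin_center_hours,
            "value": prof.mean_value,
        }))
    return pd.concat(parts, ignore_index=True)


def _cohort(n_per_group, seed, dmesor=0.0, dacro=0.0, mesor_sd=0.5, n_days=5):
    preset = tr.CohortPreset(
        base=SimulationConfig(
            n_days=n_days, mesor=31.0, acrophase=-0.93,
            phase_jitter_sd=0.0, frag_noise_sd=2.0, nonwear_rate=0.0,
        ),
        groups=[
            tr.GroupSpec("control", n_per_group),
            tr.GroupSpec("case", n_per_group,
                         deltas={"mesor": dmesor, "acrophase": dacro}),
        ],
        subject_sd={"mesor": mesor_sd},
    )
    records, meta = tr.generate_cohort(preset, seed=seed)
    label_of = dict(zip(meta.subject_id, meta.cohort))
    return _profile_frame(records, label_of)


class TestGroupCosinor:
    def test_null_contrasts_within_se(self):
        frame = _cohort(10, seed=11)
        model = tr.fit_group_cosinor(frame)
        c = model.contrasts[("case", "control")]
        assert abs(c["d_mesor"]) < 3 * c["se_mesor"]
        assert abs(c["d_acrophase"]) < 3 * c["se_acrophase"]

    def test_recovery_within_2se_coverage(self):
        """Injected mesor/acrophase deltas are recovered within 2 SE in the
        vast majority of replicates."""
        hits_m = hits_p = 0
        n_seeds = 30
        for seed in range(n_seeds):
            frame = _cohort(10, seed=seed, dmesor=-1.1, dacro=-0.52)
            model = tr.fit_group_cosinor(frame)
            # contrast is (case, control) = control minus case
            c = model.contrasts[("case", "control")]
            hits_m += abs(c["d_mesor"] - 1.1) <= 2 * c["se_mesor"]
            hits_p += abs(c["d_acrophase"] - 0.52) <= 2 * c["se_acrophase"]
        assert hits_m >= 24
        assert hits_p >= 24

    def test_reduces_to_fixed_effects_without_heterogeneity(self):
        frame = _cohort(6, seed=5, mesor_sd=0.0, n_days=7)
        model = tr.fit_group_cosinor(frame)
        assert model.random_intercept_var < 0.02
        for g in ("control", "case"):
            sub = frame[frame.group == g]
            pooled = tr.fit_cosinor(
                (sub.t_hours.to_numpy(), sub.value.to_numpy())
            )
            assert model.groups[g]["mesor"] == pytest.approx(pooled.mesor, abs=1e-3)
            assert model.groups[g]["amplitude"] == pytest.approx(
                pooled.amplitude, abs=1e-3
            )
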