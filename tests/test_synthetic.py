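"""Simulator contracts: timing, ground truth, determinism, recoverability."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from dyadcausal import io as dio
from dyadcausal.synthetic import (
    SimulationConfig,
    canonical_hrf,
    make_dataset,
    simulate_dyad,
    truth_frame,
)


class TestCanonicalHrf:
    def test_zero_at_onset_and_before(self):
        assert canonical_hrf(0.0) == 0.0
        assert canonical_hrf(-1.0) == 0.0

    def test_unit_peak_at_peak_delay(self):
        t = np.linspace(0, 40, 4001)
        h = canonical_hrf(t, peak_delay=6.0)
        assert h.max() == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=0.02)

    def test_integral_positive_finite(self):
        t = np.linspace(0, 60, 6001)
        area = np.trapezoid(canonical_hrf(t), t)
        assert np.isfinite(area) and area > 0


class TestSimulateDyad:
    def test_default_epoch_counts(self, small_config):
        rec, events, truth = simulate_dyad(SimulationConfig(), seed=0)
        for cond in ("hand", "foot"):
            eps = dio.extract_epochs(rec, events, "M1", conditions=[cond])
            assert len(eps) == 10
            assert all(e.n_samples == 204 for e in eps)
            assert all(e.fs == pytest.approx(10.17) for e in eps)

    def test_events_and_truth_aligned(self, small_config):
        rec, events, truth = simulate_dyad(small_config, seed=1)
        assert len(events) == len(truth)
        for row, g in zip(events.frame.itertuples(index=False), truth):
            assert row.condition == g.condition
            if g.condition == "baseline":
                assert g.true_direction == "none"
            else:
                assert g.true_direction == "M_to_I"
                assert g.lag >= small_config.coupling_lag

    def test_uncoupled_truth_all_none(self, small_config):
        cfg = dataclasses.replace(small_config, coupling_gain=0.0)
        _, _, truth = simulate_dyad(cfg, seed=2)
        assert all(g.true_direction == "none" for g in truth)

    def test_reproducible_from_seed(self, small_config):
        a, ea, _ = simulate_dyad(small_config, seed=7)
        b, eb, _ = simulate_dyad(small_config, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert ea.frame.equals(eb.frame)
        c, _, _ = simulate_dyad(small_config, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_sdc_channels_have_no_task_response(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.01,
                                  confounder_amplitude=0.01)
        rec, events, _ = simulate_dyad(cfg, seed=3)
        sdc_cols = [i for i, ch in enumerate(rec.channel_labels)
                    if rec.region_map[ch] == "SDC"]
        m1_cols = [i for i, ch in enumerate(rec.channel_labels)
                   if rec.region_map[ch] == "M1"]
        assert rec.samples[:, sdc_cols].std() < 0.1 * rec.samples[:, m1_cols].std()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(coupling_lag=0)
        with pytest.raises(ValueError):
            SimulationConfig(task_duration=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(confounder_freq=6.0)


class TestTaskComponentConstruction:
    def clean_components(self, cfg, seed):
        """Re-derive the noise-free task components by silencing nuisances."""
        quiet = dataclasses.replace(cfg, noise_sd=1e-9, background_sd=1e-9,
                                    confounder_amplitude=0.0,
                                    drive_noise_sd=0.0)
        return simulate_dyad(quiet, seed=seed)

    def test_peak_crosscorrelation_at_constructed_lag(self, small_config):
        """Construction oracle: the clean Imitator task component is the
        Model component delayed by coupling_lag + onset_delay * fs."""
        rec, events, truth = self.clean_components(small_config, seed=4)
        for cond in ("hand", "foot"):
            expected = small_config.total_lag(cond)
            m = rec.samples[:, 0]
            i = rec.samples[:, rec.channel_labels.index("I_M1_1")]
            xc = sps.correlate(i, m, mode="full")
            lags = sps.correlation_lags(len(i), len(m), mode="full")
            best = lags[np.argmax(xc)]
            # the whole-recording xcorr mixes both conditions; the peak must
            # sit within the constructed delay range
            assert small_config.total_lag("hand") <= best <= \
                small_config.total_lag("foot")

    def test_direction_recoverable_from_clean_components(self, small_config):
        """Sanity floor: with nuisances silenced, per-epoch cross-correlation
        identifies Model -> Imitator in every task epoch."""
        rec, events, truth = self.clean_components(small_config, seed=5)
        hits = n = 0
        for ep in dio.extract_epochs(rec, events, "M1",
                                     conditions=["hand", "foot"]):
            m = ep.data[:, :3].mean(axis=1)
            i = ep.data[:, 3:].mean(axis=1)
            best_lag, best_r = 0, -np.inf
            for lag in range(-40, 41):
                if lag >= 0:
                    a, b = m[: len(m) - lag or None], i[lag:]
                else:
                    a, b = m[-lag:], i[: len(i) + lag]
                a, b = a - a.mean(), b - b.mean()
                denom = np.sqrt((a * a).sum() * (b * b).sum())
                if denom == 0:
                    continue
                r = (a * b).sum() / denom
                if r > best_r:
                    best_r, best_lag = r, lag
            hits += best_lag > 0
            n += 1
        assert hits / n > 0.95

    def test_task_power_within_analysis_band(self, small_config):
        """> 90% of task-component power lies below 0.2 Hz."""
        rec, _, _ = self.clean_components(small_config, seed=6)
        x = rec.samples[:, 0] - rec.samples[:, 0].mean()
        freqs, pxx = sps.periodogram(x, fs=rec.fs)
        assert pxx[freqs <= 0.2].sum() / pxx.sum() > 0.9


class TestMakeDataset:
    def test_counts(self):
        data = make_dataset(10, SimulationConfig(n_trials_per_condition=10),
                            seed=0)
        assert len(data) == 10
        total_task = sum(
            len(dio.extract_epochs(rec, ev, "M1", conditions=["hand", "foot"]))
            for rec, ev, _ in data)
        assert total_task == 200

    def test_master_seed_determinism(self, small_config):
        a = make_dataset(2, small_config, seed=42)
        b = make_dataset(2, small_config, seed=42)
        for (ra, _, _), (rb, _, _) in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_dyads_correlate_only_through_shared_task_schedule(
            self, small_config):
        """Distinct dyads' stochastic parts are independent: their channel
        correlation matches the confounder-free expectation induced by the
        common deterministic task timing (clean-component correlation scaled
        by the per-dyad task-to-total variance ratios)."""
        cfg = dataclasses.replace(small_config, confounder_amplitude=0.0)
        data = make_dataset(4, cfg, seed=9)
        quiet = dataclasses.replace(cfg, noise_sd=1e-9, background_sd=1e-9,
                                    drive_noise_sd=0.0)
        clean = make_dataset(4, quiet, seed=9)
        resid = []
        for k in range(len(data) - 1):
            x, y = data[k][0].samples[:, 0], data[k + 1][0].samples[:, 0]
            cx, cy = clean[k][0].samples[:, 0], clean[k + 1][0].samples[:, 0]
            n = min(len(x), len(y))
            observed = np.corrcoef(x[:n], y[:n])[0, 1]
            expected = (np.corrcoef(cx[:n], cy[:n])[0, 1]
                        * cx[:n].std() / x[:n].std()
                        * cy[:n].std() / y[:n].std())
            resid.append(observed - expected)
        resid = np.array(resid)
        assert np.abs(resid).max() < 0.1
        assert abs(resid.mean()) < 0.05

    def test_truth_frame_layout(self, small_config):
        data = make_dataset(1, small_config, seed=1)
        frame = truth_frame(data[0][2])
        assert set(frame.columns) == {"dyad_id", "trial_index", "condition",
                                      "true_direction", "lag"}
        assert (frame.loc[frame.condition == "baseline",
                          "true_direction"] == "none").all()
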