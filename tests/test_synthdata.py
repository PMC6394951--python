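"""Oscillator generator: planted coupling, mixing, behavior scores."""

import numpy as np
import pytest
from scipy.signal import periodogram

from plinet.connectivity import instantaneous_phase, pli, connectivity_matrices
from plinet.inverse import LeadField
from plinet.synthdata import (SimConfig, load_sim_config, mix_to_sensors,
                              random_leadfield, save_sim_config,
                              simulate_behavior, simulate_event_log,
                              simulate_sources)

from conftest import make_sim

TRIM = 200  # analytic-signal edge samples discarded before PLI


def planted_pli(kappa, lag=np.pi / 4, epochs=30, seed=1):
    """Mean per-epoch PLI on the planted edge and on an uncoupled pair."""
    cfg = make_sim([(0, 1, lag, kappa)], epochs=epochs, seed=seed)
    es = simulate_sources(cfg, 0, "c")
    ph = instantaneous_phase(es.data)[:, :, TRIM:-TRIM]
    vals = [pli(ph[e, 0], ph[e, 1]) for e in range(epochs)]
    null = [pli(ph[e, 0], ph[e, 2]) for e in range(epochs)]
    return float(np.mean(vals)), float(np.mean(null))


def vonmises_pli_oracle(kappa, lag, n_draws, n_epochs, seed=7):
    """Brute-force Monte-Carlo: per-epoch |mean sign(sin(lag + eps))| with
    eps ~ von Mises(0, kappa), independent of the generator under test."""
    r = np.random.default_rng(seed)
    eps = r.vonmises(0.0, kappa, size=(n_epochs, n_draws))
    reps = np.abs(np.mean(np.sign(np.sin(lag + eps)), axis=1))
    return reps.mean(), reps.std()


class TestPlantedCoupling:
    def test_large_kappa_gives_unit_pli(self):
        """Constant phase difference limit: PLI -> 1."""
        m, _ = planted_pli(kappa=1000.0)
        assert m > 0.99

    @pytest.mark.parametrize("kappa,lag", [(0.0, np.pi / 4), (2.0, np.pi / 2)])
    def test_pli_matches_von_mises_oracle(self, kappa, lag):
        """Downstream PLI agrees with the i.i.d. von Mises sign oracle.

        The jitter is held for 64 ms per draw, so an epoch contributes
        roughly (samples - trim) / hold independent draws; >= 1e5 oracle
        draws in total.
        """
        epochs = 60
        m, _ = planted_pli(kappa=kappa, lag=lag, epochs=epochs)
        n_draws = (2048 - 2 * TRIM) // 64
        mu, sd = vonmises_pli_oracle(kappa, lag, n_draws, n_epochs=5000)
        assert abs(m - mu) < 3 * sd

    def test_kappa_zero_pli_near_null_level(self):
        """Uniform jitter: planted-edge PLI falls to the sampling floor."""
        m, null = planted_pli(kappa=0.0, epochs=60)
        assert m < 0.3
        assert abs(m - null) < 0.1

    def test_pli_monotone_in_kappa(self):
        """Coupling concentration maps monotonically onto PLI."""
        vals = [planted_pli(k, epochs=30)[0] for k in (0.0, 1.0, 2.0, 4.0, 16.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestGeneratorContract:
    def test_deterministic_and_subject_stable(self):
        cfg = make_sim([(0, 1, 0.5, 4.0)], noise_sd=0.2)
        a = simulate_sources(cfg, "S01", "c").data
        b = simulate_sources(cfg, "S01", "c").data
        np.testing.assert_array_equal(a, b)
        other = simulate_sources(cfg, "S02", "c").data
        assert not np.array_equal(a, other)

    def test_adding_subjects_does_not_reshuffle(self):
        cfg5 = SimConfig(n_subjects=5, n_rois=3, conditions=("c",),
                         epochs_per_condition=3, seed=9, bands=((8., 12.),))
        cfg9 = SimConfig(n_subjects=9, n_rois=3, conditions=("c",),
                         epochs_per_condition=3, seed=9, bands=((8., 12.),))
        np.testing.assert_array_equal(simulate_sources(cfg5, "S03", "c").data,
                                      simulate_sources(cfg9, "S03", "c").data)

    def test_band_power_concentrated(self):
        """>80% of the signal power lies inside the nominal band."""
        cfg = make_sim([(0, 1, np.pi / 4, 8.0)], epochs=5)
        es = simulate_sources(cfg, 0, "c")
        f, p = periodogram(es.data, fs=cfg.fs, axis=-1)
        inband = p[..., (f >= 8.0) & (f <= 12.0)].sum(axis=-1)
        frac = inband / p.sum(axis=-1)
        assert frac.min() > 0.8

    def test_epoch_geometry(self):
        cfg = make_sim(None, epochs=4)
        es = simulate_sources(cfg, 0, "c")
        assert es.data.shape == (4, 3, 2048)
        assert es.n_samples == round(cfg.epoch_ms * cfg.fs / 1000.0)

    @pytest.mark.parametrize("bad", [
        dict(bands=((10.0, 600.0),)),              # beyond Nyquist
        dict(n_rois=1),
        dict(behavior_r=1.5),
        dict(planted_edges={"c": {0: [(0, 0, 0.1, 1.0)]}}),   # self edge
        dict(planted_edges={"c": {0: [(0, 5, 0.1, 1.0)]}}),   # out of range
        dict(planted_edges={"c": {0: [(0, 1, 0.1, -1.0)]}}),  # kappa < 0
    ])
    def test_invalid_config_rejected(self, bad):
        kw = dict(n_subjects=2, n_rois=3, conditions=("c",),
                  epochs_per_condition=2, bands=((8.0, 12.0),))
        kw.update(bad)
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = make_sim([(0, 1, 0.25, 3.0)], noise_sd=0.4)
        p = tmp_path / "sim.yaml"
        save_sim_config(cfg, p)
        back = load_sim_config(p)
        assert back == cfg


class TestSensorMixing:
    def test_identity_mixing(self):
        cfg = make_sim(None, epochs=2, noise_sd=0.1)
        src = simulate_sources(cfg, 0, "c")
        lf = LeadField(np.eye(3), src.labels, src.labels)
        mixed = mix_to_sensors(src, lf)
        np.testing.assert_allclose(mixed.data, src.data)

    def test_dimension_mismatch(self):
        cfg = make_sim(None, epochs=2)
        src = simulate_sources(cfg, 0, "c")
        lf = LeadField(np.ones((4, 5)), [f"R{v}" for v in range(5)])
        with pytest.raises(ValueError, match="voxel"):
            mix_to_sensors(src, lf)

    def test_single_source_dominance_gives_zero_pli(self, rng):
        """Two sensors seeing one source: zero-lag mixture, PLI ~ 0.

        Each sensor carries its own independent measurement noise, so the
        residual phase difference jitters symmetrically around zero and
        the sign averages out.
        """
        from plinet.epochs import EpochSet

        t = np.arange(2048) / 1000.0
        n_ep = 20
        data = np.empty((n_ep, 3, 2048))
        for e in range(n_ep):
            data[e, 0] = np.cos(2 * np.pi * 10 * t + rng.uniform(-np.pi, np.pi))
            data[e, 1] = rng.standard_normal(2048)
            data[e, 2] = rng.standard_normal(2048)
        src = EpochSet(data, fs=1000.0, labels=["osc", "noise1", "noise2"])
        gain = np.array([[1.0, 0.05, 0.0],
                         [0.7, 0.0, 0.05]])
        mixed = mix_to_sensors(src, LeadField(gain, src.labels))
        ph = instantaneous_phase(mixed.data)[:, :, TRIM:-TRIM]
        vals = [pli(ph[e, 0], ph[e, 1]) for e in range(n_ep)]
        assert np.mean(vals) < 0.1

    def test_mixing_does_not_create_pli(self, rng):
        """Dense zero-lag mixing of uncoupled sources cannot raise mean PLI."""
        cfg = make_sim(None, n_rois=5, epochs=40, noise_sd=1.0)
        src = simulate_sources(cfg, 0, "c")
        lf = random_leadfield(5, 5, seed=3)
        mixed = mix_to_sensors(src, lf)
        band = {"broad": (0.5, 45.0)}
        iu = np.triu_indices(5, 1)
        src_mean = connectivity_matrices(src, band)[0].values[iu].mean()
        mix_mean = connectivity_matrices(mixed, band)[0].values[iu].mean()
        # sampling error bound: null PLI spread over 10 averaged pairs
        assert mix_mean <= src_mean + 0.05


class TestBehaviorSimulation:
    def test_perfect_correlation_limit(self, rng):
        s = rng.standard_normal(25)
        y = simulate_behavior(s, r_target=1.0, seed=0)
        assert abs(np.corrcoef(s, y)[0, 1] - 1.0) < 1e-12

    @pytest.mark.parametrize("r_target", [0.0, 0.5])
    def test_mean_sample_r_recovers_target(self, r_target):
        n_rep = 1000
        rs = np.empty(n_rep)
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            s = r.standard_normal(25)
            rs[rep] = np.corrcoef(s, simulate_behavior(s, r_target, seed=rep))[0, 1]
        se = rs.std() / np.sqrt(n_rep)
        assert abs(rs.mean() - r_target) < 3 * se

    def test_constant_strengths_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simulate_behavior(np.ones(10), 0.5, seed=0)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            simulate_behavior(np.array([1.0, 2.0]), 0.5, seed=0)


class TestEventLogSimulation:
    def test_counts_and_determinism(self):
        log = simulate_event_log(60000.0, seed=4, n_targets=10,
                                 n_distractors=8, n_irrelevant=5)
        assert len(log.onsets("target")) == 10
        assert len(log.onsets("distractor")) == 8
        assert len(log.onsets("irrelevant")) == 5
        again = simulate_event_log(60000.0, seed=4, n_targets=10,
                                   n_distractors=8, n_irrelevant=5)
        assert log.events == again.events
        assert log.responses == again.responses
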