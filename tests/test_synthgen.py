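"""Synthetic cohort generator: determinism, signatures, events, artifacts."""

import numpy as np
import pytest

import wearcam as w
from wearcam.synthgen import (
    ActivityTemplate,
    BiasInjectionSpec,
    SynthConfig,
    build_cohort,
    table3_structure,
)


class TestCohort:
    def test_zero_strength_means_identical_signatures(self):
        cfg = SynthConfig(n_subjects=5, signature_strength=0.0)
        sigs = build_cohort(cfg, seed=3)
        ref = sigs[0]
        for s in sigs[1:]:
            assert s.frequency_offset_hz == ref.frequency_offset_hz == 0.0
            np.testing.assert_array_equal(s.axis_gain, ref.axis_gain)
            np.testing.assert_array_equal(s.orientation_rotation, np.eye(3))

    def test_deterministic_per_seed(self):
        cfg = SynthConfig(n_subjects=4, signature_strength=0.7)
        a, b = build_cohort(cfg, seed=9), build_cohort(cfg, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.axis_gain, y.axis_gain)
            np.testing.assert_array_equal(x.orientation_rotation, y.orientation_rotation)

    def test_gain_spread_scales_linearly_with_strength(self):
        # Monte-Carlo over a large cohort: sd(axis_gain) at strength 1.0
        # should be ~2x the sd at strength 0.5
        sd = {}
        for strength in (1.0, 0.5):
            cfg = SynthConfig(n_subjects=1000, signature_strength=strength)
            gains = np.array([s.axis_gain for s in build_cohort(cfg, seed=5)])
            sd[strength] = gains.std(axis=0).mean()
        assert sd[1.0] / sd[0.5] == pytest.approx(2.0, rel=0.1)

    def test_rotations_are_proper(self):
        cfg = SynthConfig(n_subjects=10, signature_strength=1.0)
        for s in build_cohort(cfg, seed=2):
            R = s.orientation_rotation
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)


class TestGeneration:
    def test_windows_have_151_samples_per_axis(self, small_cohort):
        assert all(win.values.shape == (151, 3) for win in small_cohort)
        assert small_cohort.sample_rate_hz == 50.0

    def test_no_stochastic_terms_means_identical_subjects(self):
        cfg = SynthConfig(
            n_subjects=2, windows_per_subject_activity=1, signature_strength=0.0, noise_sd=0.0
        )
        ds = w.generate_dataset(cfg, seed=0)
        acts = ds.activities()
        walks = [i for i in range(len(ds)) if acts[i] == "Walking"]
        assert len(walks) == 2
        np.testing.assert_array_equal(ds[walks[0]].values, ds[walks[1]].values)

    def test_deterministic_per_seed(self):
        cfg = SynthConfig(n_subjects=2, windows_per_subject_activity=2)
        a = w.generate_dataset(cfg, seed=7)
        b = w.generate_dataset(cfg, seed=7)
        assert a.equals(b)

    def test_periodic_template_spectrum_peaks_at_base_frequency(self):
        tmpl = ActivityTemplate("osc", "periodic", base_frequency_hz=2.0, event_amplitude=5.0)
        cfg = SynthConfig(
            n_subjects=1,
            activities=[tmpl],
            windows_per_subject_activity=1,
            signature_strength=0.0,
            noise_sd=0.0,
        )
        ds = w.generate_dataset(cfg, seed=0)
        x = ds[0].values[:, 1] - ds[0].values[:, 1].mean()
        freqs = np.fft.rfftfreq(151, d=1 / 50.0)
        amp = np.abs(np.fft.rfft(x))
        peak = freqs[amp.argmax()]
        assert peak == pytest.approx(2.0, abs=50.0 / 151)  # one DFT bin

    def test_gravity_magnitude_near_g(self):
        cfg = SynthConfig(
            n_subjects=1, windows_per_subject_activity=1, signature_strength=0.0, noise_sd=0.0
        )
        ds = w.generate_dataset(cfg, seed=0)
        acts = ds.activities()
        i = int(np.flatnonzero(acts == "Walking")[0])
        # walking: steady gravity on axis z; average over the window
        assert ds[i].values[:, 2].mean() == pytest.approx(9.81, abs=1.5)

    def test_dominant_event_at_window_centre(self):
        cfg = SynthConfig(
            n_subjects=1, windows_per_subject_activity=1, signature_strength=0.0, noise_sd=0.0
        )
        ds = w.generate_dataset(cfg, seed=0)
        acts = ds.activities()
        i = int(np.flatnonzero(acts == "FallingForw")[0])
        body = np.linalg.norm(np.diff(ds[i].values, axis=0), axis=1)
        assert abs(int(body.argmax()) - 75) <= 10

    def test_dropout_pairs_produce_no_windows(self):
        cfg = SynthConfig(
            n_subjects=3,
            windows_per_subject_activity=2,
            dropout_pairs=[(2, "Walking"), (1, "Running")],
        )
        ds = w.generate_dataset(cfg, seed=1)
        pairs = {(win.subject, win.activity) for win in ds}
        assert (2, "Walking") not in pairs and (1, "Running") not in pairs
        assert (1, "Walking") in pairs

    def test_default_config_mirrors_published_structure(self):
        cfg = SynthConfig()
        counts = cfg.pair_counts()
        per_activity = {}
        subj_count = {}
        for (subj, act), n in counts.items():
            per_activity[act] = per_activity.get(act, 0) + n
            subj_count[act] = subj_count.get(act, 0) + 1
        for name, total, n_subj in table3_structure():
            assert per_activity[name] == total
            assert subj_count[name] == n_subj

    def test_empty_activity_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SynthConfig(activities=[])

    def test_subject_separability_grows_with_signature_strength(self):
        # nearest-centroid subject classification across activities:
        # centroids from two activities, evaluation on a third, noise-free
        acc = {}
        for strength in (0.8, 0.2):
            cfg = SynthConfig(
                n_subjects=8,
                activities=[t for t in SynthConfig().activities if t.kind == "periodic"][:3],
                windows_per_subject_activity=1,
                signature_strength=strength,
                noise_sd=0.0,
            )
            ds = w.generate_dataset(cfg, seed=4)
            acts, subs, X = ds.activities(), ds.subjects(), ds.values().reshape(len(ds), -1)
            train = acts != "GoingUpS"
            cents = {s: X[train & (subs == s)].mean(axis=0) for s in range(1, 9)}
            test = np.flatnonzero(~train)
            hits = sum(
                min(cents, key=lambda s: np.linalg.norm(X[i] - cents[s])) == subs[i]
                for i in test
            )
            acc[strength] = hits / len(test)
        assert acc[0.8] > acc[0.2]


class TestInjection:
    def _dataset(self, n_subjects=4, wpsa=4):
        cfg = SynthConfig(n_subjects=n_subjects, windows_per_subject_activity=wpsa)
        return w.generate_dataset(cfg, seed=2)

    def test_sustained_step_has_exact_offset_at_plant(self):
        ds = self._dataset()
        spec = BiasInjectionSpec(probability_per_window=1.0, jump_magnitude=11.0)
        out, plants = w.inject_discontinuities(ds, spec, seed=0)
        assert plants
        for i, t, axis in plants:
            delta = out[i].values[:, axis] - ds[i].values[:, axis]
            assert abs(delta[t + 1] - delta[t]) == pytest.approx(11.0)
            # the offset persists to the window end
            np.testing.assert_allclose(delta[t + 1 :], delta[t + 1], atol=1e-12)

    def test_zero_probability_is_identity(self):
        ds = self._dataset()
        out, plants = w.inject_discontinuities(
            ds, BiasInjectionSpec(probability_per_window=0.0), seed=0
        )
        assert plants == []
        assert out.equals(ds)

    def test_planted_count_binomially_plausible(self):
        ds = self._dataset(n_subjects=25, wpsa=4)  # 4 target classes x 100 windows
        spec = BiasInjectionSpec(probability_per_window=0.5, affected_axes=(1,))
        _, plants = w.inject_discontinuities(ds, spec, seed=8)
        n_targets = sum(
            1 for win in ds if win.activity in spec.target_activities
        )
        assert n_targets == 400
        sd = np.sqrt(400 * 0.5 * 0.5)
        assert abs(len(plants) - 200) <= 3 * sd

    def test_non_target_windows_untouched(self):
        ds = self._dataset()
        out, _ = w.inject_discontinuities(
            ds, BiasInjectionSpec(probability_per_window=1.0), seed=1
        )
        targets = set(BiasInjectionSpec().target_activities)
        for a, b in zip(ds, out):
            if a.activity not in targets:
                np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_target_activity_listed_in_error(self):
        ds = self._dataset()
        with pytest.raises(ValueError, match="Moonwalk"):
            w.inject_discontinuities(
                ds, BiasInjectionSpec(target_activities=("Walking", "Moonwalk")), seed=0
            )

    def test_spike_mode_displaces_single_sample(self):
        ds = self._dataset()
        spec = BiasInjectionSpec(probability_per_window=1.0, mode="single-sample-spike")
        out, plants = w.inject_discontinuities(ds, spec, seed=0)
        i, t, axis = plants[0]
        delta = out[i].values[:, axis] - ds[i].values[:, axis]
        assert np.count_nonzero(delta) == 1 and delta[t + 1] != 0
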