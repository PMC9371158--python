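"""Extent, discontinuity detection, co-localization, correlation, audit."""

import numpy as np
import pytest
import scipy.stats

import wearcam as w
from wearcam.bias_audit import (
    AuditConfig,
    AuditReport,
    colocalization,
    correlate_performance,
    detect_discontinuities,
    importance_extent,
    pvalue_from_r,
    run_audit,
)
from wearcam.gradcam1d import upsample_nearest
from wearcam.signal_data import SignalWindow
from wearcam.splitting import split_subject_dependent, split_subject_independent


def _hm(values):
    values = np.asarray(values, dtype=float)
    return w.Heatmap(values=values, class_index=0, source_resolution=len(values))


class TestExtent:
    def test_all_ones_and_zeros(self):
        assert importance_extent(_hm(np.ones(10)), 0.7) == 1.0
        assert importance_extent(_hm(np.zeros(10)), 0.7) == 0.0

    def test_upsampled_extent_by_enumeration(self):
        # 19-resolution map with exactly 3 hot positions, upsampled to 151
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 0.5, 19)
        hot = {2, 9, 17}
        for p in hot:
            src[p] = 0.9
        hm = _hm(upsample_nearest(src, 151))
        expected = sum(1 for j in range(151) if int(np.floor(j * 19 / 151)) in hot) / 151
        assert importance_extent(hm, 0.7) == pytest.approx(expected)

    def test_monotone_non_increasing_in_tau(self):
        hm = _hm(np.random.default_rng(1).uniform(size=50))
        taus = np.linspace(0, 1, 21)
        extents = [importance_extent(hm, t) for t in taus]
        assert all(b <= a for a, b in zip(extents, extents[1:]))


class TestDetector:
    def test_observed_artifact_magnitudes_detected(self):
        # a level shift from -10 to 1.3 between consecutive samples on y
        vals = np.zeros((151, 3))
        vals[:, 1] = -10.0
        vals[30:, 1] = 1.3
        win = SignalWindow(values=vals, activity="SittingDown", subject=1)
        events = detect_discontinuities(win, 10.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.timestep == 29 and ev.axis == 1
        assert ev.delta == pytest.approx(11.3)
        assert ev.elapsed == pytest.approx(0.02)

    def test_constant_window_has_no_events(self):
        win = SignalWindow(values=np.full((151, 3), 9.81), activity="x", subject=1)
        assert detect_discontinuities(win) == []

    def test_smooth_sinusoid_below_threshold(self):
        # 2 Hz, amplitude 5, at 50 Hz: max one-sample step ~ 5*2*pi*2/50 ~ 1.26
        t = np.arange(151) / 50.0
        vals = np.stack([5 * np.sin(2 * np.pi * 2 * t)] * 3, axis=1)
        win = SignalWindow(values=vals, activity="x", subject=1)
        assert detect_discontinuities(win, 10.0) == []

    def test_robust_threshold_adapts_to_scale(self):
        rng = np.random.default_rng(0)
        vals = 0.01 * rng.standard_normal((151, 3))
        vals[80:, 0] += 1.0  # big relative to the quiet signal, small absolutely
        win = SignalWindow(values=vals, activity="x", subject=1)
        assert detect_discontinuities(win, 10.0) == []
        robust = detect_discontinuities(win, robust_k=20.0)
        assert any(e.timestep == 79 and e.axis == 0 for e in robust)


class TestColocalization:
    def test_perfect_overlap_scores_one(self):
        values = np.zeros(50)
        values[10:13] = 1.0
        events = [w.DiscontinuityEvent(timestep=11, axis=0, delta=11.0, elapsed=0.02)]
        res = colocalization(_hm(values), events, tau=0.7, halo_w=2)
        assert res.defined and res.score == 1.0
        assert res.enrichment == pytest.approx(1.0 / res.chance)

    def test_no_events_is_undefined(self):
        res = colocalization(_hm(np.ones(20)), [], tau=0.7)
        assert not res.defined

    def test_no_hot_timesteps_is_undefined(self):
        events = [w.DiscontinuityEvent(timestep=5, axis=0, delta=11.0, elapsed=0.02)]
        res = colocalization(_hm(np.zeros(20)), events, tau=0.7)
        assert not res.defined

    def test_random_masks_score_at_chance(self):
        # Monte-Carlo null: heatmaps random, events fixed -> mean score ~ chance
        rng = np.random.default_rng(2)
        n, draws = 151, 10_000
        events = [
            w.DiscontinuityEvent(timestep=t, axis=0, delta=11.0, elapsed=0.02)
            for t in (30, 90)
        ]
        scores = []
        chance = None
        for _ in range(draws):
            hm = _hm((rng.uniform(size=n) > 0.8).astype(float))
            res = colocalization(hm, events, tau=0.5, halo_w=2)
            if res.defined:
                scores.append(res.score)
                chance = res.chance
        scores = np.array(scores)
        se = scores.std() / np.sqrt(len(scores))
        assert abs(scores.mean() - chance) <= 3 * se


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([0.1, 0.4, 0.5, 0.9])
        res = correlate_performance(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_published_pvalue_pairs(self):
        # the p-value formula must reproduce the printed (r, n) -> p pairs
        assert pvalue_from_r(0.775, 9) == pytest.approx(0.014, abs=0.001)
        assert pvalue_from_r(0.504, 17) == pytest.approx(0.039, abs=0.001)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(size=12), rng.uniform(size=12)
        res = correlate_performance(x, y)
        ref = scipy.stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        res = correlate_performance([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert not res.defined

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_performance([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def audited_bundle():
    """Small clean cohort with trained SD and SI models and its audit."""
    cfg = w.SynthConfig(n_subjects=4, windows_per_subject_activity=3, signature_strength=0.6)
    ds = w.generate_dataset(cfg, seed=21)
    plans = {
        "SD": split_subject_dependent(ds, 0.3, 42),
        "SI": split_subject_independent(ds, [1]),
    }
    spec = w.build_small_architecture(17, n_filters=8)
    config = w.TrainConfig(epochs=5, batch_size=64, seed=0)
    models = {tag: w.train_model(spec, ds, plans[tag], config) for tag in plans}
    report = run_audit(models, plans, ds, AuditConfig(samples_per_class=3, seed=0))
    return ds, models, plans, report


class TestRunAudit:
    def test_clean_cohort_flags_nothing(self, audited_bundle):
        *_, report = audited_bundle
        assert report.flagged_classes == []
        assert sum(report.events_per_class.values()) == 0

    def test_extent_summaries_cover_both_tags(self, audited_bundle):
        *_, report = audited_bundle
        assert set(report.extent_summaries) == {"SD", "SI"}
        for s in report.extent_summaries.values():
            assert 0.0 <= s.mean <= 1.0 and s.n > 0

    def test_recall_maps_cover_vocabulary(self, audited_bundle):
        ds, *_, report = audited_bundle
        assert set(report.recall_gaps) == set(ds.activity_vocabulary)

    def test_report_round_trips_through_json(self, audited_bundle, tmp_path):
        *_, report = audited_bundle
        report.save(tmp_path / "audit.json")
        back = AuditReport.load(tmp_path / "audit.json")
        assert back.flagged_classes == report.flagged_classes
        assert back.recall_gaps == report.recall_gaps
        assert back.events_per_class == report.events_per_class
        assert back.extent_summaries["SD"].mean == pytest.approx(
            report.extent_summaries["SD"].mean
        )

    def test_missing_tag_rejected(self, audited_bundle):
        ds, models, plans, _ = audited_bundle
        with pytest.raises(ValueError, match="SI"):
            run_audit({"SD": models["SD"]}, {"SD": plans["SD"]}, ds)
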