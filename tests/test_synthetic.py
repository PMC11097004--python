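"""Synthetic accelerometer generator: signal content, labels, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

import accelbehave as ab
from accelbehave.synthetic import _split_into_bouts


def mean_vedba(trace: ab.AccelTrace) -> float:
    """VeDBA by direct formula: norm of (raw - centred 2 s running mean)."""
    (sx, sy, sz), (dx, dy, dz) = ab.split_static_dynamic(trace)
    return float(np.mean(np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)))


class TestGenerateBout:
    def test_rest_bout_is_nearly_still(self):
        tr = ab.generate_bout(ab.DEFAULT_REGIMES["rest"], 60, 40, seed=3)
        assert mean_vedba(tr) < 0.05

    def test_run_bout_dominant_frequency_is_the_stride(self):
        regime = ab.DEFAULT_REGIMES["run"]
        tr = ab.generate_bout(regime, 60, 40, seed=5)
        heave_dyn = tr.ay - np.mean(tr.ay)
        freqs, power = sps.periodogram(heave_dyn, fs=40.0)
        peak = freqs[np.argmax(power)]
        assert peak == pytest.approx(3.5, abs=0.2)

    def test_same_seed_same_trace(self):
        a = ab.generate_bout(ab.DEFAULT_REGIMES["walk"], 10, 40, seed=9)
        b = ab.generate_bout(ab.DEFAULT_REGIMES["walk"], 10, 40, seed=9)
        assert np.array_equal(a.ax, b.ax) and np.array_equal(a.ay, b.ay) \
            and np.array_equal(a.az, b.az)

    def test_rejects_short_bouts_and_supernyquist_strides(self):
        with pytest.raises(ValueError):
            ab.generate_bout(ab.DEFAULT_REGIMES["walk"], 1.5, 40, seed=0)
        bad = ab.BehaviourRegime("buzz", 25.0, 0.2)
        with pytest.raises(ValueError):
            ab.generate_bout(bad, 10, 40, seed=0)

    def test_static_magnitude_at_rest_is_one_g(self):
        regime = ab.DEFAULT_REGIMES["rest"]
        tr = ab.generate_bout(regime, 30, 40, seed=2)
        (sx, sy, sz), _ = ab.split_static_dynamic(tr)
        mag = np.sqrt(sx ** 2 + sy ** 2 + sz ** 2)
        assert np.all(np.abs(mag - 1.0) < 3 * regime.noise_sd_g + 0.05)

    def test_mean_vedba_orders_the_gaits(self):
        # averaged over bouts so bout-level vigour draws do not mask the design
        means = {}
        for name in ("rest", "walk", "trot", "run"):
            vals = [mean_vedba(ab.generate_bout(ab.DEFAULT_REGIMES[name], 60, 40,
                                                seed=100 + i))
                    for i in range(10)]
            means[name] = np.mean(vals)
        assert means["rest"] < means["walk"] < means["trot"] < means["run"]


class TestCalibrationSet:
    def test_every_individual_expresses_every_behaviour(self, default_calibration):
        traces, segments = default_calibration
        assert len(traces) == 9
        seen = {}
        for s in segments:
            seen.setdefault(s.individual_id, set()).add(s.behaviour)
        assert all(seen[iid] == set(ab.BEHAVIOURS) for iid in seen)

    def test_label_totals_match_request_exactly(self):
        _, segments = ab.generate_calibration_set(
            5, {"rest": 200.0, "groom": 45.0}, seed=1)
        rest = sum(s.duration_s for s in segments if s.behaviour == "rest")
        groom = sum(s.duration_s for s in segments if s.behaviour == "groom")
        assert rest == pytest.approx(200.0, abs=1e-9)
        assert groom == pytest.approx(45.0, abs=1e-9)

    def test_bouts_are_at_least_two_seconds_and_disjoint(self, default_calibration):
        _, segments = default_calibration
        assert min(s.duration_s for s in segments) >= 2.0
        by_id = {}
        for s in segments:
            by_id.setdefault(s.individual_id, []).append((s.start_s, s.end_s))
        for spans in by_id.values():
            spans.sort()
            assert all(a[1] <= b[0] + 1e-9 for a, b in zip(spans, spans[1:]))

    def test_segments_tile_each_trace(self, default_calibration):
        traces, segments = default_calibration
        for i, tr in enumerate(traces):
            iid = f"cat{i + 1:02d}"
            spans = sorted((s.start_s, s.end_s) for s in segments
                           if s.individual_id == iid)
            assert spans[0][0] == 0.0
            assert spans[-1][1] == pytest.approx(tr.duration_s, abs=1e-9)
            assert all(a[1] == pytest.approx(b[0], abs=1e-9)
                       for a, b in zip(spans, spans[1:]))

    def test_seed_changes_signal_not_label_totals(self):
        req = {"rest": 50.0, "walk": 30.0}
        tr1, seg1 = ab.generate_calibration_set(3, req, seed=1)
        tr2, seg2 = ab.generate_calibration_set(3, req, seed=2)
        assert not np.array_equal(tr1[0].ay, tr2[0].ay)
        tot1 = {b: sum(s.duration_s for s in seg1 if s.behaviour == b) for b in req}
        tot2 = {b: sum(s.duration_s for s in seg2 if s.behaviour == b) for b in req}
        assert tot1 == tot2

    def test_csv_output_is_byte_identical_across_reruns(self, tmp_path):
        for run in ("a", "b"):
            traces, segments = ab.generate_calibration_set(
                2, {"rest": 20.0, "walk": 10.0}, seed=7)
            traces[0].to_csv(tmp_path / f"trace_{run}.csv")
            ab.synthetic.segments_to_csv(segments, tmp_path / f"seg_{run}.csv")
        assert (tmp_path / "trace_a.csv").read_bytes() == \
            (tmp_path / "trace_b.csv").read_bytes()
        assert (tmp_path / "seg_a.csv").read_bytes() == \
            (tmp_path / "seg_b.csv").read_bytes()

    def test_rejects_empty_behaviour_set(self):
        with pytest.raises(ValueError):
            ab.generate_calibration_set(3, {}, seed=0)

    def test_bout_splitter_respects_minimum(self, rng):
        for total in (81, 160, 4000):
            bouts = _split_into_bouts(total, 40.0, rng)
            assert sum(bouts) == total
            assert min(bouts) >= 80


class TestDeployment:
    def test_kernel_stationary_time_fractions_equal_budget(self):
        cfg = ab.DeploymentConfig()
        names, P = ab.build_transition_kernel(cfg.budget, cfg.mean_bout_s)
        # eigen-analysis oracle: stationary law of the embedded chain,
        # time-weighted by mean bout length, must reproduce the budget
        w, vec = np.linalg.eig(P.T)
        nu = np.real(vec[:, np.argmin(np.abs(w - 1.0))])
        nu = nu / nu.sum()
        time_frac = nu * np.array([cfg.mean_bout_s[b] for b in names])
        time_frac /= time_frac.sum()
        for i, b in enumerate(names):
            assert time_frac[i] == pytest.approx(cfg.budget[b], abs=1e-9)

    def test_long_deployment_recovers_rest_fraction(self):
        cfg = ab.DeploymentConfig(seed=21)
        bouts = ab.simulate_behaviour_sequence(cfg)
        total = sum(d for _, d in bouts)
        rest = sum(d for b, d in bouts if b == "rest")
        assert total == pytest.approx(2.74 * 86400, rel=1e-9)
        assert rest / total == pytest.approx(0.921, abs=0.02)

    def test_single_behaviour_budget_gives_one_segment(self):
        cfg = ab.DeploymentConfig(duration_days=0.01, budget={"rest": 1.0},
                                  mean_bout_s={"rest": 600.0}, seed=0)
        trace, segments = ab.generate_deployment(cfg)
        assert len(segments) == 1
        assert segments[0].behaviour == "rest"
        assert segments[0].end_s == pytest.approx(trace.duration_s)

    def test_segments_tile_the_deployment_trace(self):
        cfg = ab.DeploymentConfig(duration_days=0.02, seed=5)
        trace, segments = ab.generate_deployment(cfg)
        spans = [(s.start_s, s.end_s) for s in segments]
        assert spans[0][0] == 0.0
        assert spans[-1][1] == pytest.approx(trace.duration_s, abs=1e-9)
        assert all(a[1] == pytest.approx(b[0]) for a, b in zip(spans, spans[1:]))
        labels = ab.labels_per_sample(segments, trace.t)
        assert not any(lab is None for lab in labels)

    def test_zero_budget_with_requested_bout_mean_is_rejected(self):
        with pytest.raises(ValueError):
            ab.DeploymentConfig(budget={"rest": 1.0, "walk": 0.0},
                                mean_bout_s={"rest": 600.0, "walk": 30.0})

    def test_budget_is_normalised(self):
        cfg = ab.DeploymentConfig(budget={"rest": 3.0, "walk": 1.0},
                                  mean_bout_s={"rest": 60.0, "walk": 30.0})
        assert sum(cfg.budget.values()) == pytest.approx(1.0, abs=1e-9)
        assert cfg.budget["rest"] == pytest.approx(0.75)
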