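"""Cycle segmentation: smoothing, minima gating, limits, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bendreturn import (
    SegmentationParams,
    mean_cycle,
    normalize_cycles,
    rolling_centered_mean,
    segment_cycles,
    segment_recording,
    trim_warmup,
)
from bendreturn.segmentation import NoCyclesError, detect_minima

from conftest import make_recording


class TestRollingMean:
    def test_constant_series_unchanged(self):
        x = np.full(100, 2.5)
        np.testing.assert_array_equal(rolling_centered_mean(x, 25), x)

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(50)
        np.testing.assert_array_equal(rolling_centered_mean(x, 1), x)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = rolling_centered_mean(x, 25)
        inside = out[100 - 12: 100 + 13]
        np.testing.assert_allclose(inside, 1 / 25)
        assert out[100 - 13] == 0.0 and out[100 + 13] == 0.0

    def test_edges_shrink_symmetrically(self):
        x = np.arange(100.0)
        out = rolling_centered_mean(x, 25)
        # Symmetric shrink keeps a linear ramp exactly linear everywhere.
        np.testing.assert_allclose(out, x)

    def test_width_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rolling_centered_mean(np.zeros(10), 25)


def cosine_signal(n_minima: int, period_s: float = 2.0, fs: float = 100.0):
    t = np.arange(0, n_minima * period_s, 1 / fs)
    return np.cos(2 * np.pi * t / period_s), t


class TestSegmentCycles:
    def test_cosine_limits_sit_at_trough_midpoints(self):
        x, t = cosine_signal(10)
        boundaries = segment_cycles(x)
        expected = 200 * np.arange(1, 10)  # midpoints of consecutive troughs
        assert len(boundaries) == 9
        assert np.abs(boundaries - expected).max() <= 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        offset=st.floats(-50, 50),
        scale=st.floats(0.1, 90.0),
    )
    def test_amplitude_relative_threshold_invariance(self, offset, scale):
        x, _ = cosine_signal(6)
        base = segment_cycles(x)
        moved = segment_cycles(scale * x + offset)
        np.testing.assert_array_equal(base, moved)

    def test_shallow_minimum_above_threshold_is_ignored(self):
        # Deep troughs to -1 with a shallow dip to +0.4 between them: the
        # 40% threshold sits at -0.2, so the dip never forms its own run.
        fs = 100
        t = np.arange(0, 6, 1 / fs)
        deep = sum(np.exp(-((t - c) ** 2) / 0.02) for c in (1.0, 3.0, 5.0))
        shallow = sum(0.45 * np.exp(-((t - c) ** 2) / 0.02) for c in (2.0, 4.0))
        x = 1.0 - deep - shallow  # shallow dips bottom out at 0.55 > 0.40
        _, minima, threshold = detect_minima(x)
        assert len(minima) == 3
        np.testing.assert_allclose(minima, [100, 300, 500], atol=3)

    def test_flat_series_has_no_cycles(self):
        with pytest.raises(NoCyclesError):
            segment_cycles(np.zeros(1000) + 1e-12 * np.arange(1000))

    def test_synthetic_subject_boundaries_match_ground_truth(self, nlbp_subject):
        rec, truth = nlbp_subject
        boundaries = segment_cycles(rec.channel("SENS1", "Acc Z"))
        true_b = truth.boundary_samples(10.0, 70.0, 100.0)
        hits = sum(
            1 for tb in true_b if np.abs(boundaries - tb).min() <= 5
        )
        assert hits / len(true_b) >= 0.95
        # Cycle count tracks the ground-truth limit count.
        assert abs((len(boundaries) - 1) - (len(true_b) - 1)) <= 2


class TestNormalize:
    def test_450_sample_cycle_is_preserved_identically(self, flat_recording):
        n = 1000
        ramp = np.arange(float(n))
        rec = make_recording(lambda sid, name: ramp, n=n)
        boundaries = np.array([100, 550, 1000 - 1])
        cs = normalize_cycles(rec, boundaries)
        first = cs.channel("SENS1", "Acc X")[0]
        np.testing.assert_allclose(first, ramp[100:550], rtol=1e-12)

    def test_linear_ramp_keeps_endpoints_at_any_length(self):
        n = 1000
        ramp = np.arange(float(n))
        rec = make_recording(lambda sid, name: ramp, n=n)
        cs = normalize_cycles(rec, np.array([0, 313, 700]))
        cyc = cs.channel("SENS2", "Gyr Y")
        assert cs.n_points == 450 and cyc.shape == (2, 450)
        np.testing.assert_allclose(cyc[0][[0, -1]], [0.0, 312.0])
        np.testing.assert_allclose(cyc[1][[0, -1]], [313.0, 699.0])
        # Linearity is preserved pointwise.
        np.testing.assert_allclose(cyc[0], np.linspace(0, 312, 450))

    def test_resampled_sine_conserves_energy(self):
        n = 1000
        sine = np.sin(2 * np.pi * np.arange(n) / 180.0)
        rec = make_recording(lambda sid, name: sine, n=n)
        cs = normalize_cycles(rec, np.array([0, 540, 999]))
        orig = sine[0:540]
        res = cs.channel("SENS1", "Acc Z")[0]
        assert abs(np.mean(res**2) - np.mean(orig**2)) < 0.01 * np.mean(orig**2)

    def test_degenerate_cycle_skipped_with_warning(self):
        rec = make_recording(lambda sid, name: np.arange(500.0), n=500)
        with pytest.warns(UserWarning, match="skipped"):
            cs = normalize_cycles(rec, np.array([0, 250, 251, 499]))
        assert cs.n_cycles == 2


class TestMeanCycle:
    def test_duplicated_cycles_have_zero_sd(self, nlbp_subject):
        rec, _ = nlbp_subject
        cs = segment_recording(rec)
        first = cs.channel("SENS2", "Gyr Y")[:1]
        cs.cycles = {k: np.repeat(v[:1], 4, axis=0) for k, v in cs.cycles.items()}
        mean, sd = mean_cycle(cs, "SENS2", "Gyr Y")
        np.testing.assert_array_equal(sd, 0.0)
        np.testing.assert_array_equal(mean, first[0])

    def test_two_cycle_mean_is_pointwise_average(self, nlbp_subject):
        rec, _ = nlbp_subject
        cs = segment_recording(rec)
        cs.cycles = {k: v[:2] for k, v in cs.cycles.items()}
        mean, _ = mean_cycle(cs, "SENS1", "Acc Z")
        arr = cs.channel("SENS1", "Acc Z")
        np.testing.assert_allclose(mean, (arr[0] + arr[1]) / 2)

    def test_tidy_export_covers_every_cycle_sample(self, nlbp_subject, tmp_path):
        import pandas as pd

        rec, _ = nlbp_subject
        cs = segment_recording(rec)
        cs.to_csv(tmp_path / "cycles.csv")
        tidy = pd.read_csv(tmp_path / "cycles.csv")
        assert set(tidy.columns) == {"subject", "group", "cycle", "itime",
                                     "channel", "value"}
        assert len(tidy) == 18 * cs.n_cycles * cs.n_points
        sel = tidy[(tidy.channel == "Gyr Y SENS2") & (tidy.cycle == 0)]
        np.testing.assert_allclose(
            sel.sort_values("itime").value.to_numpy(),
            cs.channel("SENS2", "Gyr Y")[0],
        )

    def test_group_contrast_in_mean_cycle_depth(self, small_cohort):
        recs, _ = small_cohort
        depth = {"NLBP": [], "CLBP": []}
        for rec in recs:
            cs = segment_recording(rec)
            mean, _ = mean_cycle(cs, "SENS2", "Gyr Y")
            depth[rec.group.value].append(abs(mean.min()))
        assert np.mean(depth["NLBP"]) > np.mean(depth["CLBP"])
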