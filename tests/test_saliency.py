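"""Saliency oracles (linear model, finite differences) and the
spatio-temporal quantifications."""

import numpy as np
import pandas as pd
import pytest

from p300decode.epochs import epoch_times
from p300decode.layout import ChannelLayout
from p300decode.nn import build_model
from p300decode.saliency import (
    IntervalResult,
    LinearOracleModel,
    SaliencyMap,
    average_maps,
    compute_saliency,
    latency_trend,
    most_varied_interval,
    normalize_map,
    peak_gradient,
    spatial_profile,
    temporal_profile,
)


def _map(values, normalized=False):
    return SaliencyMap(
        values=values, class_index=1, times=epoch_times(), normalized=normalized
    )


class TestComputeSaliency:
    def test_linear_oracle_exact(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(2, 8, 201))
        model = LinearOracleModel(weights=w, biases=np.array([0.3, -0.2]))
        x = rng.normal(size=(8, 201))
        smap = compute_saliency(model, x, class_index=1)
        np.testing.assert_array_equal(smap.values, w[1])

    def test_zero_weight_model_zero_map(self):
        model = LinearOracleModel(weights=np.zeros((1, 8, 201)))
        smap = compute_saliency(model, np.random.default_rng(1).normal(size=(8, 201)), 0)
        np.testing.assert_array_equal(smap.values, 0.0)

    def test_cnn_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        model = build_model(seed=21)
        x = rng.standard_normal((8, 201))
        smap = compute_saliency(model, x, class_index=1)
        eps = 1e-5
        for _ in range(20):
            c, t = rng.integers(8), rng.integers(201)
            xp, xm = x.copy(), x.copy()
            xp[c, t] += eps
            xm[c, t] -= eps
            fd = (model.class_score(xp[None], 1)[0] - model.class_score(xm[None], 1)[0]) / (2 * eps)
            assert smap.values[c, t] == pytest.approx(fd, rel=1e-3, abs=1e-10)

    def test_class_out_of_range(self):
        model = LinearOracleModel(weights=np.zeros((2, 8, 201)))
        with pytest.raises(IndexError):
            compute_saliency(model, np.zeros((8, 201)), 5)


class TestNormalizeMap:
    def test_scales_to_unit_max(self):
        rng = np.random.default_rng(1)
        m = _map(rng.normal(scale=4.0, size=(8, 201)))
        out = normalize_map(m)
        assert np.abs(out.values).max() == pytest.approx(1.0)
        assert out.normalized

    def test_idempotent(self):
        m = normalize_map(_map(np.random.default_rng(2).normal(size=(8, 201))))
        out = normalize_map(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_sign_pattern_preserved(self):
        rng = np.random.default_rng(3)
        m = _map(rng.normal(size=(8, 201)))
        out = normalize_map(m)
        np.testing.assert_array_equal(np.sign(out.values), np.sign(m.values))

    def test_all_zero_passes_through(self):
        out = normalize_map(_map(np.zeros((8, 201))))
        np.testing.assert_array_equal(out.values, 0.0)
        assert out.provenance.get("all_zero")


class TestAverageMaps:
    def test_cancellation(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(8, 201))
        out = average_maps([_map(v), _map(-v)])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_idempotence(self):
        v = np.random.default_rng(6).normal(size=(8, 201))
        out = average_maps([_map(v)] * 3)
        np.testing.assert_allclose(out.values, v)
        assert out.provenance["n_averaged"] == 3

    def test_equals_brute_force_mean(self):
        rng = np.random.default_rng(7)
        vals = [rng.normal(size=(8, 201)) for _ in range(5)]
        out = average_maps([_map(v) for v in vals])
        np.testing.assert_allclose(out.values, np.mean(vals, axis=0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_maps([])

    def test_shape_mismatch_rejected(self):
        a = _map(np.zeros((8, 201)))
        b = SaliencyMap(values=np.zeros((8, 100)), class_index=1, times=np.arange(100.0))
        with pytest.raises(ValueError):
            average_maps([a, b])


class TestProfiles:
    def test_spatial_argmax_single_row(self):
        layout = ChannelLayout()
        v = np.zeros((8, 201))
        v[layout.index("Pz")] = np.random.default_rng(8).normal(size=201)
        sp = spatial_profile(_map(v))
        assert sp.idxmax() == "Pz"

    def test_temporal_zero_outside_span(self):
        times = epoch_times()
        v = np.zeros((8, 201))
        cols = (times >= 300) & (times <= 400)
        v[:, cols] = 1.0
        tp = temporal_profile(_map(v))
        assert (tp[~cols] == 0).all()
        assert (tp[cols] > 0).all()

    def test_profiles_equal_brute_force(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(8, 201))
        m = _map(v)
        np.testing.assert_allclose(spatial_profile(m).to_numpy(), np.abs(v).mean(axis=1))
        np.testing.assert_allclose(temporal_profile(m).to_numpy(), np.abs(v).mean(axis=0))

    def test_channel_permutation_commutes(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=(8, 201))
        names = ChannelLayout().names
        perm = rng.permutation(8)
        layout_p = ChannelLayout(
            names=tuple(names[i] for i in perm), positions=ChannelLayout().positions[perm]
        )
        m = _map(v)
        mp = SaliencyMap(values=v[perm], class_index=1, times=epoch_times(), layout=layout_p)
        sp, spp = spatial_profile(m), spatial_profile(mp)
        for name in names:
            assert sp[name] == pytest.approx(spp[name])
        np.testing.assert_allclose(
            temporal_profile(m).to_numpy(), temporal_profile(mp).to_numpy()
        )


class TestPeakGradient:
    def test_single_bump(self):
        times = epoch_times()
        prof = pd.Series(np.exp(-0.5 * ((times - 350) / 20.0) ** 2), index=times)
        value, lat = peak_gradient(prof)
        assert lat == pytest.approx(348.0, abs=4.0)  # nearest grid sample

    def test_flat_profile_earliest(self):
        times = epoch_times()
        prof = pd.Series(np.ones_like(times), index=times)
        _, lat = peak_gradient(prof, (300.0, 400.0))
        assert lat == pytest.approx(300.0)

    def test_two_equal_peaks_earliest_wins(self):
        times = epoch_times()
        vals = np.zeros_like(times)
        vals[np.argmin(np.abs(times - 320))] = 1.0
        vals[np.argmin(np.abs(times - 380))] = 1.0
        _, lat = peak_gradient(pd.Series(vals, index=times), (300.0, 400.0))
        assert lat == pytest.approx(320.0)


class TestMostVariedInterval:
    def test_mass_inside_350_450(self):
        layout = ChannelLayout()
        times = epoch_times()
        v = np.zeros((8, 201))
        v[layout.index("Pz"), (times >= 350) & (times <= 450)] = 1.0
        res = most_varied_interval(_map(v))
        assert res.start_ms == pytest.approx(350.0)
        assert res.end_ms == pytest.approx(450.0)

    def test_uniform_row_earliest_window(self):
        v = np.ones((8, 201))
        res = most_varied_interval(_map(v))
        assert res.start_ms == pytest.approx(-100.0)
        assert res.end_ms == pytest.approx(0.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        layout = ChannelLayout()
        times = epoch_times()
        v = rng.normal(size=(8, 201))
        res = most_varied_interval(_map(v), electrode="P3")
        row = np.abs(v[layout.index("P3")])
        best_val, best_start = -np.inf, None
        start = -100.0
        while start + 100.0 <= 700.0 + 1e-9:
            mask = (times >= start - 1e-9) & (times <= start + 100.0 + 1e-9)
            val = row[mask].mean()
            if val > best_val + 1e-15:
                best_val, best_start = val, start
            start += 5.0
        assert res.start_ms == pytest.approx(best_start)
        assert res.statistic == pytest.approx(best_val)

    def test_window_grid_count(self):
        """starts -100, -95, ..., 600 -> 141 candidate windows."""
        starts = np.arange(-100.0, 601.0, 5.0)
        assert len(starts) == 141

    def test_unknown_electrode(self):
        with pytest.raises(ValueError):
            most_varied_interval(_map(np.zeros((8, 201))), electrode="Oz")

    def test_statistic_variants(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=(8, 201))
        for stat in ("mean", "sum", "max"):
            res = most_varied_interval(_map(v), statistic=stat)
            assert isinstance(res, IntervalResult)
            assert res.end_ms - res.start_ms == pytest.approx(100.0)


class TestLatencyTrend:
    def test_linear_decreasing_r_minus_one(self):
        r, p = latency_trend(np.linspace(400, 340, 7))
        assert r == pytest.approx(-1.0)

    def test_brute_force_formula(self):
        rng = np.random.default_rng(13)
        centers = np.sort(rng.uniform(300, 500, 7))[::-1].copy()
        r, _ = latency_trend(centers)
        s = np.arange(1.0, 8.0)
        n = 7
        num = n * (s * centers).sum() - s.sum() * centers.sum()
        den = np.sqrt(n * (s**2).sum() - s.sum() ** 2) * np.sqrt(
            n * (centers**2).sum() - centers.sum() ** 2
        )
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_permuted_null_near_zero(self):
        rng = np.random.default_rng(14)
        rs = []
        base = np.linspace(400, 340, 20)
        for _ in range(300):
            rs.append(latency_trend(rng.permutation(base))[0])
        assert abs(np.mean(rs)) < 0.05

    def test_constant_flagged(self):
        with pytest.raises(ValueError):
            latency_trend(np.full(7, 400.0))
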