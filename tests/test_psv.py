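import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import deltasync as ds
from deltasync.psv import (
    FIRST_TWO_SECONDS,
    REST,
    WHOLE_STIMULI,
    BandRequiredError,
    EpochSkipped,
    MissingCellError,
)
from oracles import plv_brute


def phases_of(x, rate=256.0):
    return ds.instantaneous_phase(x, rate, band="delta")


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        rate, f = 256.0, 2.0
        t = np.arange(int(10 * rate)) / rate
        ph = phases_of(np.cos(2 * np.pi * f * t)).phases
        un = np.unwrap(ph)
        k = len(un) // 10
        sl = np.polyfit(t[k:-k], un[k:-k], 1)[0]
        assert abs(sl - 2 * np.pi * f) / (2 * np.pi * f) < 0.01

    def test_sin_lags_cos_by_half_pi(self):
        rate, f = 256.0, 3.0
        t = np.arange(int(8 * rate)) / rate
        pc = phases_of(np.cos(2 * np.pi * f * t)).phases
        ps = phases_of(np.sin(2 * np.pi * f * t)).phases
        k = len(t) // 10
        lag = np.angle(np.exp(1j * (pc - ps)))[k:-k]
        assert np.all(np.abs(lag - np.pi / 2) < 0.05)

    def test_amplitude_free(self, rng):
        x = rng.standard_normal(2048)
        a = phases_of(x).phases
        b = phases_of(7.3 * x).phases
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_wrapped_range(self, rng):
        ph = phases_of(rng.standard_normal(1024)).phases
        assert np.all(ph > -np.pi - 1e-12) and np.all(ph <= np.pi + 1e-12)

    def test_broadband_input_rejected(self, rng):
        with pytest.raises(BandRequiredError):
            ds.instantaneous_phase(rng.standard_normal(64), 64.0,
                                   band="broadband")
        with pytest.raises(BandRequiredError):
            ds.instantaneous_phase(rng.standard_normal(64), 64.0)


class TestPlv:
    def test_identical_series_lock_at_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert ds.plv(ph, ph) == pytest.approx(1.0)

    def test_fixed_lag_still_locks(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert ds.plv(ph, ph - np.pi / 3) == pytest.approx(1.0)

    def test_uniformly_spread_differences_cancel(self):
        n = 360
        diffs = np.linspace(-np.pi, np.pi, n, endpoint=False)
        assert ds.plv(diffs, np.zeros(n)) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_equivalence(self, rng):
        for _ in range(100):
            n = int(rng.integers(50, 400))
            a = rng.uniform(-np.pi, np.pi, n)
            b = rng.uniform(-np.pi, np.pi, n)
            assert abs(ds.plv(a, b) - plv_brute(a, b)) < 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounded_symmetric_and_scale_free(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(512)
        y = rng.standard_normal(512)
        pa, pb = phases_of(x), phases_of(y)
        r = ds.plv(pa, pb)
        assert 0.0 <= r <= 1.0
        assert ds.plv(pb, pa) == pytest.approx(r)
        assert ds.plv(phases_of(5.0 * x), pb) == pytest.approx(r, abs=1e-9)

    def test_empty_window_rejected(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 100)
        with pytest.raises(ValueError):
            ds.plv(ph, ph, window=(50, 50))


class TestSegmentWindows:
    def test_whole_stimuli_54s_example(self):
        w = ds.segment_windows(54.0, WHOLE_STIMULI)
        assert len(w) == 19
        assert w[0] == (2.0, 7.0)
        assert w[-1] == (47.0, 52.0)

    def test_first_two_seconds_six_windows(self):
        w = ds.segment_windows(40.0, FIRST_TWO_SECONDS)
        expected = [(0.25 + 0.25 * k, 0.75 + 0.25 * k) for k in range(6)]
        np.testing.assert_allclose(w, expected)

    def test_rest_75s_example(self):
        assert len(ds.segment_windows(75.0, REST)) == 29

    def test_shortest_stimulus_three_windows(self):
        w = ds.segment_windows(13.0, WHOLE_STIMULI)
        assert w == [(2.0, 7.0), (4.5, 9.5), (7.0, 12.0)]

    def test_windows_fit_analysis_span(self):
        for dur in np.linspace(8.0, 70.0, 40):
            for scheme in (WHOLE_STIMULI, REST):
                for w0, w1 in ds.segment_windows(float(dur), scheme):
                    assert w0 >= scheme.start_offset_s - 1e-9
                    assert w1 <= dur + scheme.end_offset_s + 1e-9

    def test_too_short_epoch_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert ds.segment_windows(6.0, WHOLE_STIMULI) == []


class TestPsvAggregation:
    @staticmethod
    def coupled_epoch(rng, dur=12.0, rate=256.0):
        t = np.arange(int(dur * rate)) / rate
        base = 2 * np.pi * 2.0 * t
        return {
            "a": ds.PhaseSeries(np.angle(np.exp(1j * base)), rate, "delta"),
            "b": ds.PhaseSeries(np.angle(np.exp(1j * (base + 0.4))), rate,
                                "delta"),
        }

    def test_perfect_locking_is_one_for_any_window_count(self, rng):
        phases = self.coupled_epoch(rng, dur=30.0)
        pairs = [ds.ElectrodePair("a", "b")]
        out = ds.psv_epoch(phases, WHOLE_STIMULI, pairs)
        assert out[pairs[0]] == pytest.approx(1.0, abs=1e-9)

    def test_single_window_equals_direct_plv(self, rng):
        # 8.0-s epoch: the whole-stimuli span [2, 7) holds exactly one window
        rate = 256.0
        x = rng.standard_normal(int(8.0 * rate))
        y = rng.standard_normal(int(8.0 * rate))
        phases = {"a": phases_of(x), "b": phases_of(y)}
        pairs = [ds.ElectrodePair("a", "b")]
        out = ds.psv_epoch(phases, WHOLE_STIMULI, pairs)
        direct = ds.plv(phases["a"], phases["b"],
                        window=(int(2 * rate), int(7 * rate)))
        assert out[pairs[0]] == pytest.approx(direct, abs=1e-12)

    def test_epoch_too_short_is_signalled_with_id(self, rng):
        phases = self.coupled_epoch(rng, dur=6.0)
        with pytest.warns(UserWarning):
            with pytest.raises(EpochSkipped) as err:
                ds.psv_epoch(phases, WHOLE_STIMULI,
                             [ds.ElectrodePair("a", "b")], epoch_id="demo-3")
        assert err.value.epoch_id == "demo-3"

    def test_aggregate_condition_mean_and_permutation_invariance(self):
        p = ds.ElectrodePair("a", "b")
        epochs = [{p: v} for v in (0.2, 0.4, 0.6, 0.8)]
        assert ds.aggregate_condition(epochs)[p] == pytest.approx(0.5)
        assert ds.aggregate_condition(epochs[::-1])[p] == pytest.approx(0.5)
        assert ds.aggregate_condition([{p: 0.37}] * 4)[p] == pytest.approx(0.37)

    def test_aggregate_condition_empty_cell(self):
        with pytest.raises(MissingCellError):
            ds.aggregate_condition([])

    def test_psv_rest_matches_epoch_machinery(self, rng):
        rate = 256.0
        x = rng.standard_normal(int(20 * rate))
        y = rng.standard_normal(int(20 * rate))
        phases = {"a": phases_of(x), "b": phases_of(y)}
        pairs = [ds.ElectrodePair("a", "b")]
        out = ds.psv_rest(phases, pairs)
        again = ds.psv_epoch(phases, REST, pairs)
        assert out == again

    def test_batched_phase_equals_per_block_phase(self, rng):
        from deltasync.psv import phase_matrix_batch

        blocks = [rng.standard_normal((2, n)) for n in (700, 1024, 700, 333)]
        batched = phase_matrix_batch(blocks)
        for b, got in zip(blocks, batched):
            rec = ds.Recording(b, 256.0, ("a", "b"), band="delta")
            np.testing.assert_array_equal(got, ds.phase_matrix(rec))

    def test_matrix_path_matches_plv_per_window(self, rng):
        rate = 128.0
        sig = rng.standard_normal((3, int(16 * rate)))
        ph = np.stack([phases_of(s, rate).phases for s in sig])
        mat = ds.psv_epoch_matrix(ph, rate, 16.0, WHOLE_STIMULI)
        windows = ds.segment_windows(16.0, WHOLE_STIMULI)
        for i in range(3):
            for j in range(i + 1, 3):
                vals = []
                for w0, w1 in windows:
                    s0 = int(np.floor(w0 * rate + 1e-9))
                    s1 = s0 + int(round((w1 - w0) * rate))
                    vals.append(plv_brute(ph[i, s0:s1], ph[j, s0:s1]))
                assert mat[i, j] == pytest.approx(np.mean(vals), abs=1e-12)
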