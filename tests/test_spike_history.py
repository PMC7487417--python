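import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcpnn_cue import SpikeHistoryBuffer, StatusRecorder
from bcpnn_cue.activity import LOSER, SILENT, WINNER
from bcpnn_cue.spike_history import ApproxFunction, approx_adaptive, approx_static
from bcpnn_cue.rate_table import rate_constants


@given(seed=st.integers(0, 10**6))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_buffer_recall_is_exact_within_window(seed):
    rng = np.random.default_rng(seed)
    L, T = 16, 50
    raster = rng.random((T, 2, 3)) < 0.3
    buf = SpikeHistoryBuffer(2, 3, L)
    for t in range(T):
        buf.push(raster[t], t)
    lo = T - L
    assert np.array_equal(buf.window(lo, T - 1), raster[lo:])
    t = int(rng.integers(lo, T))
    assert buf.query(1, 2, t) == raster[t, 1, 2]


def test_buffer_window_boundaries_and_errors():
    buf = SpikeHistoryBuffer(1, 1, 10)
    for t in range(15):
        buf.push(np.array([[t % 2 == 0]]), t)
    with pytest.raises(IndexError):
        buf.query(0, 0, 4)       # oldest 5 steps fell beyond the LBH
    assert buf.query(0, 0, 5) is False or buf.query(0, 0, 5) in (True, False)
    with pytest.raises(IndexError):
        buf.query(0, 0, 15)      # the future
    with pytest.raises(ValueError):
        buf.push(np.array([[False]]), 20)  # non-consecutive push


def test_zero_length_buffer_rejects_every_query():
    buf = SpikeHistoryBuffer(1, 1, 0)
    buf.push(np.array([[True]]), 0)
    with pytest.raises(IndexError):
        buf.query(0, 0, 0)


def test_recorder_coverage_and_storage_claim():
    rec = StatusRecorder(1, 1, record_period=300, record_slots=32)
    assert rec.coverage_steps == 9600


def test_recorder_nearest_record_with_older_tie_break():
    rec = StatusRecorder(1, 1, record_period=10, record_slots=8)
    rec.record(10, np.array([[WINNER]], dtype=np.int8))
    rec.record(20, np.array([[LOSER]], dtype=np.int8))
    assert rec.status_at([12])[0, 0, 0] == WINNER
    assert rec.status_at([18])[0, 0, 0] == LOSER
    assert rec.status_at([15])[0, 0, 0] == WINNER   # tie -> older record
    assert rec.status_at([500])[0, 0, 0] == LOSER   # beyond newest: nearest
    with pytest.raises(ValueError):
        StatusRecorder(1, 1).status_at([5])


def test_recorder_ring_drops_oldest():
    rec = StatusRecorder(1, 1, record_period=1, record_slots=3)
    for t, code in enumerate([WINNER, LOSER, SILENT, LOSER]):
        rec.record(t, np.array([[code]], dtype=np.int8))
    assert rec.status_at([0])[0, 0, 0] == LOSER  # slot 0 (winner) evicted


def test_static_approximation_rate():
    rc = rate_constants(10)
    assert not approx_static(5, 0.5, rc.r_s)     # r_s = 0.01 for M = 10
    rng = np.random.default_rng(3)
    n = 10**6
    hits = approx_static(0, rng.random(n), rc.r_s).mean()
    assert abs(hits - rc.r_s) < 3 * np.sqrt(rc.r_s / n)


def test_adaptive_approximation_uses_table_rates():
    rec = StatusRecorder(1, 1, record_period=10, record_slots=4)
    rec.record(0, np.array([[WINNER]], dtype=np.int8))
    rc = rate_constants(10)
    assert rec.rates_at([3], 10)[0, 0, 0] == pytest.approx(rc.r_w)  # 0.0991090
    assert approx_adaptive(3, rec, 10, x=np.array([[[0.05]]]))[0, 0, 0]
    rec100 = StatusRecorder(1, 1)
    rec100.record(0, np.array([[SILENT]], dtype=np.int8))
    assert rec100.rates_at([0], 100)[0, 0, 0] == pytest.approx(0.001)  # r_s, M=100


def test_all_silent_adaptive_equals_static():
    rec = StatusRecorder(2, 5)
    rec.record(0, np.full((2, 5), SILENT, dtype=np.int8))
    adaptive = ApproxFunction("adaptive", 2, 5, recorder=rec)
    static = ApproxFunction("static", 2, 5)
    rng1 = np.random.default_rng(9)
    rng2 = np.random.default_rng(9)
    a = adaptive.predict(0, 99, rng1)
    s = static.predict(0, 99, rng2)
    assert np.array_equal(a, s)


def test_oracle_predicts_recorded_history():
    raster = np.zeros((20, 1, 2), dtype=bool)
    raster[7, 0, 1] = True
    oracle = ApproxFunction("oracle", 1, 2, raster=raster)
    got = oracle.predict(5, 9, np.random.default_rng(0))
    assert got[2, 0, 1] and got.sum() == 1
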