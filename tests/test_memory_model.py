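import numpy as np
import pytest

from bcpnn_cue import (
    SimulationConfig,
    demand_report,
    expected_update_rates,
    row_column_traffic,
    run_simulation,
    storage_bytes,
    storage_report,
)
from bcpnn_cue.io import make_patterns
from bcpnn_cue.memory_model import AccessLedger, IVEC_VARS, JVEC_VARS, WORD


def test_synaptic_storage_human_cortex_hypercolumn():
    lazy = storage_bytes("lazy", n_conn=10**4, n_mcu=100)
    assert lazy["synaptic_bytes"] == 10**4 * 100 * 6 * 4  # 24 MB
    cue = storage_bytes("cue", n_conn=10**4, n_mcu=100, buffer_len=100)
    red = 100 * (1 - cue["synaptic_bytes"] / lazy["synaptic_bytes"])
    assert red == pytest.approx(100 * 2 / 6)  # two of six variables removed


def test_flushing_keeps_lazy_storage_plus_buffer():
    lazy = storage_bytes("lazy", 1000, 50, buffer_len=100)
    flush = storage_bytes("flushing", 1000, 50, buffer_len=100)
    assert flush["synaptic_bytes"] == lazy["synaptic_bytes"]
    assert flush["buffer_bytes"] == (50 * 100 + 7) // 8
    assert flush["total_bytes"] > lazy["total_bytes"]


def test_storage_report_reductions():
    rep = storage_report(10**4, 100, buffer_len=100)
    assert rep["lazy"]["synaptic_reduction_pct"] == 0.0
    assert rep["cue"]["synaptic_reduction_pct"] == pytest.approx(33.333, abs=0.01)


def test_row_column_traffic_240kb_equivalence():
    # 100 rows of a 10^4 x 100 matrix with six 4-byte variables = 240 KB,
    # and a single column moves exactly the same amount
    assert row_column_traffic(10**4, 100, n_rows=100, n_cols=0) == 240_000
    assert row_column_traffic(10**4, 100, n_rows=0, n_cols=1) == 240_000
    assert row_column_traffic(10**4, 100, 0, 0) == 0


def test_expected_update_rates():
    assert expected_update_rates(10**4, 100, r_max=0.1, dt=1.0) == (10_000.0, 100.0)
    assert expected_update_rates(100, 10, r_max=0.1, dt=1.0) == (1000.0, 100.0)
    assert expected_update_rates(100, 10, r_max=0.0) == (0.0, 0.0)


def test_ledger_event_byte_formulas():
    led = AccessLedger("lazy", n_hcu=2, n_mcu=5, n_conn=10)
    led.row_event()
    per_hcu_cells = 5 * 6 * WORD
    assert led.n_load_bytes == 2 * (per_hcu_cells + IVEC_VARS * WORD)
    assert led.n_store_bytes == led.n_load_bytes
    led2 = AccessLedger("lazy", 2, 5, 10)
    led2.col_event()
    assert led2.n_load_bytes == 10 * 6 * WORD
    led3 = AccessLedger("cue", 2, 5, 10)
    led3.row_event()
    assert led3.n_load_bytes == 2 * (5 * 4 * WORD + IVEC_VARS * WORD)
    led3.step()
    assert led3.n_load_bytes - 2 * (5 * 4 * WORD + IVEC_VARS * WORD) == 2 * 5 * JVEC_VARS * WORD


def test_demand_report_identity_and_mismatch():
    cfg = SimulationConfig(n_hcu=2, n_mcu=3, seed=1)
    sched = make_patterns(2, 3, n_patterns=2, duration=50, seed=0)
    a = run_simulation(cfg.replace(strategy="lazy"), sched)
    b = run_simulation(cfg.replace(strategy="lazy"), sched)
    rep = demand_report(a.ledger, b.ledger)
    assert rep["reduction_pct"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        demand_report(b.ledger, run_simulation(
            SimulationConfig(n_hcu=3, n_mcu=3, seed=1).replace(strategy="cue"),
            make_patterns(3, 3, 2, 50, 0)).ledger)


def test_cue_and_flushing_demand_ordering(paper_scale_runs):
    """CUE removes the column share and shrinks cells; flushing only
    regroups column updates, so its saving is smaller."""
    lazy = paper_scale_runs[("lazy", "none")].ledger
    cue = paper_scale_runs[("cue", "static")].ledger
    flush = paper_scale_runs[("flushing", "none")].ledger
    r_cue = demand_report(lazy, cue)["reduction_pct"]
    r_flush = demand_report(lazy, flush)["reduction_pct"]
    assert 0 < r_flush < r_cue < 50


def test_lazy_and_flushing_synaptic_trajectories_identical(paper_scale_runs):
    lazy = paper_scale_runs[("lazy", "none")]
    flush = paper_scale_runs[("flushing", "none")]
    assert np.allclose(lazy.eval_weights, flush.eval_weights, rtol=1e-10, atol=1e-10)
    assert flush.ledger.n_col_events == 0  # columns only via flush events
    assert flush.ledger.n_flush_events > 0
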