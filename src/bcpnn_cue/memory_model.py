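"""Storage and logical memory-traffic accounting.

Counters are *logical* bytes — synaptic-state words actually read or
written by the algorithm (cells x variables x 4-byte words) — not cache
lines or DRAM transactions.  A configurable line-size factor ``k_line``
can multiply the totals when modelling a specific cache, but the package
models no particular hardware and defaults to 1.

Per-synapse state variables by strategy:

* time-driven — e_ij, p_ij, w_ij (3 words; z traces live in the vectors)
* lazy / flushing — e_ij, p_ij, w_ij, z_i2, z_j2, t_ij (6 words)
* CUE — e_ij, p_ij, w_ij, z_j2 (4 words; the per-cell timestamp collapses
  onto the row timestamp and z_i2 onto the i-vector z_i)

The CUE/flushing spike buffer stores L bits per minicolumn; a row update
queries it at one word per minicolumn and every step pushes M bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WORD = 4  # bytes per stored variable

VARS_PER_CELL = {"time_driven": 3, "lazy": 6, "cue": 4, "flushing": 6}
IVEC_VARS = 4  # z_i, e_i, p_i, t_i
JVEC_VARS = 3  # z_j, e_j, p_j


@dataclass
class AccessLedger:
    """Logical byte counts of synaptic-state traffic during one run.

    ``n_load_bytes``/``n_store_bytes`` cover the ij-matrix events, the
    i-/j-vector updates and the weight-row loads of support integration;
    ``buffer_bytes`` covers spike-buffer pushes and queries.
    """

    strategy: str
    n_hcu: int
    n_mcu: int
    n_conn: int
    n_steps: int = 0
    n_load_bytes: int = 0
    n_store_bytes: int = 0
    buffer_bytes: int = 0
    n_row_events: int = 0
    n_col_events: int = 0
    n_flush_events: int = 0

    @property
    def vars_per_cell(self) -> int:
        return VARS_PER_CELL[self.strategy]

    @property
    def total_bytes(self) -> int:
        return self.n_load_bytes + self.n_store_bytes + self.buffer_bytes

    # -- engine hooks -------------------------------------------------------

    def step(self) -> None:
        """Per-step j-vector (time-driven) update traffic, all hypercolumns."""
        self.n_steps += 1
        b = self.n_hcu * self.n_mcu * JVEC_VARS * WORD
        self.n_load_bytes += b
        self.n_store_bytes += b

    def row_event(self, n_hcu_touched: int | None = None) -> None:
        """One presynaptic spike: a row update in each receiving hypercolumn."""
        h = self.n_hcu if n_hcu_touched is None else n_hcu_touched
        self.n_row_events += h
        cell = self.n_mcu * self.vars_per_cell * WORD
        ivec = IVEC_VARS * WORD
        self.n_load_bytes += h * (cell + ivec)
        self.n_store_bytes += h * (cell + ivec)

    def weight_read(self, n_hcu_touched: int | None = None) -> None:
        """Loading one weight row per hypercolumn for support integration."""
        h = self.n_hcu if n_hcu_touched is None else n_hcu_touched
        self.n_load_bytes += h * self.n_mcu * WORD

    def col_event(self, flush: bool = False) -> None:
        """One column update (lazy) or flush replay (flushing) of C cells."""
        if flush:
            self.n_flush_events += 1
        else:
            self.n_col_events += 1
        b = self.n_conn * self.vars_per_cell * WORD
        self.n_load_bytes += b
        self.n_store_bytes += b

    def buffer_push(self) -> None:
        """Per-step push of M bits per hypercolumn."""
        self.buffer_bytes += self.n_hcu * self.n_mcu // 8 or 1

    def buffer_query(self, n_hcu_touched: int | None = None) -> None:
        """Row-update buffer read: one word per minicolumn per hypercolumn."""
        h = self.n_hcu if n_hcu_touched is None else n_hcu_touched
        self.buffer_bytes += h * self.n_mcu * WORD

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_steps": self.n_steps,
            "n_load_bytes": self.n_load_bytes,
            "n_store_bytes": self.n_store_bytes,
            "buffer_bytes": self.buffer_bytes,
            "total_bytes": self.total_bytes,
            "n_row_events": self.n_row_events,
            "n_col_events": self.n_col_events,
            "n_flush_events": self.n_flush_events,
        }


# ---------------------------------------------------------------------------
# analytic storage / traffic arithmetic

def storage_bytes(strategy: str, n_conn: int, n_mcu: int, buffer_len: int = 0) -> dict:
    """Per-hypercolumn storage breakdown in bytes.

    Synaptic matrix C x M cells at the strategy's variables-per-cell, plus
    the i-/j-vectors, plus the spike buffer (L bits per minicolumn) for the
    buffered strategies.
    """
    if strategy not in VARS_PER_CELL:
        raise ValueError(f"unknown strategy {strategy!r}")
    syn = n_conn * n_mcu * VARS_PER_CELL[strategy] * WORD
    ivec = n_conn * IVEC_VARS * WORD
    jvec = n_mcu * JVEC_VARS * WORD
    buf = (n_mcu * buffer_len + 7) // 8 if strategy in ("cue", "flushing") and buffer_len else 0
    return {
        "strategy": strategy,
        "synaptic_bytes": syn,
        "ivector_bytes": ivec,
        "jvector_bytes": jvec,
        "buffer_bytes": buf,
        "total_bytes": syn + ivec + jvec + buf,
    }


def storage_report(n_conn: int, n_mcu: int, buffer_len: int = 100,
                   strategies=("lazy", "cue", "flushing")) -> dict:
    """Storage table plus percent reductions relative to the lazy baseline."""
    table = {s: storage_bytes(s, n_conn, n_mcu, buffer_len) for s in strategies}
    base = table["lazy"]
    for s, row in table.items():
        row["synaptic_reduction_pct"] = 100.0 * (1 - row["synaptic_bytes"] / base["synaptic_bytes"])
        row["total_reduction_pct"] = 100.0 * (1 - row["total_bytes"] / base["total_bytes"])
    return table


def row_column_traffic(n_conn: int, n_mcu: int, n_rows: int, n_cols: int,
                       n_vars: int = 6, word: int = WORD) -> int:
    """Bytes moved by ``n_rows`` row updates and ``n_cols`` column updates.

    A row touches M cells, a column touches C cells; with the human-cortex
    hypercolumn shape (C = 10^4, M = 100, 6 variables) 100 rows and 1
    column each amount to the same 240 KB.
    """
    return (n_rows * n_mcu + n_cols * n_conn) * n_vars * word


def expected_update_rates(n_conn: int, n_mcu: int, r_max: float = 0.1,
                          dt: float = 1.0) -> tuple[float, float]:
    """Expected (rows/s, columns/s) of synaptic updates per hypercolumn.

    Every connection fires at the mean rate <r> = r_max / M per step, so a
    hypercolumn sees ``C <r>`` row updates and ``M <r>`` column updates per
    step; multiplied by the 1000/dt steps per second.
    """
    steps_per_second = 1000.0 / dt
    mean_rate = r_max / n_mcu
    return (n_conn * mean_rate * steps_per_second,
            n_mcu * mean_rate * steps_per_second)


def demand_report(ledger_lazy: AccessLedger, ledger_other: AccessLedger,
                  k_line: float = 1.0) -> dict:
    """Percent reduction in logical traffic of a strategy vs the lazy baseline.

    Both ledgers must come from runs with identical shape, schedule and
    seed; bytes include the spike-buffer overhead.  ``k_line`` scales both
    totals by a cache-line factor (cancels in the percentage).
    """
    for attr in ("n_hcu", "n_mcu", "n_conn", "n_steps"):
        if getattr(ledger_lazy, attr) != getattr(ledger_other, attr):
            raise ValueError(f"mismatched runs: {attr} differs between ledgers")
    if ledger_lazy.strategy != "lazy":
        raise ValueError("baseline ledger must come from the lazy strategy")
    base = k_line * ledger_lazy.total_bytes
    other = k_line * ledger_other.total_bytes
    return {
        "strategy": ledger_other.strategy,
        "lazy_bytes": base,
        "other_bytes": other,
        "reduction_pct": 100.0 * (1.0 - other / base),
        "lazy": ledger_lazy.to_dict(),
        "other": ledger_other.to_dict(),
    }
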