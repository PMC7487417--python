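"""The four synaptic-matrix update engines over identical network dynamics.

* ``time_driven`` — forward-Euler update of every trace at every step.
* ``lazy``        — event-driven baseline: presynaptic spikes trigger row
  updates, post-synaptic spikes trigger column updates, each applying the
  exact closed-form gap update.
* ``cue``         — column-update elimination: post-synaptic spikes only go
  into a spike-history buffer; a row update replays the buffered spikes of
  its gap segment-by-segment and *predicts* spikes older than the look-back
  horizon with the configured approximation function.  With the oracle
  predictor (or an unbounded buffer) CUE is trajectory-identical to lazy.
* ``flushing``    — exactness-preserving alternative: row updates replay
  buffered spikes, and a spike about to fall out of the buffer forces a
  column update that replays and clears the column's buffered spikes, so no
  spike information is ever lost.

All engines share spike generation, j-vector kinetics and support
integration, and consume identical random draws per (seed, hypercolumn,
minicolumn) stream, so runs with a common seed are spike-train identical
and synaptic trajectories are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import (
    LOSER, SILENT, WINNER,
    PatternSchedule, apply_pattern, integrate_support, regime_codes, soft_wta,
)
from .config import SimulationConfig, DerivedConstants, derive_constants
from .kernels import compute_bias, compute_weight, postsyn_decay, presyn_decay, syn_decay
from .memory_model import AccessLedger
from .spike_history import ApproxFunction, SpikeHistoryBuffer, StatusRecorder

_APPROX_STREAM_TAG = 0xA9  # keys the beyond-LBH prediction substreams


# ---------------------------------------------------------------------------
# helpers

def _padded_spike_times(rec: np.ndarray, steps_abs: np.ndarray) -> np.ndarray:
    """Per-cell ordered spike-time table from a time-major raster block.

    ``rec`` is (n_steps, n_cells) boolean, ``steps_abs`` the absolute step
    of each row.  Returns a (K_max, n_cells) int64 array of each cell's
    spike steps in order, padded with -1, so the caller can replay the
    k-th segment of every cell in lock-step.
    """
    n, N = rec.shape
    step_idx, cell_idx = np.nonzero(rec)
    if step_idx.size == 0:
        return np.zeros((0, N), dtype=np.int64)
    order = np.lexsort((step_idx, cell_idx))
    cells = cell_idx[order]
    steps = steps_abs[step_idx[order]]
    counts = np.bincount(cells, minlength=N)
    first = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(counts, out=first[1:])
    rank = np.arange(cells.size) - first[cells]
    times = np.full((int(counts.max()), N), -1, dtype=np.int64)
    times[rank, cells] = steps
    return times


def _replay_segments(e, p, zi, zj, cur, times, t_now, k: DerivedConstants, dt: float,
                     final_advance: bool = True):
    """Advance flattened synapse cells through their post-synaptic spikes.

    Each column of ``times`` holds one cell's spike steps (−1 padded).  Per
    segment the e/p traces advance by the exact closed form using the z
    values at the segment start, both z copies decay, and the post-synaptic
    copy gains +1 at the spike.  With ``final_advance`` the cells are then
    advanced to ``t_now`` (no spike added there).
    """
    for kk in range(times.shape[0]):
        tk = times[kk]
        valid = tk >= 0
        d = np.where(valid, tk - cur, 0) * dt
        e, p = syn_decay(e, p, zi * zj, d, k)
        zi = zi * np.exp(-d / k.tau_zi)
        zj = zj * np.exp(-d / k.tau_zj) + valid
        cur = np.where(valid, tk, cur)
    if final_advance:
        d = (t_now - cur) * dt
        e, p = syn_decay(e, p, zi * zj, d, k)
        zi = zi * np.exp(-d / k.tau_zi)
        zj = zj * np.exp(-d / k.tau_zj)
        cur = np.full_like(cur, t_now)
    return e, p, zi, zj, cur


# ---------------------------------------------------------------------------
# engines

class _EngineBase:
    """State shared by all engines: i-vector, j-vector, ij-matrix."""

    nvars = 6

    def __init__(self, cfg: SimulationConfig, k: DerivedConstants, ledger: AccessLedger):
        H, M, C = cfg.n_hcu, cfg.n_mcu, cfg.n_conn
        if C != H * M:
            raise NotImplementedError(
                "engines implement full connectivity: n_conn must equal n_hcu * n_mcu"
            )
        self.cfg, self.k, self.ledger = cfg, k, ledger
        self.H, self.M, self.C = H, M, C
        # presynaptic i-vector (identical for every hypercolumn under full
        # connectivity, so stored once; traffic is charged per hypercolumn)
        self.iz = np.zeros(C)
        self.ie = np.zeros(C)
        self.ip = np.zeros(C)
        # timestamps start at -1 ("before step 0") so the first half-open
        # gap (t_last, t] includes events occurring at step 0
        self.it = np.full(C, -1, dtype=np.int64)
        # post-synaptic j-vector, time-driven
        self.jz = np.zeros((H, M))
        self.je = np.zeros((H, M))
        self.jp = np.zeros((H, M))
        # ij-matrix
        self.E = np.zeros((H, C, M))
        self.P = np.zeros((H, C, M))
        self.W = np.zeros((H, C, M))

    def j_step(self, s: np.ndarray) -> None:
        """Exact one-step advance of the post-synaptic chain; spike added last."""
        dt = self.cfg.dt
        z, e, p = postsyn_decay(self.jz, self.je, self.jp, dt, self.k)
        self.jz = z + s
        self.je, self.jp = e, p

    def _i_row_advance(self, r: int, t: int) -> None:
        d = (t - self.it[r]) * self.cfg.dt
        z, e, p = presyn_decay(self.iz[r], self.ie[r], self.ip[r], d, self.k)
        self.iz[r] = z + 1.0
        self.ie[r], self.ip[r] = e, p
        self.it[r] = t

    def weights(self) -> np.ndarray:
        return self.W

    def process(self, t: int, s: np.ndarray, rows: np.ndarray):
        raise NotImplementedError


class TimeDrivenEngine(_EngineBase):
    """Per-step forward Euler of every trace (the reference dynamics)."""

    nvars = 3

    def j_step(self, s: np.ndarray) -> None:
        dt, k = self.cfg.dt, self.k
        je = self.je + dt * (self.jz - self.je) / k.tau_e
        jp = self.jp + dt * (self.je - self.jp) / k.tau_p
        self.jz = self.jz * (1.0 - dt / k.tau_zj) + s
        self.je, self.jp = je, jp

    def process(self, t: int, s: np.ndarray, rows: np.ndarray) -> None:
        dt, k, cfg = self.cfg.dt, self.k, self.cfg
        zz = self.iz[None, :, None] * self.jz_prev[:, None, :]
        E = self.E + dt * (zz - self.E) / k.tau_e
        self.P = self.P + dt * (self.E - self.P) / k.tau_p
        self.E = E
        # i-vector Euler with decay-then-spike
        s_i = np.zeros(self.C)
        s_i[rows] = 1.0
        ie = self.ie + dt * (self.iz - self.ie) / k.tau_e
        ip = self.ip + dt * (self.ie - self.ip) / k.tau_p
        self.iz = self.iz * (1.0 - dt / k.tau_zi) + s_i
        self.ie, self.ip = ie, ip
        self.W = compute_weight(self.ip[None, :, None], self.jp[:, None, :],
                                self.P, cfg.weight_floor)
        # full-matrix traffic each step
        b = self.H * self.C * self.M * self.nvars * 4
        self.ledger.n_load_bytes += b
        self.ledger.n_store_bytes += b

    def step_pre(self) -> None:
        # z_j before this step's j-vector update feeds the ij Euler input
        self.jz_prev = self.jz.copy()


class LazyEngine(_EngineBase):
    """Event-driven baseline: exact row and column gap updates."""

    nvars = 6

    def __init__(self, cfg, k, ledger):
        super().__init__(cfg, k, ledger)
        self.ZI2 = np.zeros((self.H, self.C, self.M))
        self.ZJ2 = np.zeros((self.H, self.C, self.M))
        self.TIJ = np.full((self.H, self.C, self.M), -1, dtype=np.int64)
        self.eval_log: list[tuple[int, int, np.ndarray]] = []

    def _col_update(self, h: int, j: int, t: int) -> None:
        dt, k = self.cfg.dt, self.k
        d = (t - self.TIJ[h, :, j]) * dt
        e, p = syn_decay(self.E[h, :, j], self.P[h, :, j],
                         self.ZI2[h, :, j] * self.ZJ2[h, :, j], d, k)
        self.E[h, :, j], self.P[h, :, j] = e, p
        self.ZI2[h, :, j] = self.ZI2[h, :, j] * np.exp(-d / k.tau_zi)
        self.ZJ2[h, :, j] = self.ZJ2[h, :, j] * np.exp(-d / k.tau_zj) + 1.0
        self.TIJ[h, :, j] = t
        self.ledger.col_event()

    def _row_update(self, r: int, t: int) -> None:
        dt, k, cfg = self.cfg.dt, self.k, self.cfg
        sl = (slice(None), r, slice(None))
        d = (t - self.TIJ[sl]) * dt
        e, p = syn_decay(self.E[sl], self.P[sl], self.ZI2[sl] * self.ZJ2[sl], d, k)
        self.E[sl], self.P[sl] = e, p
        self.ZI2[sl] = self.ZI2[sl] * np.exp(-d / k.tau_zi) + 1.0
        self.ZJ2[sl] = self.ZJ2[sl] * np.exp(-d / k.tau_zj)
        self.TIJ[sl] = t
        self._i_row_advance(r, t)
        self.W[sl] = compute_weight(self.ip[r], self.jp, self.P[sl], cfg.weight_floor)
        self.ledger.row_event()
        self.eval_log.append((t, r, self.W[sl].copy()))

    def process(self, t: int, s: np.ndarray, rows: np.ndarray) -> None:
        # post-synaptic spikes are applied before presynaptic bookkeeping
        for h, j in zip(*np.nonzero(s)):
            self._col_update(int(h), int(j), t)
        for r in rows:
            self._row_update(int(r), t)

    def sync(self, t: int) -> None:
        """Advance every cell and i-vector row to step ``t`` (no spikes
        added) and refresh all weights — a coherent state snapshot."""
        dt, k, cfg = self.cfg.dt, self.k, self.cfg
        d = (t - self.TIJ) * dt
        self.E, self.P = syn_decay(self.E, self.P, self.ZI2 * self.ZJ2, d, k)
        self.ZI2 = self.ZI2 * np.exp(-d / k.tau_zi)
        self.ZJ2 = self.ZJ2 * np.exp(-d / k.tau_zj)
        self.TIJ[:] = t
        di = (t - self.it) * dt
        self.iz, self.ie, self.ip = presyn_decay(self.iz, self.ie, self.ip, di, k)
        self.it[:] = t
        self.W = compute_weight(self.ip[None, :, None], self.jp[:, None, :],
                                self.P, cfg.weight_floor)


class CueEngine(_EngineBase):
    """Column-update elimination: rows only, buffer + approximation.

    Per-cell timestamps collapse onto the shared row timestamp ``t_i`` and
    the presynaptic z copy onto the i-vector ``z_i`` (4 state variables per
    cell).  A row update reconstructs each column's post-synaptic spike
    train over the gap — exactly from the buffer where possible, predicted
    beyond the look-back horizon — and replays it segment by segment.
    """

    nvars = 4

    def __init__(self, cfg, k, ledger, approx: ApproxFunction,
                 buffer: SpikeHistoryBuffer):
        super().__init__(cfg, k, ledger)
        self.ZJ2 = np.zeros((self.H, self.C, self.M))
        self.approx = approx
        self.buffer = buffer
        self.eval_log: list[tuple[int, int, np.ndarray]] = []

    def _row_update(self, r: int, t: int) -> None:
        cfg, k, dt = self.cfg, self.k, self.cfg.dt
        N = self.H * self.M
        t0 = int(self.it[r])
        lbh = t - cfg.buffer_len
        n_beyond = max(0, min(lbh, t) - t0)
        parts = []
        if n_beyond > 0:
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([cfg.seed, _APPROX_STREAM_TAG, r, t])))
            parts.append(self.approx.predict(t0 + 1, t0 + n_beyond, rng))
        buf_lo = max(t0, lbh) + 1
        if buf_lo <= t:
            parts.append(self.buffer.window(buf_lo, t))
        rec = (np.concatenate(parts, axis=0) if parts
               else np.zeros((0, self.H, self.M), dtype=bool))
        steps_abs = np.arange(t0 + 1, t + 1, dtype=np.int64)
        times = _padded_spike_times(rec.reshape(rec.shape[0], N), steps_abs)
        e = self.E[:, r, :].reshape(N).copy()
        p = self.P[:, r, :].reshape(N).copy()
        zj = self.ZJ2[:, r, :].reshape(N).copy()
        zi = np.full(N, self.iz[r])
        cur = np.full(N, t0, dtype=np.int64)
        e, p, zi, zj, _ = _replay_segments(e, p, zi, zj, cur, times, t, k, dt)
        self.E[:, r, :] = e.reshape(self.H, self.M)
        self.P[:, r, :] = p.reshape(self.H, self.M)
        self.ZJ2[:, r, :] = zj.reshape(self.H, self.M)
        self._i_row_advance(r, t)
        self.W[:, r, :] = compute_weight(self.ip[r], self.jp, self.P[:, r, :],
                                         cfg.weight_floor)
        self.ledger.row_event()
        self.ledger.buffer_query()
        self.eval_log.append((t, r, self.W[:, r, :].copy()))

    def process(self, t: int, s: np.ndarray, rows: np.ndarray) -> None:
        self.buffer.push(s, t)
        self.ledger.buffer_push()
        for r in rows:
            self._row_update(int(r), t)


class FlushingEngine(_EngineBase):
    """Buffered lazy evaluation with forced column updates at spike expiry.

    Row updates replay buffered post-synaptic spikes; when a buffered spike
    of column j reaches the buffer tail, a column update replays *all* of
    j's buffered spikes exactly and marks them consumed.  No spike is ever
    predicted, so the strategy is exact.
    """

    nvars = 6

    def __init__(self, cfg, k, ledger, buffer: SpikeHistoryBuffer, raster_ref):
        super().__init__(cfg, k, ledger)
        self.ZI2 = np.zeros((self.H, self.C, self.M))
        self.ZJ2 = np.zeros((self.H, self.C, self.M))
        self.TIJ = np.full((self.H, self.C, self.M), -1, dtype=np.int64)
        self.buffer = buffer
        self.raster_ref = raster_ref  # callable: step -> (H, M) bool
        # newest step whose spikes have been flushed (consumed), per column
        self.consumed = np.full((self.H, self.M), -1, dtype=np.int64)
        self.eval_log: list[tuple[int, int, np.ndarray]] = []

    def _flush(self, h: int, j: int, t: int) -> None:
        dt, k = self.cfg.dt, self.k
        lo = max(0, t - self.cfg.buffer_len)
        spikes = [u for u in range(lo, t + 1)
                  if u > self.consumed[h, j] and self.raster_ref(u)[h, j]]
        cur = self.TIJ[h, :, j].copy()
        e, p = self.E[h, :, j].copy(), self.P[h, :, j].copy()
        zi, zj = self.ZI2[h, :, j].copy(), self.ZJ2[h, :, j].copy()
        for u in spikes:
            m = cur < u
            d = np.where(m, u - cur, 0) * dt
            e, p = syn_decay(e, p, zi * zj, d, k)
            zi = zi * np.exp(-d / k.tau_zi)
            zj = zj * np.exp(-d / k.tau_zj) + m
            cur = np.where(m, u, cur)
        self.E[h, :, j], self.P[h, :, j] = e, p
        self.ZI2[h, :, j], self.ZJ2[h, :, j] = zi, zj
        self.TIJ[h, :, j] = cur
        self.consumed[h, j] = t
        self.ledger.col_event(flush=True)

    def _row_update(self, r: int, t: int) -> None:
        cfg, k, dt = self.cfg, self.k, self.cfg.dt
        N = self.H * self.M
        lo = max(0, t - cfg.buffer_len + 1)
        steps_abs = np.arange(lo, t + 1, dtype=np.int64)
        rec = np.stack([self.raster_ref(u) for u in steps_abs]) if steps_abs.size \
            else np.zeros((0, self.H, self.M), dtype=bool)
        rec2d = rec.reshape(rec.shape[0], N).copy()
        floor = np.maximum(self.TIJ[:, r, :], self.consumed)
        rec2d &= steps_abs[:, None] > floor.reshape(N)[None, :]
        times = _padded_spike_times(rec2d, steps_abs)
        e = self.E[:, r, :].reshape(N).copy()
        p = self.P[:, r, :].reshape(N).copy()
        zi = self.ZI2[:, r, :].reshape(N).copy()
        zj = self.ZJ2[:, r, :].reshape(N).copy()
        cur = self.TIJ[:, r, :].reshape(N).astype(np.int64)
        e, p, zi, zj, _ = _replay_segments(e, p, zi, zj, cur, times, t, k, dt)
        self.E[:, r, :] = e.reshape(self.H, self.M)
        self.P[:, r, :] = p.reshape(self.H, self.M)
        self.ZI2[:, r, :] = zi.reshape(self.H, self.M) + 1.0
        self.ZJ2[:, r, :] = zj.reshape(self.H, self.M)
        self.TIJ[:, r, :] = t
        self._i_row_advance(r, t)
        self.W[:, r, :] = compute_weight(self.ip[r], self.jp, self.P[:, r, :],
                                         cfg.weight_floor)
        self.ledger.row_event()
        self.ledger.buffer_query()
        self.eval_log.append((t, r, self.W[:, r, :].copy()))

    def process(self, t: int, s: np.ndarray, rows: np.ndarray) -> None:
        self.buffer.push(s, t)
        self.ledger.buffer_push()
        te = t - self.cfg.buffer_len
        if te >= 0:
            expiring = self.raster_ref(te) & (te > self.consumed)
            for h, j in zip(*np.nonzero(expiring)):
                self._flush(int(h), int(j), t)
        for r in rows:
            self._row_update(int(r), t)


# ---------------------------------------------------------------------------
# simulation driver

@dataclass
class SimulationResult:
    """Outputs of one schedule run (raster, traffic ledger, evaluation log)."""

    cfg: SimulationConfig
    raster: np.ndarray                 # (n_steps, H, M) bool, this run only
    ledger: AccessLedger
    eval_times: np.ndarray             # (n_events,) step of each row update
    eval_rows: np.ndarray              # (n_events,) presynaptic row index
    eval_weights: np.ndarray           # (n_events, H, M) weights after update
    winners: np.ndarray                # (n_entries, H) argmax support at entry end
    weights: np.ndarray                # final (H, C, M) weight matrix
    regimes: np.ndarray                # (n_steps, H, M) clamped-regime codes (-1 = free)


class Simulation:
    """Stateful simulator: build once, run one or more schedules.

    Spike generation consumes one uniform draw per minicolumn per step from
    a stream keyed by (seed, hypercolumn, minicolumn), so two simulations
    with equal seeds see identical random numbers regardless of strategy.
    """

    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        self.k = derive_constants(cfg)
        H, M = cfg.n_hcu, cfg.n_mcu
        self.ledger = AccessLedger(cfg.strategy, H, M, cfg.n_conn)
        self.raster = np.zeros((0, H, M), dtype=bool)
        self.recorder = StatusRecorder(H, M, cfg.record_period, cfg.record_slots)
        self._mcu_rngs = [
            [np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, h, m])))
             for m in range(M)] for h in range(H)
        ]
        self.t = 0  # global step
        self.h_supp = np.zeros((H, M))
        buffer = None
        if cfg.strategy in ("cue", "flushing"):
            buffer = SpikeHistoryBuffer(H, M, cfg.buffer_len)
        if cfg.strategy == "time_driven":
            self.engine: _EngineBase = TimeDrivenEngine(cfg, self.k, self.ledger)
        elif cfg.strategy == "lazy":
            self.engine = LazyEngine(cfg, self.k, self.ledger)
        elif cfg.strategy == "cue":
            approx = ApproxFunction(
                cfg.approx, H, M, cfg.r_max,
                recorder=self.recorder if cfg.approx == "adaptive" else None,
                raster=_RasterView(self) if cfg.approx == "oracle" else None,
            )
            self.engine = CueEngine(cfg, self.k, self.ledger, approx, buffer)
        elif cfg.strategy == "flushing":
            self.engine = FlushingEngine(cfg, self.k, self.ledger, buffer,
                                         lambda u: self.raster[u])
        else:  # pragma: no cover - guarded by cfg.validate()
            raise ValueError(cfg.strategy)

    # -- dynamics helpers ---------------------------------------------------

    def _classify(self, o: np.ndarray) -> np.ndarray:
        codes = np.full(o.shape, LOSER, dtype=np.int8)
        codes[o > 0.5] = WINNER
        inactive = o.max(axis=1) < 2.0 / self.cfg.n_mcu
        codes[inactive, :] = SILENT
        return codes

    def run(self, schedule: PatternSchedule) -> SimulationResult:
        cfg, H, M = self.cfg, self.cfg.n_hcu, self.cfg.n_mcu
        T = schedule.n_steps
        t_off = self.t
        # extend the global raster, then draw this run's uniforms
        self.raster = np.concatenate(
            [self.raster, np.zeros((T, H, M), dtype=bool)], axis=0)
        if cfg.strategy == "flushing":
            self.engine.raster_ref = lambda u: self.raster[u]
        if cfg.strategy == "cue" and cfg.approx == "oracle":
            self.engine.approx.raster = self.raster
        U = np.empty((T, H, M))
        for h in range(H):
            for m in range(M):
                U[:, h, m] = self._mcu_rngs[h][m].random(T)

        clamp_rates = [None if pat is None else apply_pattern(pat, M, cfg.r_max)
                       for pat, _ in schedule.entries]
        regimes = np.full((T, H, M), -1, dtype=np.int8)
        winners = np.zeros((len(schedule.entries), H), dtype=np.int64)
        n_eval0 = len(self.engine.eval_log) if hasattr(self.engine, "eval_log") else 0

        entry_idx, entry_end = 0, schedule.entries[0][1]
        for step in range(T):
            t = t_off + step
            pat, _ = schedule.entries[entry_idx]
            if schedule.training and pat is not None:
                r = clamp_rates[entry_idx]
                regimes[step] = regime_codes(pat, M)
            else:
                r = cfg.r_max * soft_wta(self.h_supp)
            s = r > U[step]
            self.raster[t] = s
            rows = np.flatnonzero(s.ravel())
            self.ledger.step()
            if isinstance(self.engine, TimeDrivenEngine):
                self.engine.step_pre()
            self.engine.j_step(s)
            self.engine.process(t, s, rows)
            # support integration reads one weight row per presynaptic spike
            drive = compute_bias(self.engine.jp, cfg.weight_floor)
            if rows.size:
                drive = drive + self.engine.W[:, rows, :].sum(axis=1)
                for _ in rows:
                    self.ledger.weight_read()
            self.h_supp = integrate_support(self.h_supp, drive, cfg.tau_m, cfg.dt)
            if (t + 1) % cfg.record_period == 0:
                self.recorder.record(t, self._classify(soft_wta(self.h_supp)))
            if step == entry_end - 1:
                winners[entry_idx] = np.argmax(self.h_supp, axis=1)
                entry_idx += 1
                if entry_idx < len(schedule.entries):
                    entry_end += schedule.entries[entry_idx][1]
            self.t = t + 1

        log = getattr(self.engine, "eval_log", [])[n_eval0:]
        eval_times = np.array([ev[0] for ev in log], dtype=np.int64)
        eval_rows = np.array([ev[1] for ev in log], dtype=np.int64)
        eval_weights = (np.stack([ev[2] for ev in log])
                        if log else np.zeros((0, H, M)))
        return SimulationResult(
            cfg=cfg,
            raster=self.raster[t_off:self.t].copy(),
            ledger=self.ledger,
            eval_times=eval_times,
            eval_rows=eval_rows,
            eval_weights=eval_weights,
            winners=winners,
            weights=self.engine.W.copy(),
            regimes=regimes,
        )


class _RasterView:
    """Sliceable view of the growing global raster (oracle predictor input)."""

    def __init__(self, sim: Simulation):
        self._sim = sim

    def __getitem__(self, item):
        return self._sim.raster[item]


def run_simulation(cfg: SimulationConfig, schedule: PatternSchedule) -> SimulationResult:
    """Run one schedule from a fresh network state (deterministic per seed)."""
    return Simulation(cfg).run(schedule)
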