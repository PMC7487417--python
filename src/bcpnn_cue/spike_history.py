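"""Finite spike-history buffer, status recorder, and approximation functions.

The CUE strategy removes post-synaptic column updates; a row update
triggered at step ``t`` must therefore reconstruct the post-synaptic spike
trains over its gap.  Steps newer than the look-back horizon (LBH)
``t - L`` are recalled exactly from a ring buffer of the last ``L`` steps
(1 bit per minicolumn per step); older steps are *predicted* by an
approximation function H:

* ``static``   — Bernoulli at the constant silent-regime rate
  ``r_s = r_max / M`` (the expectancy of the regime rate distribution).
* ``adaptive`` — Bernoulli at the rate of the winner/loser/silent status
  recorded nearest in time to the queried step.
* ``oracle``   — the true recorded history (testing only; error-free).
* ``none``     — predicts no spikes; drops lost spikes and accumulates a
  systematic one-signed error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import LOSER, WINNER, SILENT
from .rate_table import rate_constants


class SpikeHistoryBuffer:
    """Ring buffer of the last ``L`` steps of post-synaptic spikes.

    Stores one boolean per (hypercolumn, minicolumn) per step; a query at
    step ``t`` is valid only while ``head - L < t <= head`` where ``head``
    is the most recently pushed step.
    """

    def __init__(self, n_hcu: int, n_mcu: int, buffer_len: int):
        if buffer_len < 0:
            raise ValueError("buffer_len must be >= 0")
        self.L = int(buffer_len)
        self.shape = (n_hcu, n_mcu)
        self._bits = np.zeros((max(self.L, 1), n_hcu, n_mcu), dtype=bool)
        self.head = -1  # step of the newest entry; -1 = empty

    @property
    def storage_bits(self) -> int:
        """Logical storage: L bits per minicolumn."""
        return self.L * self.shape[0] * self.shape[1]

    def push(self, spikes: np.ndarray, step: int) -> None:
        """Record the spikes of ``step``; steps must be pushed in order."""
        if step != self.head + 1:
            raise ValueError(f"pushes must be consecutive: head={self.head}, got {step}")
        self.head = step
        if self.L > 0:
            self._bits[step % self.L] = spikes

    def _check_window(self, t_lo: int, t_hi: int) -> None:
        if t_hi > self.head or t_lo <= self.head - self.L:
            raise IndexError(
                f"query [{t_lo}, {t_hi}] outside buffer window "
                f"({self.head - self.L}, {self.head}]"
            )

    def query(self, hcu: int, mcu: int, t: int) -> bool:
        """Exact recall of one spike bit; raises beyond the look-back horizon."""
        self._check_window(t, t)
        return bool(self._bits[t % self.L, hcu, mcu])

    def window(self, t_lo: int, t_hi: int) -> np.ndarray:
        """Spikes of steps ``t_lo .. t_hi`` inclusive, shape (n, H, M)."""
        if t_hi < t_lo:
            return np.zeros((0,) + self.shape, dtype=bool)
        self._check_window(t_lo, t_hi)
        idx = np.arange(t_lo, t_hi + 1) % self.L
        return self._bits[idx]


class StatusRecorder:
    """Coarse winner/loser/silent history for the adaptive predictor.

    One regime code per minicolumn is recorded every ``record_period``
    steps in a ring of ``record_slots`` entries, so the recorder covers
    ``record_slots * record_period`` steps (9600 with the defaults) at a
    cost of 2 bits per entry — a single integer word per minicolumn.
    """

    def __init__(self, n_hcu: int, n_mcu: int, record_period: int = 300,
                 record_slots: int = 32):
        self.period = int(record_period)
        self.slots = int(record_slots)
        self.shape = (n_hcu, n_mcu)
        self._times: list[int] = []
        self._codes: list[np.ndarray] = []

    @property
    def coverage_steps(self) -> int:
        return self.slots * self.period

    def record(self, step: int, codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != self.shape:
            raise ValueError("status codes shape mismatch")
        if self._times and step <= self._times[-1]:
            raise ValueError("records must be appended in increasing step order")
        self._times.append(int(step))
        self._codes.append(codes.copy())
        if len(self._times) > self.slots:
            del self._times[0], self._codes[0]

    def status_at(self, steps: np.ndarray) -> np.ndarray:
        """Regime codes of the record nearest in time to each queried step.

        Ties between two straddling records go to the older one.  Raises if
        nothing has been recorded.  Result shape: ``(len(steps), H, M)``.
        """
        if not self._times:
            raise ValueError("empty status recorder")
        steps = np.atleast_1d(np.asarray(steps, dtype=np.int64))
        times = np.asarray(self._times)
        codes = np.stack(self._codes)
        right = np.searchsorted(times, steps, side="left")
        left = np.clip(right - 1, 0, len(times) - 1)
        right = np.clip(right, 0, len(times) - 1)
        d_left = np.abs(steps - times[left])
        d_right = np.abs(times[right] - steps)
        pick = np.where(d_left <= d_right, left, right)  # tie -> older
        return codes[pick]

    def rates_at(self, steps: np.ndarray, n_mcu: int, r_max: float = 0.1) -> np.ndarray:
        """Predicted firing rate r* per (step, hypercolumn, minicolumn)."""
        rc = rate_constants(n_mcu, r_max)
        lut = np.array([rc.r_l, rc.r_w, rc.r_s])
        return lut[self.status_at(steps)]


def approx_static(t, x, r_s: float):
    """Static approximation: spike iff ``x < r_s`` (constant predicted rate)."""
    return np.asarray(x) < r_s


def approx_adaptive(t, recorder: StatusRecorder, n_mcu: int, x, r_max: float = 0.1):
    """Adaptive approximation: spike iff ``x < r*`` with r* from the nearest
    recorded winner/loser/silent status."""
    rates = recorder.rates_at(np.atleast_1d(t), n_mcu, r_max)
    return np.asarray(x) < rates


@dataclass
class ApproxFunction:
    """Configured beyond-LBH spike predictor used by the CUE engine.

    ``predict(t_lo, t_hi, rng)`` returns a boolean array of shape
    ``(t_hi - t_lo + 1, n_hcu, n_mcu)`` for the requested (old) steps.
    """

    kind: str  # none | static | adaptive | oracle
    n_hcu: int
    n_mcu: int
    r_max: float = 0.1
    recorder: StatusRecorder | None = None
    raster: np.ndarray | None = None  # full history, oracle only

    def __post_init__(self) -> None:
        if self.kind not in ("none", "static", "adaptive", "oracle"):
            raise ValueError(f"unknown approximation kind {self.kind!r}")
        if self.kind == "adaptive" and self.recorder is None:
            raise ValueError("adaptive approximation requires a status recorder")
        if self.kind == "oracle" and self.raster is None:
            raise ValueError("oracle approximation requires the full spike history")

    def predict(self, t_lo: int, t_hi: int, rng: np.random.Generator) -> np.ndarray:
        n = t_hi - t_lo + 1
        shape = (n, self.n_hcu, self.n_mcu)
        if n <= 0:
            return np.zeros((0, self.n_hcu, self.n_mcu), dtype=bool)
        if self.kind == "none":
            return np.zeros(shape, dtype=bool)
        if self.kind == "oracle":
            return np.asarray(self.raster[t_lo:t_hi + 1], dtype=bool)
        x = rng.random(shape)
        if self.kind == "static":
            return x < (self.r_max / self.n_mcu)
        steps = np.arange(t_lo, t_hi + 1)
        if not self.recorder._times:
            # nothing recorded yet: all-silent prior, identical to static
            return x < (self.r_max / self.n_mcu)
        rates = self.recorder.rates_at(steps, self.n_mcu, self.r_max)
        return x < rates
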