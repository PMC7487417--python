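"""Per-step network dynamics: support integration, soft-WTA, spiking.

Minicolumns integrate weighted presynaptic spikes into a leaky support
value, compete within their hypercolumn through a soft winner-take-all
normalization (a softmax over supports), are scaled to a per-step firing
rate ``r_j = r_max * o_j``, and emit spikes through a Bernoulli/Poisson
generator (``s_j = 1`` iff ``r_j > x`` with ``x ~ U[0, 1)``).

Training uses teacher forcing: the target minicolumn of every active
hypercolumn is clamped to ``r_max``, the others to the losing-regime rate
``r_l``, and minicolumns of deactivated hypercolumns fire uniformly at
``r_s = r_max / M``.  This reproduces the winner/loser/silent regime
structure deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_table import rate_constants

# regime codes used throughout the package
LOSER, WINNER, SILENT = 0, 1, 2


@dataclass
class PatternSchedule:
    """Ordered training/recall protocol.

    Each entry is ``(pattern, duration)`` where ``pattern`` is an integer
    array of one target minicolumn per hypercolumn (-1 marks a deactivated
    hypercolumn) and ``duration`` is in steps.
    """

    entries: list[tuple[np.ndarray, int]]
    training: bool = True

    def __post_init__(self) -> None:
        for pat, dur in self.entries:
            if dur <= 0:
                raise ValueError("pattern durations must be positive")

    @property
    def n_steps(self) -> int:
        return sum(d for _, d in self.entries)

    def pattern_at(self, step: int) -> np.ndarray:
        """The pattern active at ``step`` (0-based)."""
        acc = 0
        for pat, dur in self.entries:
            acc += dur
            if step < acc:
                return pat
        raise IndexError(f"step {step} beyond schedule of {self.n_steps} steps")

    def pattern_index_at(self, step: int) -> int:
        acc = 0
        for i, (_, dur) in enumerate(self.entries):
            acc += dur
            if step < acc:
                return i
        raise IndexError(step)


def soft_wta(h: np.ndarray, axis: int = -1) -> np.ndarray:
    """Soft winner-take-all: softmax of supports within each hypercolumn.

    Max-subtracted for numerical stability; the result sums to 1 along
    ``axis``.
    """
    h = np.asarray(h, dtype=float)
    m = np.max(h, axis=axis, keepdims=True)
    ex = np.exp(h - m)
    return ex / np.sum(ex, axis=axis, keepdims=True)


def integrate_support(h, drive, tau_m: float, dt: float = 1.0):
    """One leaky-integrator step ``h' = h + dt ((drive) - h) / tau_m``.

    ``drive`` is the bias plus the weighted presynaptic spike sum
    ``beta_j + sum_i s_i w_ij``.
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    return h + dt * (np.asarray(drive, dtype=float) - h) / tau_m


def spike_draw(r, x):
    """Poisson spike generator: spike iff the rate exceeds the uniform draw."""
    return np.asarray(r) > np.asarray(x)


def apply_pattern(pattern: np.ndarray, n_mcu: int, r_max: float = 0.1) -> np.ndarray:
    """Clamped training rates for one pattern.

    Returns an (n_hcu, n_mcu) rate array: the target minicolumn at
    ``r_max``, the rest of its hypercolumn at the losing rate ``r_l(M)``,
    and every minicolumn of a deactivated hypercolumn (target -1) at
    ``r_s = r_max / M``.
    """
    pattern = np.asarray(pattern)
    if pattern.ndim != 1:
        raise ValueError("pattern must be one target index per hypercolumn")
    if np.any(pattern >= n_mcu):
        raise ValueError("pattern targets a minicolumn index out of range")
    rc = rate_constants(n_mcu, r_max)
    rates = np.full((pattern.size, n_mcu), rc.r_l)
    silent = pattern < 0
    rates[silent, :] = rc.r_s
    active = np.flatnonzero(~silent)
    rates[active, pattern[active]] = r_max
    return rates


def regime_codes(pattern: np.ndarray, n_mcu: int) -> np.ndarray:
    """Regime label (LOSER/WINNER/SILENT) per minicolumn for one pattern."""
    pattern = np.asarray(pattern)
    codes = np.full((pattern.size, n_mcu), LOSER, dtype=np.int8)
    codes[pattern < 0, :] = SILENT
    active = np.flatnonzero(pattern >= 0)
    codes[active, pattern[active]] = WINNER
    return codes


def measure_rate_constants(raster: np.ndarray, regimes: np.ndarray,
                           min_samples: int = 1) -> tuple[float, float, float]:
    """Empirical (r_l, r_w, r_s) from a spike raster and per-step regimes.

    ``raster`` and ``regimes`` are (n_steps, n_hcu, n_mcu) arrays of spike
    booleans and regime codes.  Returns the mean per-step spike frequency
    of losing, winning and silent minicolumn-steps.  Raises if any regime
    has fewer than ``min_samples`` minicolumn-steps.
    """
    raster = np.asarray(raster, dtype=bool)
    regimes = np.asarray(regimes)
    if raster.shape != regimes.shape:
        raise ValueError("raster and regimes shapes differ")
    out = []
    for code in (LOSER, WINNER, SILENT):
        mask = regimes == code
        n = int(mask.sum())
        if n < min_samples:
            raise ValueError(f"regime {code} has only {n} minicolumn-steps")
        out.append(float(raster[mask].mean()) if n else float("nan"))
    return out[0], out[1], out[2]
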