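"""Per-step firing-rate constants of the three minicolumn regimes.

In an associative-memory BCPNN a minicolumn at any instant is in one of
three regimes: the *winner* of an active hypercolumn (rate ``r_w``, close
to ``r_max``), a *loser* of an active hypercolumn (rate ``r_l``, close to
0), or a member of an inactive/silent hypercolumn where the soft-WTA
produces a uniform rate ``r_s = r_max / M``.

``RATE_TABLE`` ships the measured ``r_l``/``r_w`` constants for
M in {10, 20, ..., 100} at ``r_max = 0.1``; they satisfy the mass balance
``(r_w + (M-1) r_l) / M == r_max / M`` for every column, i.e. the mean rate
inside an active hypercolumn equals the silent-hypercolumn rate.
``r_s`` is always computed analytically as ``r_max / M``; ``r_l``/``r_w``
are interpolated linearly in M between the tabulated sizes.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

R_MAX_TABLE = 0.1

# M -> (r_l, r_w); measured per-step rates of losing and winning minicolumns.
RATE_TABLE: dict[int, tuple[float, float]] = {
    10: (0.0000990, 0.0991090),
    20: (0.0000981, 0.0981361),
    30: (0.0000972, 0.0971812),
    40: (0.0000963, 0.0962443),
    50: (0.0000954, 0.0953254),
    60: (0.0000945, 0.0944245),
    70: (0.0000936, 0.0935416),
    80: (0.0000927, 0.0926767),
    90: (0.0000918, 0.0918298),
    100: (0.0000909, 0.0910009),
}


class RateConstants(NamedTuple):
    r_l: float
    r_w: float
    r_s: float


def rate_constants(n_mcu: int, r_max: float = R_MAX_TABLE) -> RateConstants:
    """Regime rates (r_l, r_w, r_s) for a hypercolumn of ``n_mcu`` minicolumns.

    Exact table values at the tabulated sizes, linear interpolation in M
    otherwise (extrapolation is clamped to the table edges).  ``r_s`` is
    always ``r_max / n_mcu``.
    """
    if n_mcu < 1:
        raise ValueError(f"n_mcu must be >= 1, got {n_mcu}")
    ms = np.array(sorted(RATE_TABLE), dtype=float)
    r_l = float(np.interp(n_mcu, ms, [RATE_TABLE[int(m)][0] for m in ms]))
    r_w = float(np.interp(n_mcu, ms, [RATE_TABLE[int(m)][1] for m in ms]))
    if r_max != R_MAX_TABLE:
        # the tabulated rates were measured at r_max = 0.1; rescale
        scale = r_max / R_MAX_TABLE
        r_l, r_w = r_l * scale, r_w * scale
    return RateConstants(r_l=r_l, r_w=r_w, r_s=r_max / n_mcu)
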