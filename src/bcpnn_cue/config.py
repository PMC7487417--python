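"""Simulation configuration and derived filter constants.

All times are in milliseconds; the simulation clock advances in integer
steps of ``dt`` and every timestamp in the package is a 0-based step count.
An interval ``(t', t]`` is half-open on the left: the state stored at a
timestamp already includes the spike that triggered the event there.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

STRATEGIES = ("time_driven", "lazy", "cue", "flushing")
APPROXIMATIONS = ("none", "static", "adaptive", "oracle")


@dataclass
class SimulationConfig:
    """All network, kinetic, strategy and experiment parameters.

    Parameters
    ----------
    n_hcu, n_mcu:
        Network shape: ``n_hcu`` hypercolumns of ``n_mcu`` minicolumn units
        each.  ``n_mcu`` is capped at 100 (a hypercolumn aggregates at most
        ~100 minicolumns); networks grow by adding hypercolumns.
    n_conn:
        Incoming connection slots per hypercolumn (the row count of the
        synaptic matrix).  Defaults to the fully connected value
        ``n_hcu * n_mcu`` when left as ``None``.
    dt:
        Simulation step in ms.
    r_max:
        Maximum per-step firing probability of a minicolumn (0.1 at
        dt = 1 ms corresponds to the ~100 Hz ceiling of an active
        minicolumn's projecting cells).
    tau_zi, tau_zj, tau_e, tau_p:
        Time constants (ms) of the low-pass filter chains
        ``s -> z -> e -> p``; the three must be pairwise distinct because
        the closed-form multi-step update divides by their differences.
    tau_m:
        Membrane/support leak time constant (ms).
    kappa:
        Learning-rate modulation of the probability traces; the effective
        probability time constant is ``tau_p / kappa``.  Default 1.
    buffer_len:
        Post-synaptic spike-history buffer size L in steps.  The look-back
        horizon (LBH) of a row update triggered at step t is ``t - L``.
    record_period, record_slots:
        The adaptive predictor records each minicolumn's winner/loser/silent
        status every ``record_period`` steps in a ring of ``record_slots``
        entries (32 x 300 = 9600 steps of coverage by default).
    epsilon:
        Relative weight-error tolerance used by the error analysis.
    strategy, approx:
        Synaptic update engine and beyond-LBH approximation function.
    weight_floor:
        Probability floor inside the log-odds weight (prevents log 0).
    euler_substep:
        Substep (ms) of the fine-step Euler reference integrator.
    """

    n_hcu: int = 10
    n_mcu: int = 10
    n_conn: int | None = None
    dt: float = 1.0
    r_max: float = 0.1
    tau_zi: float = 10.0
    tau_zj: float = 10.0
    tau_e: float = 200.0
    tau_p: float = 1000.0
    tau_m: float = 10.0
    kappa: float = 1.0
    buffer_len: int = 100
    record_period: int = 300
    record_slots: int = 32
    epsilon: float = 0.01
    strategy: str = "lazy"
    approx: str = "static"
    seed: int = 0
    weight_floor: float = 1e-8
    euler_substep: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_conn is None:
            self.n_conn = int(self.n_hcu) * int(self.n_mcu)

    @property
    def tau_p_eff(self) -> float:
        """Effective probability-trace time constant tau_p / kappa."""
        return self.tau_p / self.kappa

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated invariant."""
        violations = validate_config(self)
        if violations:
            raise ValueError("invalid configuration: " + "; ".join(violations))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DerivedConstants:
    """Coefficients of the closed-form multi-step trace updates.

    For the presynaptic chain ``s_i -> z_i -> e_i -> p_i`` and the synaptic
    chain ``z_i*z_j -> e_ij -> p_ij`` the exact solution of the linear
    filter ODEs over a spike-free gap is a mixture of exponentials whose
    coefficients are::

        a_i  = tau_zi  / (tau_zi  - tau_e)
        b_i  = tau_zi  / (tau_zi  - tau_p*)
        c    = tau_e   / (tau_e   - tau_p*)
        tau_zij = (1/tau_zi + 1/tau_zj)^-1
        a_ij = tau_zij / (tau_zij - tau_e)
        b_ij = tau_zij / (tau_zij - tau_p*)

    with ``tau_p* = tau_p / kappa``.  ``a_j``/``b_j`` are the post-synaptic
    analogues (same formulas with tau_zj).
    """

    a_i: float
    b_i: float
    c: float
    tau_zij: float
    a_ij: float
    b_ij: float
    a_j: float
    b_j: float
    tau_zi: float
    tau_zj: float
    tau_e: float
    tau_p: float  # effective tau_p (tau_p / kappa)


def derive_constants(cfg: SimulationConfig) -> DerivedConstants:
    """Compute the closed-form update constants for ``cfg``.

    Raises ``ValueError`` when any two chained time constants coincide
    (the closed form divides by their difference).
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    tp = cfg.tau_p_eff
    tau_zij = 1.0 / (1.0 / cfg.tau_zi + 1.0 / cfg.tau_zj)
    return DerivedConstants(
        a_i=cfg.tau_zi / (cfg.tau_zi - cfg.tau_e),
        b_i=cfg.tau_zi / (cfg.tau_zi - tp),
        c=cfg.tau_e / (cfg.tau_e - tp),
        tau_zij=tau_zij,
        a_ij=tau_zij / (tau_zij - cfg.tau_e),
        b_ij=tau_zij / (tau_zij - tp),
        a_j=cfg.tau_zj / (cfg.tau_zj - cfg.tau_e),
        b_j=cfg.tau_zj / (cfg.tau_zj - tp),
        tau_zi=cfg.tau_zi,
        tau_zj=cfg.tau_zj,
        tau_e=cfg.tau_e,
        tau_p=tp,
    )


def validate_config(cfg: SimulationConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []

    def _pos(name: str) -> float:
        x = getattr(cfg, name)
        if not (isinstance(x, (int, float)) and math.isfinite(x) and x > 0):
            v.append(f"{name} must be a positive finite number, got {x!r}")
            return float("nan")
        return float(x)

    if not (isinstance(cfg.n_hcu, int) and cfg.n_hcu >= 1):
        v.append(f"n_hcu must be an integer >= 1, got {cfg.n_hcu!r}")
    if not (isinstance(cfg.n_mcu, int) and 1 <= cfg.n_mcu <= 100):
        v.append(f"n_mcu must be an integer in [1, 100], got {cfg.n_mcu!r}")
    if not (isinstance(cfg.n_conn, int) and cfg.n_conn >= (cfg.n_mcu if isinstance(cfg.n_mcu, int) else 1)):
        v.append(f"n_conn must be an integer >= n_mcu, got {cfg.n_conn!r}")
    _pos("dt")
    if not (0 < cfg.r_max <= 1):
        v.append(f"r_max must lie in (0, 1], got {cfg.r_max!r}")
    for name in ("tau_zi", "tau_zj", "tau_e", "tau_p", "tau_m", "kappa"):
        _pos(name)
    # Pairwise distinctness along each chain: the closed form has poles at
    # tau_z == tau_e, tau_z == tau_p*, tau_e == tau_p* (and the same with
    # tau_zij for the synaptic chain).
    try:
        tp = cfg.tau_p_eff
        tau_zij = 1.0 / (1.0 / cfg.tau_zi + 1.0 / cfg.tau_zj)
        pairs = [
            ("tau_zi", cfg.tau_zi, "tau_e", cfg.tau_e),
            ("tau_zi", cfg.tau_zi, "tau_p*", tp),
            ("tau_zj", cfg.tau_zj, "tau_e", cfg.tau_e),
            ("tau_zj", cfg.tau_zj, "tau_p*", tp),
            ("tau_e", cfg.tau_e, "tau_p*", tp),
            ("tau_zij", tau_zij, "tau_e", cfg.tau_e),
            ("tau_zij", tau_zij, "tau_p*", tp),
        ]
        for na, xa, nb, xb in pairs:
            if xa == xb:
                v.append(
                    f"{na} == {nb} ({xa}): closed-form update constants are "
                    "singular (division by the difference of time constants)"
                )
    except (TypeError, ZeroDivisionError):
        pass
    if not (isinstance(cfg.buffer_len, int) and cfg.buffer_len >= 0):
        v.append(f"buffer_len must be an integer >= 0, got {cfg.buffer_len!r}")
    if not (isinstance(cfg.record_period, int) and cfg.record_period >= 1):
        v.append(f"record_period must be an integer >= 1, got {cfg.record_period!r}")
    if not (isinstance(cfg.record_slots, int) and cfg.record_slots >= 1):
        v.append(f"record_slots must be an integer >= 1, got {cfg.record_slots!r}")
    if not (isinstance(cfg.epsilon, float) and cfg.epsilon > 0 or isinstance(cfg.epsilon, int) and cfg.epsilon > 0):
        v.append(f"epsilon must be > 0, got {cfg.epsilon!r}")
    if cfg.strategy not in STRATEGIES:
        v.append(f"strategy must be one of {STRATEGIES}, got {cfg.strategy!r}")
    if cfg.approx not in APPROXIMATIONS:
        v.append(f"approx must be one of {APPROXIMATIONS}, got {cfg.approx!r}")
    if not (0 < cfg.weight_floor < 1):
        v.append(f"weight_floor must lie in (0, 1), got {cfg.weight_floor!r}")
    if not (isinstance(cfg.euler_substep, float) and cfg.euler_substep > 0):
        v.append(f"euler_substep must be > 0, got {cfg.euler_substep!r}")
    return v
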