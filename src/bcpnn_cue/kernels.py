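"""Closed-form and Euler updates of the BCPNN trace filter chains.

Every trace is a cascade of first-order low-pass filters driven by spike
trains: presynaptic ``s_i -> z_i -> e_i -> p_i``, post-synaptic
``s_j -> z_j -> e_j -> p_j``, and synaptic ``z_i * z_j -> e_ij -> p_ij``.
Between spikes the cascade is a linear ODE system whose solution is a
mixture of exponentials; the ``lazy_*`` functions apply that exact solution
over an arbitrary spike-free gap, which is what makes event-driven (lazy)
simulation possible.  ``euler_step`` is the first-order time-driven
alternative and, at a fine substep, the reference oracle.

Conventions (used consistently across the package):

* A gap update advances the state from ``t_last`` to ``t`` using the trace
  values *at* ``t_last``; a spike arriving at ``t`` is added to the z trace
  *after* the decay (the ``+ s(t)`` term of the closed form).
* When pre- and post-synaptic spikes coincide at a step, the post-synaptic
  spike is applied at the segment boundary before any presynaptic
  bookkeeping.

All functions broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DerivedConstants


# ---------------------------------------------------------------------------
# domain containers

@dataclass
class PresynTraces:
    """Presynaptic trace rows (the i-vector of one hypercolumn)."""

    z: np.ndarray
    e: np.ndarray
    p: np.ndarray
    t: np.ndarray  # step of last row evaluation

    @classmethod
    def zeros(cls, n: int) -> "PresynTraces":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n, dtype=np.int64))


@dataclass
class PostsynTraces:
    """Post-synaptic traces (the j-vector), advanced every step."""

    z: np.ndarray
    e: np.ndarray
    p: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "PostsynTraces":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))


@dataclass
class SynapseCell:
    """State of one (or an array of) synaptic matrix cell(s).

    The lazy and flushing strategies materialize all six per-cell
    variables (e_ij, p_ij, w_ij, z_i2, z_j2, t_ij); CUE eliminates the
    per-cell timestamp and the presynaptic z copy and keeps only four.
    """

    e: np.ndarray
    p: np.ndarray
    w: np.ndarray
    z_j2: np.ndarray
    z_i2: np.ndarray | None = None
    t: np.ndarray | None = None


# ---------------------------------------------------------------------------
# elementary updates

def euler_step(y, x, tau: float, dt_sub: float):
    """One forward-Euler step of ``tau dY/dt = X - Y``."""
    if tau <= 0 or dt_sub <= 0:
        raise ValueError("tau and dt_sub must be positive")
    return y + dt_sub * (np.asarray(x) - y) / tau


def presyn_decay(z, e, p, dt, k: DerivedConstants):
    """Exact spike-free advance of a ``s -> z -> e -> p`` chain by ``dt`` steps.

    Returns the new ``(z, e, p)``.  ``dt`` may be an array (broadcast).
    """
    Ez = np.exp(-np.asarray(dt, dtype=float) / k.tau_zi)
    Ee = np.exp(-np.asarray(dt, dtype=float) / k.tau_e)
    Ep = np.exp(-np.asarray(dt, dtype=float) / k.tau_p)
    p_new = p * Ep + k.a_i * k.b_i * (Ez - Ep) * z + (e - k.a_i * z) * k.c * (Ee - Ep)
    e_new = e * Ee + k.a_i * (Ez - Ee) * z
    z_new = z * Ez
    return z_new, e_new, p_new


def postsyn_decay(z, e, p, dt, k: DerivedConstants):
    """Exact spike-free advance of the post-synaptic chain (tau_zj kinetics)."""
    Ez = np.exp(-np.asarray(dt, dtype=float) / k.tau_zj)
    Ee = np.exp(-np.asarray(dt, dtype=float) / k.tau_e)
    Ep = np.exp(-np.asarray(dt, dtype=float) / k.tau_p)
    p_new = p * Ep + k.a_j * k.b_j * (Ez - Ep) * z + (e - k.a_j * z) * k.c * (Ee - Ep)
    e_new = e * Ee + k.a_j * (Ez - Ee) * z
    z_new = z * Ez
    return z_new, e_new, p_new


def syn_decay(e, p, zz, dt, k: DerivedConstants):
    """Exact spike-free advance of ``z_i*z_j -> e_ij -> p_ij`` by ``dt`` steps.

    ``zz`` is the product ``z_i(t_last) * z_j(t_last)``; the product itself
    decays with the harmonic time constant tau_zij.  Returns ``(e, p)``.
    """
    Ezij = np.exp(-np.asarray(dt, dtype=float) / k.tau_zij)
    Ee = np.exp(-np.asarray(dt, dtype=float) / k.tau_e)
    Ep = np.exp(-np.asarray(dt, dtype=float) / k.tau_p)
    p_new = p * Ep + k.a_ij * k.b_ij * (Ezij - Ep) * zz + (e - k.a_ij * zz) * k.c * (Ee - Ep)
    e_new = e * Ee + k.a_ij * (Ezij - Ee) * zz
    return e_new, p_new


# ---------------------------------------------------------------------------
# lazy (event-driven) updates on the domain containers

def lazy_presyn_update(tr: PresynTraces, now: int, spike, k: DerivedConstants, rows=slice(None)):
    """Advance the i-vector rows ``rows`` to step ``now``; add the spike last.

    ``spike`` is boolean (broadcast over the selected rows).  Decay uses the
    values stored at the rows' last evaluation; the triggering spike adds +1
    to z at the end.
    """
    dt = now - tr.t[rows]
    if np.any(dt < 0):
        raise ValueError("presynaptic row timestamp is ahead of the update step")
    z, e, p = presyn_decay(tr.z[rows], tr.e[rows], tr.p[rows], dt, k)
    tr.z[rows] = z + np.asarray(spike, dtype=float)
    tr.e[rows] = e
    tr.p[rows] = p
    tr.t[rows] = now
    return tr


def lazy_synapse_update(cell: SynapseCell, z_i_last, z_j_last, dt_gap, k: DerivedConstants):
    """Advance a synapse cell across a spike-free gap of ``dt_gap`` steps.

    ``z_i_last``/``z_j_last`` are the z values at the cell's last
    evaluation.  Only e_ij/p_ij are touched; z copies and timestamps are the
    caller's bookkeeping (they differ between strategies).
    """
    if np.any(np.asarray(dt_gap) < 0):
        raise ValueError("negative synaptic update gap")
    cell.e, cell.p = syn_decay(cell.e, cell.p, np.asarray(z_i_last) * np.asarray(z_j_last), dt_gap, k)
    return cell


def compute_weight(p_i, p_j, p_ij, floor_eps: float = 1e-8):
    """BCPNN log-odds weight ``w_ij = log(p_ij / (p_i p_j))`` with a floor.

    Each probability trace is floored at ``floor_eps`` before the logs, so
    the weight is finite (and minimal for the given p_i, p_j) even when the
    joint trace is zero.  Symmetric in p_i and p_j.
    """
    pi = np.maximum(p_i, floor_eps)
    pj = np.maximum(p_j, floor_eps)
    pij = np.maximum(p_ij, floor_eps)
    return np.log(pij / (pi * pj))


def compute_bias(p_j, floor_eps: float = 1e-8):
    """Intrinsic excitability term ``beta_j = log p_j`` (floored)."""
    return np.log(np.maximum(p_j, floor_eps))


# ---------------------------------------------------------------------------
# test utility

def semigroup_check(state, dt1: float, dt2: float, k: DerivedConstants,
                    kind: str = "syn", rtol: float = 1e-10) -> bool:
    """True iff advancing by ``dt1 + dt2`` equals advancing by ``dt1`` then
    ``dt2`` (no spikes in either gap), within ``rtol``.

    ``state`` is ``(z, e, p)`` for ``kind='presyn'`` or ``(e, p, z_i, z_j)``
    for ``kind='syn'``.  Holds exactly for the closed form (it is the ODE
    flow); fails for coarse Euler stepping.
    """
    if dt1 < 0 or dt2 < 0:
        raise ValueError("gaps must be nonnegative")
    if kind == "presyn":
        z, e, p = state
        one = presyn_decay(z, e, p, dt1 + dt2, k)
        two = presyn_decay(*presyn_decay(z, e, p, dt1, k), dt2, k)
        return all(np.allclose(a, b, rtol=rtol, atol=1e-300) for a, b in zip(one, two))
    elif kind == "syn":
        e, p, z_i, z_j = state
        one = syn_decay(e, p, z_i * z_j, dt1 + dt2, k)
        e1, p1 = syn_decay(e, p, z_i * z_j, dt1, k)
        zi1 = z_i * np.exp(-dt1 / k.tau_zi)
        zj1 = z_j * np.exp(-dt1 / k.tau_zj)
        two = syn_decay(e1, p1, zi1 * zj1, dt2, k)
        return all(np.allclose(a, b, rtol=rtol, atol=1e-300) for a, b in zip(one, two))
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# fine-step Euler reference integrators (oracles for the closed forms)

def euler_reference_presyn(z, e, p, gap_steps: float, k: DerivedConstants, dt_sub: float):
    """Integrate the spike-free presynaptic chain with fine Euler substeps."""
    n = int(round(gap_steps / dt_sub))
    z = np.asarray(z, dtype=float).copy()
    e = np.asarray(e, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    for _ in range(n):
        e_new = e + dt_sub * (z - e) / k.tau_e
        p_new = p + dt_sub * (e - p) / k.tau_p
        z = z - dt_sub * z / k.tau_zi
        e, p = e_new, p_new
    return z, e, p


def euler_reference_syn(e, p, z_i, z_j, gap_steps: float, k: DerivedConstants, dt_sub: float):
    """Integrate the spike-free synaptic chain with fine Euler substeps."""
    n = int(round(gap_steps / dt_sub))
    e = np.asarray(e, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    z_i = np.asarray(z_i, dtype=float).copy()
    z_j = np.asarray(z_j, dtype=float).copy()
    for _ in range(n):
        e_new = e + dt_sub * (z_i * z_j - e) / k.tau_e
        p_new = p + dt_sub * (e - p) / k.tau_p
        z_i = z_i - dt_sub * z_i / k.tau_zi
        z_j = z_j - dt_sub * z_j / k.tau_zj
        e, p = e_new, p_new
    return e, p
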