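"""Error-bound analysis of the CUE approximation.

The probability that a row update commits a relative weight error larger
than a tolerance eps factorizes as::

    P(err > eps | L, H) = P(t - t' > L) * P(err > eps | H)

where the first factor is the analytic probability that a presynaptic gap
outruns the look-back horizon of an L-step buffer, and the second — the
probability that the approximation function H then mispredicts badly — is
estimated by Monte-Carlo simulation of single synapses.

The firing-rate model is a three-point distribution: a minicolumn fires at
the losing rate r_l with probability alpha (M-1)/M, at the winning rate
r_w with probability alpha / M, and at the silent-hypercolumn rate
r_s = r_max / M with probability 1 - alpha, where alpha is the fraction of
active hypercolumns.  Spikes are assumed bursty: a regime persists for the
whole observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig, derive_constants
from .kernels import compute_weight, postsyn_decay, presyn_decay, syn_decay
from .rate_table import rate_constants

#: trials with |w_true| below this log-unit floor are tallied separately and
#: excluded from the error fraction: a relative error against a weight this
#: close to zero is an artifact of the near-zero denominator, not of the
#: spike prediction.
W_TRUE_FLOOR = 0.01

_GAP_CAP_FACTOR = 10   # gaps are capped at 10 L (contributions decay as (1-r)^G)
_BURN_IN_STEPS = 500   # pre-gap steps that develop trace fluctuations


@dataclass(frozen=True)
class RateModel:
    """Discrete firing-rate distribution of one minicolumn."""

    alpha: float
    n_mcu: int
    r_l: float
    r_w: float
    r_s: float

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.r_l, self.r_w, self.r_s])

    @property
    def probs(self) -> np.ndarray:
        a, M = self.alpha, self.n_mcu
        return np.array([a * (M - 1) / M, a / M, 1.0 - a])


@dataclass
class ErrorEstimate:
    """One grid point of the error bound."""

    alpha: float
    n_mcu: int
    buffer_len: int
    approx: str
    epsilon: float
    p_beyond: float
    p_cond: float
    ci_low: float
    ci_high: float
    n_trials: int
    n_excluded: int
    deltas: np.ndarray = field(repr=False, default=None)  # signed w_pred - w_true

    @property
    def p_overall(self) -> float:
        return self.p_beyond * self.p_cond


def rate_distribution(alpha: float, n_mcu: int, r_max: float = 0.1) -> RateModel:
    """The three-point rate distribution for activity level ``alpha``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rc = rate_constants(n_mcu, r_max)
    return RateModel(alpha, n_mcu, rc.r_l, rc.r_w, rc.r_s)


def rate_expectancy(dist: RateModel) -> float:
    """Mean per-step rate <r> = sum r P(r); equals r_s with the shipped table."""
    return float(np.dot(dist.rates, dist.probs))


def beyond_lbh_probability(L: int, dist: RateModel) -> float:
    """P(t - t' > L): a presynaptic spike whose predecessor is beyond the LBH.

    A connection in regime r produces a spike at the current step with
    probability r and none during the previous L steps with probability
    (1 - r)^L; summed over the rate distribution.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    r = dist.rates
    return float(np.sum(dist.probs * r * (1.0 - r) ** L))


def relative_weight_error(w_true, w_pred, s_i=1):
    """Relative weight error at an evaluation point (0 off evaluation)."""
    w_true = np.asarray(w_true, dtype=float)
    err = np.abs((w_true - np.asarray(w_pred, dtype=float)) / w_true)
    return np.where(np.asarray(s_i, dtype=bool), err, 0.0)


# ---------------------------------------------------------------------------
# Monte-Carlo conditional error

def conditional_error_probability(
    approx: str,
    alpha: float,
    n_mcu: int,
    n_trials: int = 100_000,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> ErrorEstimate:
    """Monte-Carlo estimate of P(err > eps | a beyond-LBH prediction was needed).

    Each trial simulates one synapse.  The presynaptic regime and the
    post-synaptic regime are drawn independently from the rate
    distribution; the presynaptic gap G is geometric at the presynaptic
    rate conditioned on G > L (and capped at 10 L).  The trial state is
    initialized at the regime's stationary trace means and burned in for
    500 steps of joint Bernoulli firing, then the gap is simulated twice
    with common random numbers: the ground-truth run sees the full
    post-synaptic history while the candidate run sees the exact history
    only inside the trailing L-step buffer window and the approximation's
    prediction before it.  The error is the relative weight difference at
    the evaluating presynaptic spike; trials whose true weight is within
    ``W_TRUE_FLOOR`` of zero are tallied separately and excluded.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if approx not in ("none", "static", "adaptive", "oracle"):
        raise ValueError(f"unknown approximation {approx!r}")
    cfg = cfg or SimulationConfig(n_mcu=n_mcu)
    k = derive_constants(cfg)
    dt, L, eps = cfg.dt, cfg.buffer_len, cfg.epsilon
    dist = rate_distribution(alpha, n_mcu, cfg.r_max)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xE7])))

    n = int(n_trials)
    regime_pre = rng.choice(3, size=n, p=dist.probs)
    regime_post = rng.choice(3, size=n, p=dist.probs)
    r_pre = dist.rates[regime_pre]
    r_post = dist.rates[regime_post]

    # gap > L, geometric in the presynaptic rate, capped
    u = rng.random(n)
    extra = np.ceil(np.log1p(-u) / np.log1p(-r_pre)).astype(np.int64)
    G = np.minimum(L + np.maximum(extra, 1), _GAP_CAP_FACTOR * L)
    g_max = int(G.max())

    # stationary-mean initialization of every trace
    zi = r_pre * k.tau_zi
    ei, pi = zi.copy(), zi.copy()
    zj = r_post * k.tau_zj
    ej, pj = zj.copy(), zj.copy()
    e = zi * zj
    p = e.copy()

    for _ in range(_BURN_IN_STEPS):
        s_pre = rng.random(n) < r_pre
        s_post = rng.random(n) < r_post
        e, p = syn_decay(e, p, zi * zj, dt, k)
        zi_new, ei, pi = presyn_decay(zi, ei, pi, dt, k)
        zj_new, ej, pj = postsyn_decay(zj, ej, pj, dt, k)
        zi = zi_new + s_pre
        zj = zj_new + s_post

    # gap: presynaptic silence; fork true/predicted post-synaptic copies
    e_t, p_t, zj_t = e.copy(), p.copy(), zj.copy()
    e_p, p_p, zj_p = e.copy(), p.copy(), zj.copy()
    out = {name: np.zeros(n) for name in ("pij_t", "pij_p", "pi", "pj")}
    for step in range(1, g_max + 1):
        s_true = rng.random(n) < r_post
        x = rng.random(n)
        if approx == "none":
            s_apx = np.zeros(n, dtype=bool)
        elif approx == "static":
            s_apx = x < dist.r_s
        elif approx == "adaptive":
            s_apx = x < r_post  # recorder resolves the true regime
        else:  # oracle
            s_apx = s_true
        beyond = step <= G - L
        s_pred = np.where(beyond, s_apx, s_true)

        e_t, p_t = syn_decay(e_t, p_t, zi * zj_t, dt, k)
        zj_t = zj_t * np.exp(-dt / k.tau_zj) + s_true
        e_p, p_p = syn_decay(e_p, p_p, zi * zj_p, dt, k)
        zj_p = zj_p * np.exp(-dt / k.tau_zj) + s_pred
        zi_new, ei, pi = presyn_decay(zi, ei, pi, dt, k)
        zi = zi_new
        zj_new, ej, pj = postsyn_decay(zj, ej, pj, dt, k)
        zj = zj_new + s_true

        done = G == step
        if np.any(done):
            out["pij_t"][done] = p_t[done]
            out["pij_p"][done] = p_p[done]
            out["pi"][done] = pi[done]
            out["pj"][done] = pj[done]

    w_true = compute_weight(out["pi"], out["pj"], out["pij_t"], cfg.weight_floor)
    w_pred = compute_weight(out["pi"], out["pj"], out["pij_p"], cfg.weight_floor)
    ok = np.abs(w_true) >= W_TRUE_FLOOR
    n_excluded = int(n - ok.sum())
    err = relative_weight_error(w_true[ok], w_pred[ok])
    n_ok = int(ok.sum())
    n_bad = int(np.sum(err > eps))
    p_cond = n_bad / n_ok if n_ok else 0.0
    ci = stats.binomtest(n_bad, n_ok).proportion_ci(0.99) if n_ok else (0.0, 1.0)
    return ErrorEstimate(
        alpha=alpha, n_mcu=n_mcu, buffer_len=L, approx=approx, epsilon=eps,
        p_beyond=beyond_lbh_probability(L, dist),
        p_cond=p_cond, ci_low=float(ci[0]), ci_high=float(ci[1]),
        n_trials=n_ok, n_excluded=n_excluded,
        deltas=(w_pred - w_true)[ok],
    )


def overall_bound(
    alpha_grid,
    n_mcu: int,
    l_grid,
    approx: str,
    n_trials: int = 100_000,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Overall error-probability table P(err > eps | L, H) over a grid.

    One Monte-Carlo conditional estimate per (alpha, L) point; the overall
    probability is the product with the analytic beyond-LBH factor.
    """
    base = cfg or SimulationConfig(n_mcu=n_mcu)
    rows = []
    for alpha in np.atleast_1d(alpha_grid):
        for L in np.atleast_1d(l_grid):
            c = base.replace(buffer_len=int(L))
            est = conditional_error_probability(
                approx, float(alpha), n_mcu, n_trials=n_trials,
                seed=seed + int(L), cfg=c)
            rows.append({
                "alpha": float(alpha), "M": n_mcu, "L": int(L), "approx": approx,
                "p_beyond": est.p_beyond, "p_cond": est.p_cond,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "p_overall": est.p_overall,
                "n_trials": est.n_trials, "n_excluded": est.n_excluded,
            })
    return pd.DataFrame(rows)
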