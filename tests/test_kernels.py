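import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcpnn_cue import SimulationConfig, compute_weight, derive_constants, euler_step
from bcpnn_cue.kernels import (
    PresynTraces,
    euler_reference_presyn,
    euler_reference_syn,
    lazy_presyn_update,
    presyn_decay,
    postsyn_decay,
    semigroup_check,
    syn_decay,
)

K = derive_constants(SimulationConfig())


def test_euler_step_fixed_point_and_substitution():
    assert euler_step(2.5, 2.5, tau=10, dt_sub=1) == pytest.approx(2.5)
    assert euler_step(1.0, 0.0, tau=10, dt_sub=1) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        euler_step(1.0, 0.0, tau=-1, dt_sub=1)


def test_euler_converges_to_exponential_decay():
    dt_sub = 1e-3
    y = 1.0
    for _ in range(int(10 / dt_sub)):  # integrate to t = tau
        y = euler_step(y, 0.0, tau=10, dt_sub=dt_sub)
    assert y == pytest.approx(np.exp(-1), rel=10 * dt_sub)


def test_lazy_presyn_zero_gap_adds_exactly_one_spike():
    tr = PresynTraces(np.array([1.2]), np.array([0.5]), np.array([0.3]),
                      np.array([7], dtype=np.int64))
    lazy_presyn_update(tr, 7, np.array([True]), K)
    assert tr.z[0] == pytest.approx(2.2)
    assert tr.e[0] == pytest.approx(0.5)   # e^0 terms: decay is identity
    assert tr.p[0] == pytest.approx(0.3)


def test_lazy_presyn_pure_decay_over_one_tau():
    z, e, p = presyn_decay(1.0, 0.0, 0.0, K.tau_zi, K)
    assert z == pytest.approx(np.exp(-1), abs=1e-12)
    assert e > 0 and p > 0  # downstream filters pick up the decaying z


def test_stale_timestamp_rejected():
    tr = PresynTraces.zeros(1)
    tr.t[0] = 10
    with pytest.raises(ValueError):
        lazy_presyn_update(tr, 5, np.array([False]), K)


@pytest.mark.parametrize("chain", ["presyn", "syn"])
def test_closed_form_matches_fine_euler_on_random_states(chain):
    """Exactness: the closed form agrees with a 1 us Euler integration to
    1e-4 relative over random states and gaps (>=100 cases)."""
    rng = np.random.default_rng(42)
    n = 100
    dt_sub = 1e-3
    for _ in range(4):  # vectorized over 25-state batches, 4 gap draws
        z = rng.uniform(0, 3, 25)
        e = rng.uniform(0, 1, 25)
        p = rng.uniform(0, 1, 25)
        gap = float(rng.integers(1, 80))
        if chain == "presyn":
            got = presyn_decay(z, e, p, gap, K)
            ref = euler_reference_presyn(z, e, p, gap, K, dt_sub)
        else:
            zj = rng.uniform(0, 3, 25)
            got = syn_decay(e, p, z * zj, gap, K)
            ref = euler_reference_syn(e, p, z, zj, gap, K, dt_sub)
        for g, r in zip(got[-2:], ref[-2:]):  # e and p components
            assert np.allclose(g, r, rtol=1e-4, atol=1e-9)


@given(
    z=st.floats(0, 5), e=st.floats(0, 2), p=st.floats(0, 2),
    zj=st.floats(0, 5),
    dt1=st.floats(0, 300), dt2=st.floats(0, 300),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_semigroup_property_on_spike_free_gaps(z, e, p, zj, dt1, dt2):
    """Advancing by dt1+dt2 equals advancing by dt1 then dt2: the closed
    form is the exact ODE flow."""
    assert semigroup_check((z, e, p), dt1, dt2, K, kind="presyn")
    assert semigroup_check((e, p, z, zj), dt1, dt2, K, kind="syn")


def test_euler_stepping_violates_semigroup_at_coarse_dt():
    z, e, p = 1.0, 0.5, 0.2
    one = euler_reference_presyn(z, e, p, 20, K, dt_sub=10.0)
    two = euler_reference_presyn(*euler_reference_presyn(z, e, p, 10, K, 10.0), 10, K, 10.0)
    # identical composition for linear Euler -- so compare against closed form
    exact = presyn_decay(z, e, p, 20, K)
    assert not np.allclose(one[2], exact[2], rtol=1e-10)
    assert np.allclose(one, two)  # Euler *is* compositional; it is just inexact


@given(z=st.floats(0, 5), e=st.floats(0, 2), p=st.floats(0, 2), dt=st.floats(0, 500))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_traces_remain_nonnegative(z, e, p, dt):
    for val in presyn_decay(z, e, p, dt, K):
        assert np.all(val >= -1e-15)
    for val in postsyn_decay(z, e, p, dt, K):
        assert np.all(val >= -1e-15)


def test_weight_log_odds_examples():
    assert compute_weight(0.2, 0.3, 0.06) == pytest.approx(0.0)          # independence
    assert compute_weight(0.2, 0.3, 0.12) == pytest.approx(np.log(2))    # 2x co-activation
    w_floor = compute_weight(0.2, 0.3, 0.0, 1e-8)
    assert np.isfinite(w_floor)
    assert w_floor == pytest.approx(np.log(1e-8 / 0.06))                 # minimal weight
    # symmetry in the marginals
    assert compute_weight(0.11, 0.47, 0.02) == pytest.approx(compute_weight(0.47, 0.11, 0.02))
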