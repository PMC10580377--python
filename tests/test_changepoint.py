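"""Changepoint core: IMD computation, exponential cost, and the four
search algorithms, cross-checked against brute-force optimal partitioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kataseg.changepoint import (
    ChangepointParams,
    amoc,
    bic_penalty,
    binseg,
    brute_force_partition,
    compute_imd,
    exp_segment_cost,
    pelt,
    segneigh,
    _pelt_quadratic,
    _prefix_sums,
)


# ---------------------------------------------------------------- compute_imd
@pytest.mark.parametrize(
    "positions, length, imds, pseudo",
    [
        ([100, 150, 1150], 2000, [100, 50, 1000], 850),
        ([500], 1000, [500], 500),
        ([1000], 1000, [1000], 0),
    ],
)
def test_compute_imd_examples(positions, length, imds, pseudo):
    seq = compute_imd(positions, length)
    assert list(seq.imds) == imds
    assert seq.pseudo_imd == pseudo
    assert seq.pseudo_imd + seq.imds.sum() == length  # conservation, exactly


def test_zero_pseudo_imd_replaced_in_observations():
    seq = compute_imd([1000], 1000)
    assert seq.pseudo_imd == 0
    assert seq.observations()[-1] == 1  # keeps the exponential cost defined


def test_compute_imd_rejects_bad_input():
    with pytest.raises(ValueError):
        compute_imd([], 100)
    with pytest.raises(ValueError):
        compute_imd([10, 5], 100)
    with pytest.raises(ValueError):
        compute_imd([10, 200], 100)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=50, unique=True),
    st.integers(min_value=0, max_value=10**6),
)
def test_imd_conservation_property(raw_positions, slack):
    positions = sorted(raw_positions)
    length = positions[-1] + slack
    seq = compute_imd(positions, length)
    assert seq.pseudo_imd + seq.imds.sum() == length
    assert (seq.imds >= 1).all()


# ------------------------------------------------------------- cost & penalty
def test_exp_segment_cost_examples():
    cs = _prefix_sums(np.array([1.0, 1.0]))
    assert exp_segment_cost(cs, 1, 2) == pytest.approx(0.0)
    cs = _prefix_sums(np.array([100.0] * 4))
    assert exp_segment_cost(cs, 1, 4) == pytest.approx(8 * math.log(100))


def test_split_at_rate_change_never_increases_cost():
    obs = np.array([500.0] * 6 + [5.0] * 6)
    cs = _prefix_sums(obs)
    whole = exp_segment_cost(cs, 1, 12)
    assert exp_segment_cost(cs, 1, 6) + exp_segment_cost(cs, 7, 12) <= whole


def test_bic_penalty():
    assert bic_penalty(20) == pytest.approx(5.9915, abs=1e-4)
    assert bic_penalty(7) == 2 * math.log(7)  # one rate + one location per segment
    assert bic_penalty(100) > bic_penalty(50)
    with pytest.raises(ValueError):
        bic_penalty(1)


# ------------------------------------------------------------------ searches
def test_pelt_constant_sequence_has_no_changepoints():
    res = pelt(np.full(20, 10.0))
    assert res.changepoints == (20,)


def test_pelt_two_rate_fixture(two_rate_observations):
    res = pelt(two_rate_observations)
    assert res.changepoints == (10, 20)
    oracle = brute_force_partition(two_rate_observations)
    assert res.changepoints == oracle.changepoints
    assert res.total_objective == oracle.total_objective
    # penalized split beats the unsplit fit
    cs = _prefix_sums(two_rate_observations)
    unsplit = exp_segment_cost(cs, 1, 20) + bic_penalty(20)
    assert res.total_objective < unsplit


def _random_instance(rng):
    nseg = rng.integers(1, 4)
    parts = [
        rng.exponential(rng.uniform(1, 2000), rng.integers(2, 12))
        for _ in range(nseg)
    ]
    obs = np.maximum(np.concatenate(parts), 1e-3)[:30]
    beta = float(rng.uniform(0.5, 25))
    return obs, ChangepointParams(penalty_value=beta)


def test_pelt_matches_brute_force_on_random_instances():
    """PELT equals unpruned optimal partitioning: identical changepoint sets
    and objectives on 200 random exponential sequences (n <= 30)."""
    rng = np.random.default_rng(1234)
    for _ in range(200):
        obs, params = _random_instance(rng)
        fast = pelt(obs, params)
        oracle = brute_force_partition(obs, params)
        assert fast.changepoints == oracle.changepoints
        assert fast.total_objective == oracle.total_objective


def test_pelt_matches_quadratic_pelt_at_scale():
    """The envelope-pruned solver agrees with classic inequality-pruned PELT
    on mid-size sequences with genuine structure."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        obs = np.concatenate(
            [
                rng.exponential(2000, 400),
                rng.exponential(50, 30),
                rng.exponential(2000, 400),
            ]
        )
        a = pelt(obs)
        b = _pelt_quadratic(obs)
        assert a.changepoints == b.changepoints
        assert a.total_objective == b.total_objective


def test_segneigh_agrees_with_pelt():
    rng = np.random.default_rng(99)
    for _ in range(25):
        obs, params = _random_instance(rng)
        assert segneigh(obs, params).total_objective == pytest.approx(
            pelt(obs, params).total_objective, rel=1e-12
        )


def test_segneigh_budget_of_one_forces_single_segment(two_rate_observations):
    res = segneigh(two_rate_observations, ChangepointParams(max_segments=1))
    assert res.changepoints == (20,)


def test_binseg_two_rate_matches_pelt(two_rate_observations):
    assert binseg(two_rate_observations).changepoints == pelt(
        two_rate_observations
    ).changepoints
    assert binseg(np.full(20, 7.0)).changepoints == (20,)


def test_binseg_objective_never_beats_pelt():
    rng = np.random.default_rng(5)
    for _ in range(50):
        obs, params = _random_instance(rng)
        assert binseg(obs, params).total_objective >= pelt(obs, params).total_objective - 1e-9


def test_amoc_finds_single_changepoint(two_rate_observations):
    assert amoc(two_rate_observations).changepoints == (10, 20)
    assert amoc(np.full(20, 3.0)).changepoints == (20,)
    three = np.concatenate([np.full(8, 1000.0), np.full(8, 10.0), np.full(8, 1000.0)])
    assert len(amoc(three).changepoints) <= 2  # at most one internal changepoint


def test_all_searches_respect_min_seg_len():
    rng = np.random.default_rng(11)
    for _ in range(30):
        obs, params = _random_instance(rng)
        for algo in (pelt, binseg, segneigh, amoc, brute_force_partition):
            cps = algo(obs, params).changepoints
            bounds = (0,) + cps
            gaps = np.diff(bounds)
            assert (gaps >= params.min_seg_len).all()
            assert cps[-1] == len(obs)


def test_objective_nondecreasing_in_penalty():
    rng = np.random.default_rng(21)
    obs = np.concatenate([rng.exponential(500, 15), rng.exponential(5, 15)])
    objs, nsegs = [], []
    for beta in (0.5, 2.0, 8.0, 32.0):
        res = pelt(obs, ChangepointParams(penalty_value=beta))
        objs.append(res.total_objective)
        nsegs.append(res.n_segments)
    assert objs == sorted(objs)
    assert nsegs == sorted(nsegs, reverse=True)


def test_short_sequences_form_single_segment():
    res = pelt(np.array([5.0, 7.0, 9.0]), ChangepointParams(min_seg_len=2))
    assert res.changepoints == (3,)


def test_nonpositive_observations_rejected():
    with pytest.raises(ValueError):
        pelt(np.array([1.0, -2.0, 3.0, 4.0]))
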