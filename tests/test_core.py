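"""Scalar ES mathematics against independent brute-force oracles.

The oracle computes conditional entropy H(QF | RF) by direct 2x2
contingency counting on explicit binary vectors — it never touches the
parabola closed form it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entropysort import binary_entropy, ese_ce, pair_geometry, pair_scores
from entropysort.core import (
    choose_orientation,
    divergence,
    divergent_cells,
    dpc_dependent,
    dpc_independent,
    error_potential,
    ess,
    sort_direction,
    sort_gain,
    sort_weight,
    _geometry_from_counts,
)


def contingency_conditional_entropy(rf_min: np.ndarray, qf_min: np.ndarray) -> float:
    """H(QF | RF) in bits by direct counting over the 2x2 table."""
    n = rf_min.size
    h = 0.0
    for r in (True, False):
        sel = rf_min == r
        n_r = sel.sum()
        if n_r == 0:
            continue
        p_r = n_r / n
        for q in (True, False):
            n_rq = (sel & (qf_min == q)).sum()
            if n_rq:
                p = n_rq / n_r
                h -= p_r * p * np.log2(p)
    return h


def make_pair(rng, n):
    """Random binary pair with non-constant features, in minority encoding."""
    while True:
        g1 = rng.integers(1, n // 2 + 1)
        qfm = rng.integers(1, n // 2 + 1)
        rf = np.zeros(n, dtype=np.int8)
        rf[rng.choice(n, size=g1, replace=False)] = 1
        qf = np.zeros(n, dtype=np.int8)
        qf[rng.choice(n, size=qfm, replace=False)] = 1
        if 0 < rf.sum() < n and 0 < qf.sum() < n:
            return rf, qf


def test_ese_matches_contingency_oracle():
    """1,000 seeded random pairs: parabola CE(observed x) equals direct
    contingency-table conditional entropy to 1e-9."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(10, 201))
        rf, qf = make_pair(rng, n)
        g = pair_geometry(rf, qf)
        rf_min = rf.astype(bool) if g.G1 == rf.sum() else ~rf.astype(bool)
        qf_min = qf.astype(bool) if g.QFm == qf.sum() else ~qf.astype(bool)
        oracle = contingency_conditional_entropy(rf_min, qf_min)
        assert abs(g.ObsEnt - oracle) < 1e-9


def test_independence_identity_and_extrema():
    """CE(x_max) = H2(QFm/N); the maximum dominates a dense grid and the
    boundaries are the two minima."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(10, 151))
        rf, qf = make_pair(rng, n)
        g = pair_geometry(rf, qf)
        assert abs(g.MaxEnt - binary_entropy(g.QFm / g.N)) < 1e-9
        grid = np.linspace(g.x_lo, g.x_hi, 41)
        ces = [ese_ce(g, x) for x in grid]
        assert max(ces) <= g.MaxEnt + 1e-9
        assert min(ces) >= g.MinEnt_global - 1e-9
        assert g.MinEnt_global <= g.MinEnt_local + 1e-9
        assert {g.x_local_min, g.x_global_min} == {g.x_lo, g.x_hi}


def test_ce_worked_examples():
    g = _geometry_from_counts(N=30, G1=10, QFm=10, x=10)
    assert ese_ce(g, 10) == pytest.approx(0.0, abs=1e-12)

    g = _geometry_from_counts(N=30, G1=10, QFm=9, x=9)
    assert g.x_max == pytest.approx(3.0)
    assert ese_ce(g, 3.0) == pytest.approx(binary_entropy(9 / 30), abs=1e-12)
    # direct counting oracle for the observed arrangement
    rf = np.array([1] * 10 + [0] * 20)
    qf = np.array([1] * 9 + [0] * 21)
    oracle = contingency_conditional_entropy(rf.astype(bool), qf.astype(bool))
    assert ese_ce(g, 9) == pytest.approx(oracle, abs=1e-12)


def test_ce_domain_error():
    g = _geometry_from_counts(N=30, G1=10, QFm=9, x=5)
    with pytest.raises(ValueError, match="outside feasible"):
        ese_ce(g, 9.5)


def test_identical_and_complement_pairs():
    rng = np.random.default_rng(2)
    rf = np.zeros(30, dtype=np.int8)
    rf[rng.choice(30, size=10, replace=False)] = 1
    g = pair_geometry(rf, rf)
    assert g.x == g.x_hi == 10
    assert g.ObsEnt == pytest.approx(g.MinEnt_global, abs=1e-12)
    assert g.ObsEnt == pytest.approx(0.0, abs=1e-12)
    assert ess(g) == pytest.approx(1.0)

    comp = 1 - rf
    g2 = pair_geometry(rf, comp)
    # complement has minority count 10 as well (minority = active? no: 20
    # active of 30 -> minority is inactive); overlap of the two minority
    # encodings is the anti-sorted boundary
    assert g2.x in (g2.x_lo, g2.x_hi)
    assert g2.ObsEnt == pytest.approx(
        min(g2.MinEnt_local, g2.MinEnt_global), abs=1e-12
    )


def test_random_permutation_pair_near_independence():
    rng = np.random.default_rng(3)
    base = np.zeros(1000, dtype=np.int8)
    base[:300] = 1
    esses = []
    for _ in range(50):
        a = rng.permutation(base)
        b = rng.permutation(base)
        g = pair_geometry(a, b)
        assert abs(g.x - g.x_max) < 0.25 * g.G1
        esses.append(abs(ess(g)))
    assert np.mean(esses) < 0.05


def test_sort_direction_cases():
    g = _geometry_from_counts(N=30, G1=10, QFm=9, x=5)
    assert sort_direction(g) == 1        # x_max = 3
    g = _geometry_from_counts(N=30, G1=10, QFm=9, x=2)
    assert sort_direction(g) == -1
    g = _geometry_from_counts(N=30, G1=10, QFm=9, x=3)
    assert sort_direction(g) == 0
    s = error_potential(g)
    assert (s.SW, s.SG, s.ESS, s.EP) == (0.0, 0.0, 0.0, 0.0)


def test_sort_weight_example():
    g = _geometry_from_counts(N=30, G1=10, QFm=10, x=1)
    # SD=-1 geometry: local minimum is the x_lo boundary
    assert sort_direction(g) == -1
    expected = (g.MaxEnt - ese_ce(g, g.x_lo)) / g.MaxEnt
    assert sort_weight(g, -1) == pytest.approx(expected)
    assert sort_weight(g, -1) == pytest.approx(0.2740, abs=5e-4)
    assert sort_weight(g, 1) == pytest.approx(1.0)  # MinEnt_global = 0


def test_sort_gain_linearity():
    g = _geometry_from_counts(N=30, G1=10, QFm=10, x=8)
    sd = sort_direction(g)
    sg = sort_gain(g, sd)
    assert 0 <= sg <= 1
    # ObsEnt at the relevant minimum -> SG = 1; at MaxEnt -> 0
    g_hi = _geometry_from_counts(N=30, G1=10, QFm=10, x=10)
    assert sort_gain(g_hi, 1) == pytest.approx(1.0)


def test_divergence_fig_style_example():
    """N=100, G1=20, QFm=20, one erroneous cell: divergence equals the CE
    of the observed arrangement (global minimum is 0) and EP is positive."""
    g = _geometry_from_counts(N=100, G1=20, QFm=20, x=19)
    assert sort_direction(g) == 1
    assert g.MinEnt_global == pytest.approx(0.0, abs=1e-12)
    div = divergence(g, 1)
    assert div == pytest.approx(ese_ce(g, 19), abs=1e-12)
    assert div == pytest.approx(0.1348, abs=5e-4)
    # DPC under independence: MaxEnt over the run from max to global min
    dpc_ind = dpc_independent(g, 1)
    assert dpc_ind == pytest.approx(binary_entropy(0.2) / 16, abs=1e-9)
    assert dpc_ind == pytest.approx(0.0451, abs=5e-4)
    scores = error_potential(g)
    assert scores.n_divergent == 1
    assert scores.EP == pytest.approx(div - dpc_ind, abs=1e-12)
    assert scores.EP > 0


def test_divergent_cells_rules():
    rf = np.array([1] * 20 + [0] * 80)
    qf = np.concatenate([np.ones(19), np.zeros(80), np.ones(1)]).astype(np.int8)
    cells = divergent_cells(rf, qf, sd=1)
    assert cells.tolist() == [19]          # RF minority, QF majority
    assert divergent_cells(rf, rf, sd=1).size == 0
    anti = np.array([0] * 20 + [1] * 10 + [0] * 70)
    g = pair_geometry(rf, anti)
    assert divergent_cells(rf, anti, sort_direction(g)).size == 0


def test_dpc_dependent_conventions():
    g = _geometry_from_counts(N=100, G1=20, QFm=20, x=19)
    assert dpc_dependent(g, 1, 1) == pytest.approx(divergence(g, 1))
    assert dpc_dependent(g, 1, 0) == 0.0
    assert dpc_dependent(g, 1, 2) == pytest.approx(divergence(g, 1) / 2)


def test_dpc_independent_scaling():
    """Scaling all counts by k leaves MaxEnt fixed and scales the run by k,
    so DPC_independent scales by 1/k."""
    g1 = _geometry_from_counts(N=100, G1=20, QFm=20, x=19)
    g4 = _geometry_from_counts(N=400, G1=80, QFm=80, x=76)
    assert dpc_independent(g4, 1) == pytest.approx(dpc_independent(g1, 1) / 4)


def test_symmetric_geometry_equal_dpc():
    g = _geometry_from_counts(N=40, G1=20, QFm=20, x=15)
    assert dpc_independent(g, 1) == pytest.approx(abs(dpc_independent(g, -1)))


def test_mean_ep_negative_for_independent_pairs():
    rng = np.random.default_rng(5)
    base = np.zeros(1000, dtype=np.int8)
    base[:250] = 1
    eps = []
    for _ in range(120):
        s = pair_scores(rng.permutation(base), rng.permutation(base))
        eps.append(s.EP)
    assert np.mean(eps) < 0


def test_ep_negative_at_exact_independence_point():
    # x exactly on x_max carries no sorting evidence: all scores zero
    g = _geometry_from_counts(N=100, G1=20, QFm=25, x=5)
    assert sort_direction(g) == 0
    s = error_potential(g)
    assert s.EP == 0.0 and s.ESS == 0.0


def test_choose_orientation():
    rng = np.random.default_rng(6)
    a = np.zeros(60, dtype=np.int8)
    a[rng.choice(60, 12, replace=False)] = 1
    ab, ba = choose_orientation(a, a.copy())
    assert ab.ESS == pytest.approx(1.0)
    assert ba.ESS == pytest.approx(1.0)
    b = np.zeros(60, dtype=np.int8)
    b[rng.choice(60, 25, replace=False)] = 1
    ab, ba = choose_orientation(a, b)
    assert isinstance(ab.ESS, float) and isinstance(ba.ESS, float)


def test_constant_feature_rejected():
    with pytest.raises(ValueError, match="constant"):
        pair_geometry(np.zeros(10, dtype=np.int8), np.ones(10, dtype=np.int8))


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.data())
def test_score_bounds_property(data):
    """For any non-constant pair: ESS in [-1,1], SW/SG in [0,1],
    divergence >= 0, and n_divergent consistent with the geometry."""
    n = data.draw(st.integers(6, 60))
    g1 = data.draw(st.integers(1, n - 1))
    qfm = data.draw(st.integers(1, n - 1))
    seed = data.draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    rf = np.zeros(n, dtype=np.int8)
    rf[rng.choice(n, g1, replace=False)] = 1
    qf = np.zeros(n, dtype=np.int8)
    qf[rng.choice(n, qfm, replace=False)] = 1
    s = pair_scores(rf, qf)
    assert -1 - 1e-9 <= s.ESS <= 1 + 1e-9
    assert -1e-9 <= s.SW <= 1 + 1e-9
    assert -1e-9 <= s.SG <= 1 + 1e-9
    assert s.divergence >= -1e-12
    assert s.n_divergent >= 0
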