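"""Per-position amino-acid distributions, TVD, GOF binning, pair nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedab.aa_profiles import (
    AADistribution,
    joint_pair_distribution,
    pair_tvd,
    position_aa_distribution,
    position_gof_test,
    random_pairing_reference,
    total_variation_distance,
    tvd,
)
from pairedab.errors import EmptyResultError, TestNotApplicableError

from conftest import make_dataset, make_record


def _dist(counts, position="40", chain_type="H"):
    return AADistribution(position=position, chain_type=chain_type,
                          counts=counts, n=sum(counts.values()))


def test_position_distribution_enumeration():
    ds = make_dataset([
        make_record(cell="c1", h_positions={"40": "A"}),
        make_record(cell="c2", h_positions={"40": "A"}),
        make_record(cell="c3", h_positions={"40": "G"}),
    ])
    d = position_aa_distribution(ds, "H", "40")
    assert d.n == 3
    assert d.proportions == {"A": pytest.approx(2 / 3), "G": pytest.approx(1 / 3)}


def test_gapped_records_excluded_from_n():
    ds = make_dataset([
        make_record(cell="c1", h_positions={"40": "A"}),
        make_record(cell="c2", h_positions={}),  # shorter loop: position absent
    ])
    assert position_aa_distribution(ds, "H", "40").n == 1


def test_all_gap_position_is_an_empty_signal():
    ds = make_dataset([make_record(cell="c1", h_positions={"40": "A"})])
    with pytest.raises(EmptyResultError):
        position_aa_distribution(ds, "H", "41")


# ---------------------------------------------------------------------------
# TVD
# ---------------------------------------------------------------------------

def test_tvd_identical_is_zero():
    d = _dist({"A": 5, "G": 5})
    assert total_variation_distance(d, d) == pytest.approx(0.0)


def test_tvd_disjoint_support_is_one():
    assert total_variation_distance(_dist({"A": 10}), _dist({"W": 7})) == pytest.approx(1.0)


def test_tvd_hand_example():
    # {A:.5, G:.5} vs {A:.3, G:.7} -> 0.5*(0.2+0.2) = 0.2
    d1 = _dist({"A": 50, "G": 50})
    d2 = _dist({"A": 30, "G": 70})
    assert total_variation_distance(d1, d2) == pytest.approx(0.2)


@st.composite
def _random_distribution(draw):
    k = draw(st.integers(2, 8))
    weights = draw(st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k))
    total = sum(weights)
    symbols = "ACDEFGHIKLMNPQRSTVWY"[:k]
    return {s: w / total for s, w in zip(symbols, weights)}


@settings(deadline=None, derandomize=True, max_examples=300)
@given(p1=_random_distribution(), p2=_random_distribution(), p3=_random_distribution())
def test_tvd_metric_properties(p1, p2, p3):
    """Bounds, symmetry, triangle inequality, identity of indiscernibles."""
    d12, d21 = tvd(p1, p2), tvd(p2, p1)
    assert 0.0 <= d12 <= 1.0
    assert d12 == pytest.approx(d21)
    assert tvd(p1, p3) <= d12 + tvd(p2, p3) + 1e-12
    assert tvd(p1, p1) == pytest.approx(0.0)
    if d12 < 1e-12:
        shared = set(p1) | set(p2)
        assert all(abs(p1.get(s, 0) - p2.get(s, 0)) < 1e-9 for s in shared)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def test_gof_exactly_proportional_counts_give_zero():
    ref = _dist({"A": 50, "G": 50})
    cmp_ = _dist({"A": 200, "G": 200})
    stat, df, p = position_gof_test(ref, cmp_)
    assert stat == pytest.approx(0.0)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_gof_hand_value():
    # reference {A:.5, G:.5}, compared {A:80, G:20}:
    # (80-50)^2/50 + (20-50)^2/50 = 18 + 18 = 36
    stat, df, p = position_gof_test(_dist({"A": 1, "G": 1}), _dist({"A": 80, "G": 20}))
    assert stat == pytest.approx(36.0)
    assert df == 1


def test_small_counts_binned_to_other():
    # {A:100, C:3, W:2} with min_bin 5 -> bins {A:100, other:5}
    ref = _dist({"A": 90, "C": 5, "W": 5})
    cmp_ = _dist({"A": 100, "C": 3, "W": 2})
    stat, df, p = position_gof_test(ref, cmp_, min_bin=5)
    assert df == 1  # two bins: A and other
    # totals conserved: statistic computed on A=100 vs 94.5, other=5 vs 10.5
    expected_a = 0.9 * 105
    hand = (100 - expected_a) ** 2 / expected_a + (5 - (105 - expected_a)) ** 2 / (105 - expected_a)
    assert stat == pytest.approx(hand)


def test_binning_conserves_totals_via_reference_only_symbols():
    ref = _dist({"A": 50, "G": 40, "W": 10})
    cmp_ = _dist({"A": 120, "G": 80})  # W unobserved -> pooled expected mass
    stat, df, p = position_gof_test(ref, cmp_, min_bin=5)
    assert df == 2  # A, G, other (pooled expected W mass with observed 0)
    assert np.isfinite(stat)


def test_fewer_than_two_bins_not_applicable():
    with pytest.raises(TestNotApplicableError):
        position_gof_test(_dist({"A": 10}), _dist({"A": 30}))


# ---------------------------------------------------------------------------
# joint pair distributions and random-pairing nulls
# ---------------------------------------------------------------------------

def _coupled_dataset():
    recs = []
    for i, (h, l) in enumerate([("A", "D"), ("A", "D"), ("V", "E"), ("V", "E")]):
        recs.append(make_record(cell=f"c{i}", h_positions={"105": h},
                                l_positions={"105": l}))
    return make_dataset(recs)


def test_joint_distribution_enumeration():
    joint = joint_pair_distribution(_coupled_dataset(), "105", "105")
    assert joint.n == 4
    assert joint.joint == {("A", "D"): pytest.approx(0.5), ("V", "E"): pytest.approx(0.5)}


def test_single_record_joint_is_a_point_mass():
    ds = make_dataset([make_record(h_positions={"105": "A"}, l_positions={"105": "D"})])
    joint = joint_pair_distribution(ds, "105", "105")
    assert joint.joint == {("A", "D"): pytest.approx(1.0)}


def test_record_missing_light_position_excluded():
    ds = make_dataset([
        make_record(cell="c1", h_positions={"105": "A"}, l_positions={"105": "D"}),
        make_record(cell="c2", h_positions={"105": "V"}, l_positions={}),
    ])
    assert joint_pair_distribution(ds, "105", "105").n == 1


def test_analytic_reference_with_degenerate_marginal():
    ds = make_dataset([
        make_record(cell="c1", h_positions={"105": "A"}, l_positions={"105": "G"}),
        make_record(cell="c2", h_positions={"105": "V"}, l_positions={"105": "G"}),
    ])
    ref = random_pairing_reference(ds, "105", "105", mode="analytic")
    assert ref.joint == {("A", "G"): pytest.approx(0.5), ("V", "G"): pytest.approx(0.5)}


def test_analytic_reference_is_product_of_marginals():
    ds = _coupled_dataset()
    ref = random_pairing_reference(ds, "105", "105", mode="analytic")
    for (h, l), p in ref.joint.items():
        assert p == pytest.approx(0.5 * 0.5)


def test_permutation_reference_is_seed_deterministic():
    ds = _coupled_dataset()
    r1 = random_pairing_reference(ds, "105", "105", mode="permutation", seed=11)
    r2 = random_pairing_reference(ds, "105", "105", mode="permutation", seed=11)
    assert r1.joint == r2.joint


def test_pair_tvd_perfect_coupling_hand_value():
    # observed {AD:.5, VE:.5} vs product {each .25} -> 0.5
    ds = _coupled_dataset()
    obs = joint_pair_distribution(ds, "105", "105")
    ref = random_pairing_reference(ds, "105", "105", mode="analytic")
    assert pair_tvd(obs, ref) == pytest.approx(0.5)


def test_pair_tvd_identical_is_zero():
    obs = joint_pair_distribution(_coupled_dataset(), "105", "105")
    assert pair_tvd(obs, obs) == pytest.approx(0.0)


def test_independent_coupling_tvd_shrinks_with_n():
    """Under independence the observed-vs-product TVD decays toward 0."""
    from test_synthetic_data import kappa_only_config
    from pairedab.synthetic_data import simulate_paired_repertoire

    profiles = {("H", "105"): {"A": 0.5, "V": 0.5}, ("L", "105"): {"D": 0.5, "E": 0.5}}
    tvds = []
    for n in (200, 20_000):
        cfg = kappa_only_config(n_cells=n, seed=77, position_profiles=profiles)
        ds = simulate_paired_repertoire(cfg)
        obs = joint_pair_distribution(ds, "105", "105")
        ref = random_pairing_reference(ds, "105", "105", mode="analytic")
        tvds.append(pair_tvd(obs, ref))
    assert tvds[1] < tvds[0]
    assert tvds[1] < 0.02


def test_coupling_recovery_matches_configured_tvd():
    """pair_tvd on generated data reproduces the configured joint-vs-product TVD."""
    from test_synthetic_data import kappa_only_config
    from pairedab.synthetic_data import simulate_paired_repertoire

    joint = {("A", "D"): 0.4, ("A", "E"): 0.1, ("V", "D"): 0.1, ("V", "E"): 0.4}
    # configured marginals: H A/V = .5/.5, L D/E = .5/.5; product = .25 each
    target = 0.5 * sum(abs(p - 0.25) for p in joint.values())  # = 0.3
    n = 50_000
    cfg = kappa_only_config(n_cells=n, seed=88, position_profiles={},
                            coupling=[("105", "105", joint)])
    ds = simulate_paired_repertoire(cfg)
    obs = joint_pair_distribution(ds, "105", "105")
    ref = random_pairing_reference(ds, "105", "105", mode="analytic")
    se = np.sqrt(0.25 * 0.75 / n)  # Monte-Carlo scale of one joint cell
    assert pair_tvd(obs, ref) == pytest.approx(target, abs=3 * 4 * se)
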