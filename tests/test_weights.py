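"""Weight system: count/cost fractions, duration and controllability flags,
cumulative weight, boundary conditions, and the Monte Carlo treatment of
uncertain cost weights."""
import itertools
from fractions import Fraction as F

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bulksense import (
    F_S,
    WeightConfig,
    boundary_conditions,
    delta,
    f_delta,
    f_lambda,
    f_t,
    lambda_,
    monte_carlo_weights,
    w_tot,
    w_tot_min,
)
from conftest import vset

SIX_VARS = ("BOD", "TN", "TP", "MLSS", "DO", "T")


# ---------------------------------------------------------------- components
@pytest.mark.parametrize(
    "names, expected",
    [((), F(0)), (("BOD", "TN", "TP"), F(1)), (("TN",), F(1, 3)), (("MLSS", "DO"), F(0))],
)
def test_delta_counts_quality_indicators(cfg, names, expected):
    assert delta(vset(*names), cfg) == expected


@pytest.mark.parametrize(
    "names, expected",
    [((), F(0)), (("MLSS", "DO", "T"), F(1)), (("DO", "T"), F(2, 3)), (("BOD",), F(0))],
)
def test_lambda_counts_operating_parameters(cfg, names, expected):
    assert lambda_(vset(*names), cfg) == expected


def test_worked_cost_examples(cfg):
    """The two hand-computed cost fractions: f(delta)({BOD,TP}) = 3/6 and
    f(lambda)({MLSS,T}) = 4/6."""
    assert f_delta(vset("BOD", "TP"), cfg) == F(3, 6)
    assert f_lambda(vset("MLSS", "T"), cfg) == F(4, 6)


@pytest.mark.parametrize(
    "fn, names, expected",
    [
        (f_delta, (), F(0)),
        (f_delta, ("TN",), F(3, 6)),
        (f_lambda, (), F(0)),
        (f_lambda, ("DO",), F(2, 6)),
    ],
)
def test_cost_fraction_examples(cfg, fn, names, expected):
    assert fn(vset(*names), cfg) == expected


def test_unpriced_quality_indicator_is_rejected_by_name(cfg):
    with pytest.raises(KeyError, match="COD"):
        f_delta(vset("COD"), cfg)


def test_too_many_quality_indicators_is_a_configuration_error():
    cfg = WeightConfig(quality_max_count=2)
    with pytest.raises(ValueError, match="quality"):
        delta(vset("BOD", "TN", "TP"), cfg)


def test_duration_flag_rules(cfg):
    assert f_t(vset("BOD"), cfg) == 1  # BOD determination exceeds 24 h
    assert f_t(vset("TN", "TP"), cfg) == 0
    assert f_t(vset("BOD"), cfg.with_modelled("BOD")) == 0  # surrogate available


def test_controllability_flag(cfg):
    assert F_S(vset("MLSS", "T"), cfg) == 0
    assert F_S(vset("Q", "TN"), cfg) == 1  # influent side cannot steer SVI
    assert F_S(vset(), cfg) == 1


def test_ratio_terms_contribute_both_constituents(cfg):
    v = vset("BOD/TN")
    assert delta(v, cfg) == F(2, 3)
    assert f_delta(v, cfg) == F(4, 6)
    assert f_t(v, cfg) == 1


# ---------------------------------------------------------------- aggregates
def test_w_tot_worked_examples(cfg):
    empty = w_tot(vset(), cfg)
    assert empty.w_tot == F(1) and empty.F_S == 1

    full = w_tot(
        vset("BOD", "TN", "TP", "MLSS", "DO", "T"), cfg.with_modelled("BOD")
    )
    assert (full.delta, full.f_delta, full.f_t) == (F(1), F(1), 0)
    assert (full.lambda_, full.f_lambda, full.F_S) == (F(1), F(1), 0)
    assert full.w_tot == F(4)

    mt = w_tot(vset("MLSS", "T"), cfg)
    assert (mt.lambda_, mt.f_lambda) == (F(2, 3), F(4, 6))
    assert mt.w_tot == F(4, 3)


def test_boundary_conditions_examples(cfg):
    pi = boundary_conditions(vset("MLSS", "T"), cfg)
    assert pi["pi1"] == 0
    assert pi["pi2"] == F(2, 3) + F(4, 6)
    assert pi["pi3"] == pi["pi2"]
    assert pi["pi4"] == pi["pi3"]

    pi = boundary_conditions(vset(), cfg)
    assert (pi["pi1"], pi["pi2"], pi["pi3"], pi["pi4"]) == (0, 0, 0, 1)

    pi = boundary_conditions(vset("BOD"), cfg)
    assert pi["pi1"] == F(1, 3) + F(1, 6) + 1
    assert pi["pi2"] == 0
    assert pi["pi4"] == pi["pi3"] + 1


def test_w_tot_min_selection_and_tiebreaks(cfg):
    best, _ = w_tot_min([vset("MLSS", "DO", "T"), vset("MLSS", "T")], cfg)
    assert best.members == ("MLSS", "T")
    only = vset("T")
    assert w_tot_min([only], cfg)[0] is only
    with pytest.raises(ValueError):
        w_tot_min([], cfg)
    # exact tie (equal costs): lexicographic member order decides
    flat = WeightConfig(operational_costs={"T": 1, "DO": 1, "MLSS": 1})
    tie, _ = w_tot_min([vset("T"), vset("DO")], flat)
    assert tie.members == ("DO",)


# ------------------------------------------------------------------- oracle
def _brute_force(names: tuple[str, ...]):
    """Independent first-principles computation on the default weights."""
    qcost = {"BOD": 1, "TP": 2, "TN": 3}
    ocost = {"T": 1, "DO": 2, "MLSS": 3}
    q = [n for n in names if n in qcost]
    o = [n for n in names if n in ocost]
    return (
        F(len(q), 3),
        F(sum(qcost[n] for n in q), 6),
        F(len(o), 3),
        F(sum(ocost[n] for n in o), 6),
        1 if "BOD" in q else 0,
        0 if o or "mPIX" in names else 1,
    )


def test_all_64_subsets_match_brute_force(cfg):
    for r in range(7):
        for names in itertools.combinations(SIX_VARS, r):
            v = vset(*names)
            d, fd, lam, fl, ft, fs = _brute_force(names)
            assert delta(v, cfg) == d
            assert f_delta(v, cfg) == fd
            assert lambda_(v, cfg) == lam
            assert f_lambda(v, cfg) == fl
            assert f_t(v, cfg) == ft
            assert F_S(v, cfg) == fs
            assert w_tot(v, cfg).w_tot == d + fd + ft + lam + fl + fs


subset_st = st.sets(st.sampled_from(SIX_VARS))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(a=subset_st, b=subset_st)
def test_monotonicity_under_inclusion(a, b):
    """Count/cost fractions grow with the set; controllability flag shrinks."""
    cfg = WeightConfig()
    va, vu = vset(*a), vset(*(a | b))
    for fn in (delta, f_delta, lambda_, f_lambda):
        lo, hi = fn(va, cfg), fn(vu, cfg)
        assert 0 <= lo <= hi <= 1
    assert f_t(vu, cfg) >= f_t(va, cfg)
    assert F_S(vu, cfg) <= F_S(va, cfg)


def test_full_sets_normalize_to_one():
    cfg = WeightConfig(
        quality_costs={"BOD": 5, "TP": 1, "TN": 2},
        operational_costs={"T": 4, "DO": 1, "MLSS": 7},
    )
    assert f_delta(vset("BOD", "TN", "TP"), cfg) == 1
    assert f_lambda(vset("MLSS", "DO", "T"), cfg) == 1


# -------------------------------------------------------------- Monte Carlo
def test_monte_carlo_degenerate_matches_deterministic(cfg):
    v = vset("BOD", "MLSS")
    out = monte_carlo_weights(v, cfg, n_draws=50, rng_seed=3, spread=0)
    assert out["mean"] == pytest.approx(float(w_tot(v, cfg).w_tot))
    assert out["sd"] == pytest.approx(0.0, abs=1e-12)


def test_monte_carlo_is_seed_reproducible(cfg):
    v = vset("TN", "DO")
    a = monte_carlo_weights(v, cfg, n_draws=1, rng_seed=9)
    b = monte_carlo_weights(v, cfg, n_draws=1, rng_seed=9)
    assert a["draws"][0] == b["draws"][0]


def test_monte_carlo_mean_matches_exact_enumeration(cfg):
    """Mean over draws agrees with the exact expectation over the finite
    +/-1 support (3^6 equally likely cost vectors)."""
    v = vset("BOD", "TP", "MLSS", "T")
    qn = sorted(cfg.quality_costs)
    on = sorted(cfg.operational_costs)
    d = float(delta(v, cfg))
    lam = float(lambda_(v, cfg))
    ft, fs = f_t(v, cfg), F_S(v, cfg)
    supports = [
        [max(1, cfg.quality_costs[n] - 1) if k == 0 else cfg.quality_costs[n] + k - 1
         for k in range(3)]
        for n in qn
    ] + [
        [max(1, cfg.operational_costs[n] - 1) if k == 0 else cfg.operational_costs[n] + k - 1
         for k in range(3)]
        for n in on
    ]
    total, count = 0.0, 0
    qin = [n in v.quality_indicators(cfg) for n in qn]
    oin = [n in v.operational_parameters(cfg) for n in on]
    for ks in itertools.product(*supports):
        qk, ok = ks[:3], ks[3:]
        fd = sum(k for k, i in zip(qk, qin) if i) / sum(qk)
        fl = sum(k for k, i in zip(ok, oin) if i) / sum(ok)
        total += (d + fd + ft) + (lam + fl) + fs
        count += 1
    exact = total / count

    out = monte_carlo_weights(v, cfg, n_draws=20_000, rng_seed=5, spread=1)
    se = out["sd"] / np.sqrt(out["n_draws"])
    assert abs(out["mean"] - exact) < 3 * se
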