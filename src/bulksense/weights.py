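"""Cost/duration/controllability weight system for candidate predictor sets.

For a candidate combination of predictors the system scores, on the
influent-quality side, the indicator count fraction delta and the cost
fraction f(delta); the binary duration penalty f(t); on the operating-
parameter side the count fraction lambda and cost fraction f(lambda);
and the controllability indicator F(S) (0 when the set contains at least
one variable an operator can use to steer SVI).  The cumulative weight

    W_tot = {delta + f(delta) + f(t)} + {lambda + f(lambda)} + F(S)

ranks candidate sets: cheaper, faster, controllable sets score lower.
All fractions are exact ``fractions.Fraction`` values.

Cost weights are ordinal and may themselves be uncertain; a Monte Carlo
summary of W_tot under perturbed cost weights is provided.
"""
from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .types import VariableSet, WeightConfig, WeightVector

__all__ = [
    "delta",
    "f_delta",
    "f_t",
    "lambda_",
    "f_lambda",
    "F_S",
    "w_tot",
    "w_tot_min",
    "boundary_conditions",
    "monte_carlo_weights",
]


def delta(vset: VariableSet, cfg: WeightConfig) -> Fraction:
    """Fraction of quality indicators included: count / q."""
    included = vset.quality_indicators(cfg)
    q = cfg.quality_max_count
    if len(included) > q:
        raise ValueError(
            f"{len(included)} quality indicators in set but quality_max_count={q}"
        )
    return Fraction(len(included), q)


def f_delta(vset: VariableSet, cfg: WeightConfig) -> Fraction:
    """Cost fraction of the included quality indicators: sum K / sum K_all."""
    return _cost_fraction(vset.quality_indicators(cfg), cfg.quality_costs, "quality")


def lambda_(vset: VariableSet, cfg: WeightConfig) -> Fraction:
    """Fraction of operating parameters included: count / g."""
    included = vset.operational_parameters(cfg)
    g = cfg.operational_max_count
    if len(included) > g:
        raise ValueError(
            f"{len(included)} operating parameters in set but operational_max_count={g}"
        )
    return Fraction(len(included), g)


def f_lambda(vset: VariableSet, cfg: WeightConfig) -> Fraction:
    """Cost fraction of the included operating parameters."""
    return _cost_fraction(
        vset.operational_parameters(cfg), cfg.operational_costs, "operational"
    )


def _cost_fraction(included: frozenset[str], costs, side: str) -> Fraction:
    total = sum(costs.values())
    s = 0
    for name in included:
        if name not in costs:
            raise KeyError(f"no {side} cost weight configured for {name!r}")
        s += costs[name]
    return Fraction(s, total)


def f_t(vset: VariableSet, cfg: WeightConfig) -> int:
    """Duration penalty: 1 if any included quality indicator needs > 24 h.

    An indicator whose value may be supplied by a statistical surrogate
    (``cfg.modelled_indicators``) carries no duration penalty.
    """
    for name in vset.quality_indicators(cfg):
        if cfg.duration_flags.get(name, 0) == 1 and name not in cfg.modelled_indicators:
            return 1
    return 0


def F_S(vset: VariableSet, cfg: WeightConfig | None = None) -> int:
    """Controllability: 0 if the set contains a controllable variable, else 1."""
    cfg = cfg or WeightConfig()
    return 0 if vset.variables() & cfg.controllable else 1


def _blocks(vset: VariableSet, cfg: WeightConfig):
    d = delta(vset, cfg)
    fd = f_delta(vset, cfg)
    ft = f_t(vset, cfg)
    lam = lambda_(vset, cfg)
    fl = f_lambda(vset, cfg)
    fs = F_S(vset, cfg)
    if cfg.aggregation == "sum":
        quality_block = d + fd + ft
        operational_block = lam + fl
    else:  # min within each block
        quality_block = min(d, fd, Fraction(ft))
        operational_block = min(lam, fl)
    return d, fd, ft, lam, fl, fs, quality_block, operational_block


def w_tot(vset: VariableSet, cfg: WeightConfig | None = None) -> WeightVector:
    """All six weight components and their cumulative aggregate."""
    cfg = cfg or WeightConfig()
    d, fd, ft, lam, fl, fs, qb, ob = _blocks(vset, cfg)
    return WeightVector(
        delta=d, f_delta=fd, f_t=ft, lambda_=lam, f_lambda=fl, F_S=fs,
        w_tot=qb + ob + fs,
    )


def boundary_conditions(vset: VariableSet, cfg: WeightConfig | None = None) -> dict[str, Fraction]:
    """The four objective values used to rank candidate sets.

    pi1 = quality block (count + cost + duration), pi2 = operational
    block, pi3 = pi1 + pi2, pi4 = pi3 + F(S).  pi4 is the full
    cumulative weight; pi1-pi3 allow ranking when only one side of the
    measurement programme is negotiable.
    """
    cfg = cfg or WeightConfig()
    _, _, _, _, _, fs, qb, ob = _blocks(vset, cfg)
    return {"pi1": qb, "pi2": ob, "pi3": qb + ob, "pi4": qb + ob + fs}


def w_tot_min(
    candidates: Sequence[VariableSet], cfg: WeightConfig | None = None
) -> tuple[VariableSet, WeightVector]:
    """Candidate minimizing the cumulative weight.

    Ties break deterministically: fewest variables, then lexicographic
    member order.
    """
    if not candidates:
        raise ValueError("no candidate variable sets supplied")
    cfg = cfg or WeightConfig()
    scored = [(w_tot(v, cfg), v) for v in candidates]
    best = min(scored, key=lambda wv: (wv[0].w_tot, len(wv[1].variables()), wv[1].members))
    return best[1], best[0]


def monte_carlo_weights(
    vset: VariableSet,
    cfg: WeightConfig | None = None,
    n_draws: int = 10_000,
    rng_seed: int = 0,
    spread: int = 1,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> dict:
    """Monte Carlo summary of W_tot under uncertain cost weights.

    Each draw perturbs every configured cost weight independently and
    uniformly over the integer window {K-spread, ..., K+spread} clipped
    below at 1, then recomputes the cost fractions with the drawn
    denominators.  ``spread=0`` is degenerate and reproduces the
    deterministic W_tot exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    cfg = cfg or WeightConfig()
    rng = np.random.default_rng(rng_seed)

    q_names = sorted(cfg.quality_costs)
    o_names = sorted(cfg.operational_costs)
    q_base = np.array([cfg.quality_costs[n] for n in q_names])
    o_base = np.array([cfg.operational_costs[n] for n in o_names])
    q_in = np.array([n in vset.quality_indicators(cfg) for n in q_names])
    o_in = np.array([n in vset.operational_parameters(cfg) for n in o_names])

    # Fixed components: only the cost fractions depend on the drawn weights.
    d = float(delta(vset, cfg))
    ft = f_t(vset, cfg)
    lam = float(lambda_(vset, cfg))
    fs = F_S(vset, cfg)

    def draw(base: np.ndarray) -> np.ndarray:
        # uniform over {K-spread..K+spread}, then value-clipped below at 1
        raw = rng.integers(base - spread, base + spread + 1, size=(n_draws, base.size))
        return np.maximum(raw, 1)

    qk = draw(q_base)
    ok = draw(o_base)
    fd = (qk * q_in).sum(axis=1) / qk.sum(axis=1)
    fl = (ok * o_in).sum(axis=1) / ok.sum(axis=1)
    if cfg.aggregation == "sum":
        tot = (d + fd + ft) + (lam + fl) + fs
    else:
        tot = np.minimum(np.minimum(d, fd), ft) + np.minimum(lam, fl) + fs

    qs = np.quantile(tot, quantiles)
    return {
        "mean": float(tot.mean()),
        "sd": float(tot.std(ddof=1)) if n_draws > 1 else 0.0,
        "quantiles": {float(q): float(v) for q, v in zip(quantiles, qs)},
        "n_draws": n_draws,
        "draws": tot,
    }
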