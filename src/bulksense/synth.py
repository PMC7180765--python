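"""Synthetic plant-monitoring records with known bulking ground truth.

Each monitored variable is drawn from a season-specific truncated
normal whose min/mean/max/SD reproduce the published seasonal summary
statistics of the studied treatment plant (two regimes: winter and
spring-fall).  Marginals are independent by default — the source gives
no correlation structure — with an optional Gaussian-copula hook for
rank-correlated stress tests.  The bulking state of record t is drawn
from Bernoulli(p) with p given by a label model (default: the shipped
logistic sensor) evaluated on record t-lag, optionally flipped with a
small label-noise probability; SVI is then sampled uniformly within the
season's observed band on the matching side of the 150 cm3/g limit, so
the binary label and the stored SVI are always mutually consistent.

The winter SVI band (154-291 cm3/g) lies entirely above the limit; when
a season's band is empty on one side, the pooled across-season band is
used for that side.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import fixture_table2  # re-exported: part of the data-provision surface
from .preprocess import SVI_LIM_DEFAULT
from .sensor import LogitBulkingSensor

__all__ = ["TABLE1_STATS", "generate", "fixture_table2"]

#: Seasonal marginal statistics (min, mean, max, SD) per variable.
TABLE1_STATS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "winter": {
        "Q": (29952, 39364, 88986, 6563),
        "BOD": (151, 290, 489, 81.83),
        "COD": (384, 782, 1183, 161.4),
        "TSS": (136, 315, 474, 62.76),
        "NNH4": (28, 48.9, 62, 5.68),
        "TN": (56.2, 82.01, 95.16, 8.42),
        "TP": (3.1, 7.22, 12.1, 1.44),
        "T": (10, 11.9, 13.5, 0.8),
        "DO": (1.8, 2.85, 3.25, 0.8),
        "MLSS": (2.85, 4.95, 6.54, 0.84),
        "MLSSR": (6.62, 8.7, 14.92, 0.72),
        "WAS": (12.69, 15.35, 18.35, 3.51),
        "RAS": (85.2, 102.9, 152, 16.25),
        "SVI": (154, 198, 291, 35),
        "mPIX": (0, 0.81, 1.75, 0.27),
    },
    "spring_fall": {
        "Q": (30125, 41842, 94772, 8559),
        "BOD": (132, 340, 557, 81.2),
        "COD": (342, 820, 1703, 178.2),
        "TSS": (110, 350, 572, 89.4),
        "NNH4": (22, 54.52, 66.9, 7.13),
        "TN": (39.9, 95.15, 124.1, 11.58),
        "TP": (3.5, 7.83, 12.6, 1.65),
        "T": (11.3, 17.8, 23, 3.1),
        "DO": (1.51, 2.2, 3.25, 0.65),
        "MLSS": (2.15, 4.11, 5.28, 0.95),
        "MLSSR": (5.03, 7.81, 11.86, 0.1),
        "WAS": (10.02, 12.35, 17.25, 3.77),
        "RAS": (75.2, 83.06, 120.5, 24.4),
        "SVI": (90, 138, 200, 37),
        "mPIX": (0, 0.84, 1.82, 0.28),
    },
}

_DRAW_ORDER = [
    "Q", "BOD", "COD", "TSS", "NNH4", "TN", "TP",
    "T", "DO", "MLSS", "MLSSR", "WAS", "RAS", "mPIX",
]


def _validate_stats(stats_table) -> None:
    for season, table in stats_table.items():
        for var, (lo, mean, hi, sd) in table.items():
            if sd <= 0:
                raise ValueError(f"{season}/{var}: SD must be > 0, got {sd}")
            if lo >= hi:
                raise ValueError(f"{season}/{var}: min {lo} must be < max {hi}")


def _truncnorm(lo, mean, hi, sd):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def generate(
    n_records: int,
    season_mix: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    stats_table: Mapping | None = None,
    label_model: LogitBulkingSensor | None = None,
    label_noise: float = 0.05,
    svi_lim: float = SVI_LIM_DEFAULT,
    lag: int = 1,
    rank_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate plant-like monitoring records.

    Parameters
    ----------
    n_records : number of records to draw.
    season_mix : mapping season -> probability (default 50/50
        winter / spring_fall, the two published regimes).
    rng_seed : seed; identical arguments reproduce the dataset exactly.
    stats_table : seasonal (min, mean, max, SD) marginals; defaults to
        the published plant statistics.
    label_model : probability-of-bulking model; default is the shipped
        logistic sensor, evaluated on the record ``lag`` steps earlier
        (a record's own values are used while no earlier record exists).
    label_noise : probability of flipping the drawn bulking state,
        emulating labelling error; must lie in [0, 0.5).
    rank_corr : optional rank-correlation matrix (over the 14 drawn
        variables, in standard column order) applied through a Gaussian
        copula; default independent marginals.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must lie in [0, 0.5)")
    stats_table = dict(stats_table or TABLE1_STATS)
    _validate_stats(stats_table)
    season_mix = dict(season_mix or {s: 1.0 / len(stats_table) for s in stats_table})
    bad = [s for s in season_mix if s not in stats_table]
    if bad:
        raise ValueError(f"season_mix names unknown season(s) {bad}")
    label_model = label_model or LogitBulkingSensor.default()

    rng = np.random.default_rng(rng_seed)
    seasons = list(season_mix)
    probs = np.array([season_mix[s] for s in seasons], dtype=float)
    probs = probs / probs.sum()
    season_col = rng.choice(seasons, size=n_records, p=probs)

    # uniform quantiles per variable, optionally rank-correlated via a copula
    k = len(_DRAW_ORDER)
    if rank_corr is not None:
        rank_corr = np.asarray(rank_corr, dtype=float)
        if rank_corr.shape != (k, k):
            raise ValueError(f"rank_corr must be {k}x{k} (order {_DRAW_ORDER})")
        z = rng.multivariate_normal(np.zeros(k), rank_corr, size=n_records)
        U = stats.norm.cdf(z)
    else:
        U = rng.random((n_records, k))

    data = {var: np.empty(n_records) for var in _DRAW_ORDER}
    for season in seasons:
        mask = season_col == season
        if not mask.any():
            continue
        for j, var in enumerate(_DRAW_ORDER):
            lo, mean, hi, sd = stats_table[season][var]
            data[var][mask] = _truncnorm(lo, mean, hi, sd).ppf(U[mask, j])

    df = pd.DataFrame(data)

    # bulking state from the label model on the lagged record
    source = df.shift(lag)
    for col in df.columns:
        source.loc[source[col].isna(), col] = df.loc[source[col].isna(), col]
    p_bulk = np.asarray(label_model.predict_proba(source), dtype=float)
    bulking = rng.random(n_records) < p_bulk
    flip = rng.random(n_records) < label_noise
    bulking = bulking ^ flip

    pooled_lo = min(stats_table[s]["SVI"][0] for s in stats_table)
    pooled_hi = max(stats_table[s]["SVI"][2] for s in stats_table)
    svi = np.empty(n_records)
    u_svi = rng.random(n_records)
    for season in seasons:
        mask = season_col == season
        lo, _, hi, _ = stats_table[season]["SVI"]
        non_lo = lo if lo < svi_lim else pooled_lo
        bulk_hi = hi if hi > svi_lim else pooled_hi
        m = mask & bulking
        svi[m] = svi_lim + u_svi[m] * (bulk_hi - svi_lim)
        m = mask & ~bulking
        svi[m] = non_lo + u_svi[m] * (svi_lim - non_lo)
    # bulking requires a strict exceedance of the limit
    svi[bulking & (svi <= svi_lim)] = np.nextafter(svi_lim, np.inf)

    df["SVI"] = svi
    df["season"] = season_col
    return df
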