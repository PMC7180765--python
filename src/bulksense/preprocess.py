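"""Turn raw plant records into lagged, binarized, screened model matrices.

The response is the binary bulking state derived from SVI against a
limit value (default 150 cm3/g): label 0 (bulking) where SVI strictly
exceeds the limit, label 1 otherwise.  Predictors are taken one record
earlier than the response by default, reflecting the plant's one-step
predictive use of the sensor.
"""
from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .types import RECORD_COLUMNS, VariableSet

__all__ = [
    "binarize_svi",
    "lag_align",
    "significance_screen",
    "split",
    "read_records",
    "write_records",
]

SVI_LIM_DEFAULT = 150.0


def binarize_svi(svi, svi_lim: float = SVI_LIM_DEFAULT) -> np.ndarray:
    """Binary bulking labels from SVI: 0 (bulking) where SVI > svi_lim, else 1.

    The boundary value SVI == svi_lim counts as non-bulking.  Idempotent on
    its own output interpreted as already-binary values (0/1 never exceed
    any positive limit, so they all map to 1 only if rebinarized — callers
    binarize the physical SVI exactly once).
    """
    if svi_lim <= 0:
        raise ValueError("svi_lim must be positive")
    arr = np.asarray(svi, dtype=float)
    return np.where(arr > svi_lim, 0, 1)


def _term_values(df: pd.DataFrame, term: str) -> pd.Series:
    if "/" in term:
        num, den = term.split("/")
        denom = df[den].where(df[den] != 0, np.nan)
        return df[num] / denom
    return df[term]


def lag_align(
    dataset: pd.DataFrame,
    vset: VariableSet,
    svi_lim: float = SVI_LIM_DEFAULT,
    lag: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Model matrix and label vector for a predictor set.

    Predictors are taken ``lag`` records before the response; the first
    ``lag`` records are dropped.  Ratio terms are computed after lagging;
    a zero denominator or any missing predictor drops the row with a
    warning reporting the count.
    """
    if not vset.members:
        raise ValueError("variable set is empty")
    lag = vset.lag if lag is None else lag
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag >= len(dataset):
        raise ValueError(f"lag={lag} leaves no rows from {len(dataset)} records")

    missing = [v for v in sorted(vset.variables()) if v not in dataset.columns]
    if missing:
        raise KeyError(f"dataset lacks columns {missing}")

    lagged = dataset.shift(lag)
    X = pd.DataFrame({m: _term_values(lagged, m) for m in vset.members})
    y = pd.Series(
        binarize_svi(dataset["SVI"], svi_lim), index=dataset.index, name="bulking_label"
    )
    X = X.iloc[lag:]
    y = y.iloc[lag:]

    ok = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} row(s) with missing or undefined predictors",
            stacklevel=2,
        )
    return X.loc[ok], y.loc[ok]


def significance_screen(
    model_matrix: pd.DataFrame, labels, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way F-test of each predictor between the two label groups.

    Returns a report frame (predictor, F, p, kept) sorted as the input
    columns; predictors with p > alpha are flagged for omission.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("significance screen needs records from both classes")
    g0 = model_matrix.loc[y == classes[0]]
    g1 = model_matrix.loc[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("significance screen needs >= 2 records per class")

    rows = []
    for col in model_matrix.columns:
        a, b = g0[col].to_numpy(float), g1[col].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            F, p = 0.0, 1.0  # constant predictor carries no between-group signal
        else:
            F, p = stats.f_oneway(a, b)
        rows.append({"predictor": col, "F": float(F), "p": float(p), "kept": bool(p <= alpha)})
    return pd.DataFrame(rows)


def split(
    model_matrix: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.75,
    seed: int = 0,
    stratify: bool = True,
    chronological: bool = False,
):
    """Split into learning and test partitions.

    Default is a seeded random split stratified by class so both classes
    appear on both sides when counts permit; a class with a single record
    is forced into the learning partition with a warning.  Chronological
    mode takes the leading ``fraction`` of records instead.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    y = np.asarray(labels)
    if chronological:
        n_train = int(round(len(y) * fraction))
        idx = np.arange(len(y))
        tr, te = idx[:n_train], idx[n_train:]
        return (
            model_matrix.iloc[tr], model_matrix.iloc[te],
            labels.iloc[tr], labels.iloc[te],
        )

    strat = None
    if stratify:
        counts = pd.Series(y).value_counts()
        if (counts < 2).any():
            rare = counts[counts < 2].index.tolist()
            warnings.warn(
                f"class(es) {rare} have a single record; forcing into the "
                "learning partition and splitting the rest unstratified",
                stacklevel=2,
            )
            rare_mask = np.isin(y, rare)
            keep_idx = np.where(~rare_mask)[0]
            Xtr, Xte, ytr, yte = train_test_split(
                model_matrix.iloc[keep_idx],
                labels.iloc[keep_idx],
                train_size=fraction,
                random_state=seed,
                stratify=y[keep_idx] if pd.Series(y[keep_idx]).value_counts().min() >= 2 else None,
            )
            Xtr = pd.concat([Xtr, model_matrix.iloc[rare_mask]])
            ytr = pd.concat([ytr, labels.iloc[rare_mask]])
            return Xtr, Xte, ytr, yte
        strat = y
    return train_test_split(
        model_matrix, labels, train_size=fraction, random_state=seed, stratify=strat
    )


def resample_records(dataset: pd.DataFrame, window: int) -> pd.DataFrame:
    """Mean-aggregate high-frequency records over non-overlapping windows.

    Joins e.g. hourly SCADA readings onto the cadence of the laboratory
    response: numeric columns are averaged per block of ``window``
    consecutive records; a season column keeps the block's first value.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return dataset.copy()
    groups = np.arange(len(dataset)) // window
    numeric = dataset.select_dtypes("number").groupby(groups).mean()
    out = numeric
    if "season" in dataset.columns:
        out = out.assign(season=dataset["season"].groupby(groups).first().to_numpy())
    return out.reset_index(drop=True)


def read_records(path) -> pd.DataFrame:
    """Read the standard plant-records CSV, validating required columns."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing column(s): {missing}")
    numeric = [c for c in RECORD_COLUMNS if c != "season"]
    neg = [c for c in numeric if (df[c].dropna() < 0).any()]
    if neg:
        raise ValueError(f"negative values in physical quantities: {neg}")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in RECORD_COLUMNS if c in df.columns])
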