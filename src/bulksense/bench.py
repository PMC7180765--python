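"""Benchmark of candidate classifier families for bulking identification.

Five families are trained per predictor combination: logistic regression
(LR, maximum likelihood, no penalty), boosted trees (BT) and random
forests (RF) with the tree count selected by internal validation under a
cap, a one-hidden-layer perceptron (MLP) grid-searched over hidden sizes
j..2j+1 and five activations, and a Gaussian-kernel SVM grid-searched
over (C, gamma).  Every search minimizes (1-SENS)+(1-SPEC) on a seeded
internal validation split of the learning partition; the held-out test
partition is never consulted during selection.  Probabilistic families
classify at threshold 0.5 by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from ._mlp import SmallMLP
from .preprocess import lag_align, split
from .types import FitMetrics, TrainConfig, VariableSet

__all__ = [
    "FAMILIES",
    "SIMPLICITY_ORDER",
    "CandidateModel",
    "train_model",
    "evaluate",
    "combination_search",
    "rank_models",
    "pareto_front",
]

FAMILIES = ("LR", "BT", "RF", "MLP", "SVM")

#: Preference order when metrics tie: simpler structure first.
SIMPLICITY_ORDER = ("LR", "BT", "RF", "SVM", "MLP")


@dataclass
class CandidateModel:
    """A fitted candidate classifier with its selected hyperparameters."""

    family: str
    estimator: object
    hyperparams: dict = field(default_factory=dict)
    threshold: float = 0.5
    converged: bool = True
    validation_metrics: FitMetrics | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            p1 = proba[:, 1] if np.ndim(proba) == 2 else proba
            return (p1 >= self.threshold).astype(int)
        return np.asarray(est.predict(X)).astype(int)

    def hyperparam_label(self) -> str:
        """Compact fit-table annotation, e.g. '98' (trees) or '5:tanh'."""
        hp = self.hyperparams
        if self.family in ("BT", "RF"):
            return str(hp.get("n_trees", ""))
        if self.family == "MLP":
            return f"{hp.get('hidden', '')}:{hp.get('activation', '')}"
        if self.family == "SVM":
            return f"{hp.get('C', '')};{hp.get('gamma', '')}"
        return ""

    def summary(self) -> str:
        lines = [f"CandidateModel(family={self.family}, converged={self.converged})"]
        if self.hyperparams:
            lines.append(f"  hyperparameters: {self.hyperparams}")
        if self.validation_metrics is not None:
            m = self.validation_metrics
            lines.append(
                f"  internal validation: SENS={m.sens:.3f} SPEC={m.spec:.3f} (n={m.n_test})"
            )
        return "\n".join(lines)


def evaluate(model: CandidateModel, X_test, y_test) -> FitMetrics:
    """SENS/SPEC on a test partition containing both classes.

    SPEC = correct among bulking records (label 0); SENS = correct among
    non-bulking records (label 1).
    """
    y = np.asarray(y_test).astype(int)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("test partition must contain both classes for SENS/SPEC")
    yhat = model.predict(np.asarray(X_test, dtype=float))
    bulk, nonbulk = y == 0, y == 1
    return FitMetrics(
        n_bulk_correct=int((yhat[bulk] == 0).sum()),
        n_bulk=int(bulk.sum()),
        n_nonbulk_correct=int((yhat[nonbulk] == 1).sum()),
        n_nonbulk=int(nonbulk.sum()),
    )


def _metrics_from_pred(y, yhat) -> FitMetrics:
    bulk, nonbulk = y == 0, y == 1
    return FitMetrics(
        int((yhat[bulk] == 0).sum()), int(bulk.sum()),
        int((yhat[nonbulk] == 1).sum()), int(nonbulk.sum()),
    )


def _objective(y, yhat) -> float:
    """(1-SENS)+(1-SPEC); classes missing from the fold count as error 1."""
    bulk, nonbulk = y == 0, y == 1
    spec = (yhat[bulk] == 0).mean() if bulk.any() else 0.0
    sens = (yhat[nonbulk] == 1).mean() if nonbulk.any() else 0.0
    return (1.0 - sens) + (1.0 - spec)


def _validation_split(X, y, cfg: TrainConfig):
    Xdf = pd.DataFrame(np.asarray(X, dtype=float))
    ys = pd.Series(np.asarray(y).astype(int))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny folds may force unstratified splits
        Xtr, Xva, ytr, yva = split(
            Xdf, ys, fraction=cfg.split_fraction, seed=cfg.rng_seed, stratify=True
        )
    return (
        Xtr.to_numpy(), Xva.to_numpy(),
        ytr.to_numpy().astype(int), yva.to_numpy().astype(int),
    )


def train_model(family: str, X_train, y_train, cfg: TrainConfig | None = None) -> CandidateModel:
    """Fit one family on the learning partition, selecting hyperparameters
    on a seeded internal validation fold, then refitting on all of it."""
    cfg = cfg or TrainConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")

    if family == "LR":
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                est.fit(X, y)
            except ConvergenceWarning:
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X, y)
                converged = False
        return CandidateModel("LR", est, {}, cfg.threshold, converged)

    Xtr, Xva, ytr, yva = _validation_split(X, y, cfg)
    best = None  # (objective, tiebreak, hyperparams, builder)

    def consider(obj: float, tiebreak, hp: dict, builder) -> None:
        nonlocal best
        key = (obj, tiebreak)
        if best is None or key < best[0]:
            best = (key, hp, builder)

    if family in ("BT", "RF"):
        for n in cfg.tree_grid:
            est = _tree_estimator(family, n, cfg.rng_seed).fit(Xtr, ytr)
            yhat = (est.predict_proba(Xva)[:, 1] >= cfg.threshold).astype(int)
            consider(
                _objective(yva, yhat), n, {"n_trees": n},
                lambda n=n: _tree_estimator(family, n, cfg.rng_seed),
            )
    elif family == "MLP":
        j = X.shape[1]
        for h in cfg.mlp_hidden_range(j):
            for act in cfg.mlp_activations:
                est = SmallMLP(h, act, random_state=cfg.rng_seed).fit(Xtr, ytr)
                yhat = est.predict(Xva, cfg.threshold)
                consider(
                    _objective(yva, yhat), (h, act),
                    {"hidden": h, "activation": act},
                    lambda h=h, act=act: SmallMLP(h, act, random_state=cfg.rng_seed),
                )
    elif family == "SVM":
        for C in cfg.svm_C_grid:
            for g in cfg.svm_gamma_grid:
                est = SVC(kernel="rbf", C=C, gamma=g, random_state=cfg.rng_seed).fit(Xtr, ytr)
                yhat = est.predict(Xva).astype(int)
                consider(
                    _objective(yva, yhat), (C, g), {"C": C, "gamma": g},
                    lambda C=C, g=g: SVC(kernel="rbf", C=C, gamma=g, random_state=cfg.rng_seed),
                )

    (obj, _), hp, builder = best
    final = builder().fit(X, y)
    converged = getattr(final, "converged_", True)
    if converged is None:
        converged = True
    model = CandidateModel(family, final, hp, cfg.threshold, bool(converged))
    # record the metrics the selection saw
    refit_val = builder().fit(Xtr, ytr)
    if hasattr(refit_val, "predict_proba") and family != "SVM":
        yhat = (np.asarray(refit_val.predict_proba(Xva))[..., 1]
                if family in ("BT", "RF") else refit_val.predict_proba(Xva))
        yhat = (np.asarray(yhat) >= cfg.threshold).astype(int)
    else:
        yhat = np.asarray(refit_val.predict(Xva)).astype(int)
    model.validation_metrics = _metrics_from_pred(yva, yhat)
    return model


def _tree_estimator(family: str, n_trees: int, seed: int):
    if family == "BT":
        return GradientBoostingClassifier(n_estimators=n_trees, random_state=seed)
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed)


def combination_search(
    dataset: pd.DataFrame,
    combinations: Sequence[VariableSet],
    families: Sequence[str] = FAMILIES,
    cfg: TrainConfig | None = None,
    svi_lim: float = 150.0,
) -> pd.DataFrame:
    """Train every requested family on every predictor combination.

    Returns a fit table with one row per combination and per-family
    SP/SE columns plus hyperparameter annotations (tree counts, MLP
    topology, C;gamma), the layout consumed by the selection matrices.
    """
    if not combinations:
        raise ValueError("no predictor combinations supplied")
    cfg = cfg or TrainConfig()
    bad = [f for f in families if f not in FAMILIES]
    if bad:
        raise ValueError(f"unknown families {bad}")

    rows = []
    for vset in combinations:
        X, y = lag_align(dataset, vset, svi_lim=svi_lim)
        Xtr, Xte, ytr, yte = split(
            X, y, fraction=cfg.split_fraction, seed=cfg.rng_seed
        )
        row: dict = {"combo": vset.label(), "n_vars": len(vset.variables())}
        for fam in families:
            model = train_model(fam, Xtr, ytr, cfg)
            m = evaluate(model, Xte, yte)
            row[f"{fam}_SP"] = round(m.spec, 4)
            row[f"{fam}_SE"] = round(m.sens, 4)
            hp = model.hyperparam_label()
            if hp:
                row[f"{fam}_hp"] = hp
        rows.append(row)
    return pd.DataFrame(rows)


def _row_family_metrics(row: pd.Series, families: Iterable[str]):
    for fam in families:
        sp, se = row.get(f"{fam}_SP"), row.get(f"{fam}_SE")
        if sp is None or se is None or pd.isna(sp) or pd.isna(se):
            continue
        yield fam, float(se), float(sp)


def _family_key(fam: str):
    order = SIMPLICITY_ORDER.index(fam) if fam in SIMPLICITY_ORDER else len(SIMPLICITY_ORDER)
    return order


def rank_models(
    fit_table: pd.DataFrame, criterion: str = "min_sens_spec",
    families: Sequence[str] = FAMILIES,
) -> pd.DataFrame:
    """Per-combination best family under the selection criterion.

    Default criterion maximizes min(SENS, SPEC); ties break by
    SENS+SPEC, then by the fixed simplicity order LR > BT > RF > SVM >
    MLP.  'max_spec' and 'max_sens' are available for single-metric
    rankings.
    """
    if criterion not in ("min_sens_spec", "max_spec", "max_sens"):
        raise ValueError(f"unknown criterion {criterion!r}")
    out = []
    for _, row in fit_table.iterrows():
        scored = []
        for fam, se, sp in _row_family_metrics(row, families):
            if criterion == "min_sens_spec":
                primary = min(se, sp)
            elif criterion == "max_spec":
                primary = sp
            else:
                primary = se
            scored.append((-primary, -(se + sp), _family_key(fam), fam, se, sp))
        if not scored:
            raise ValueError(f"no family metrics in row {row.get('combo')}")
        scored.sort()
        _, _, _, fam, se, sp = scored[0]
        out.append(
            {
                "combo": row["combo"],
                "best_family": fam,
                "best_SE": se,
                "best_SP": sp,
                "score": min(se, sp) if criterion == "min_sens_spec" else max(se, sp),
            }
        )
    return pd.DataFrame(out)


def pareto_front(fit_table: pd.DataFrame, families: Sequence[str] = FAMILIES) -> pd.DataFrame:
    """Pareto-optimal combinations over (fewest variables, best fit).

    Fit is the per-combination best min(SENS, SPEC); a combination is on
    the front when no other has both fewer-or-equal variables and a
    strictly better fit (or equal fit with strictly fewer variables).
    """
    ranked = rank_models(fit_table, "min_sens_spec", families)
    if "n_vars" in fit_table.columns:
        nv = fit_table["n_vars"].to_numpy()
    else:
        nv = np.array([
            len(VariableSet.from_string(c).variables()) for c in fit_table["combo"]
        ])
    score = ranked["score"].to_numpy()
    keep = []
    for i in range(len(ranked)):
        dominated = np.any(
            (nv <= nv[i]) & (score >= score[i]) & ((nv < nv[i]) | (score > score[i]))
        )
        keep.append(not dominated)
    out = ranked.loc[keep].copy()
    out["n_vars"] = nv[keep]
    return out.sort_values(["n_vars", "score"], ascending=[True, False]).reset_index(drop=True)
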