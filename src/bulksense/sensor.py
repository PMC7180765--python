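"""Logistic soft sensor for sludge bulking with its omega/tau decomposition.

The sensor maps eight routinely measured quantities to the probability
of activated-sludge bulking through a logit

    X = tau + omega
    tau   = b0 + b_T*T + b_MLSS*MLSS + b_DO*DO + b_mPIX*mPIX
    omega = c_TN*L_TN + c_TP*L_TP + c_BOD*L_BOD

where tau collects the *controlling* variables (operator-adjustable
bioreactor settings; all slopes negative, so raising MLSS, DO, T or the
coagulant dosage suppresses bulking) and omega the *random-effect*
influent loads L = Q * concentration / 1000 (kg/d).  The default
coefficients are the full-scale plant fit shipped with the package;
refitted coefficient files plug into the same evaluator via YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = ["LogitBulkingSensor", "DEFAULT_COEFFICIENTS", "loads_from_records"]

#: Full-scale plant fit: intercept + controlling slopes keyed by variable,
#: load slopes keyed by L_<indicator> (loads in kg/d).
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": 28.24,
    "T": -0.68,
    "MLSS": -2.66,
    "DO": -1.82,
    "mPIX": -0.56,
    "L_TN": 0.0008,
    "L_TP": 0.0009,
    "L_BOD": 0.0001,
}

_CONTROLLING = ("T", "MLSS", "DO", "mPIX")
_LOAD_INDICATORS = ("TN", "TP", "BOD")
REQUIRED_INPUTS = _CONTROLLING + ("Q",) + _LOAD_INDICATORS


def loads_from_records(inputs: Mapping) -> dict[str, np.ndarray]:
    """Influent loads L_x = Q[m3/d] * x[mg/l] / 1000, in kg/d."""
    Q = np.asarray(inputs["Q"], dtype=float)
    return {
        f"L_{ind}": Q * np.asarray(inputs[ind], dtype=float) / 1000.0
        for ind in _LOAD_INDICATORS
    }


@dataclass
class LogitBulkingSensor:
    """Evaluator for a logistic bulking sensor.

    ``third_load`` selects which indicator the smallest load coefficient
    multiplies; the shipped model uses BOD, and "TP" is kept available
    because the source coefficient table is ambiguous on this term.
    ``positive_class`` records which event the probability refers to
    (default: the bulking event, label 0).
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    third_load: str = "BOD"
    positive_class: str = "bulking"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.third_load not in ("BOD", "TP"):
            raise ValueError("third_load must be 'BOD' or 'TP'")
        missing = [k for k in DEFAULT_COEFFICIENTS if k not in self.coefficients]
        if missing:
            raise ValueError(f"coefficients missing entries: {missing}")

    # -- components ---------------------------------------------------
    def _require(self, inputs: Mapping, keys) -> None:
        missing = [k for k in keys if k not in inputs]
        if missing:
            raise KeyError(f"missing sensor input(s): {missing}")

    def tau(self, inputs: Mapping) -> np.ndarray:
        """Controlling part: intercept plus the operating-parameter terms."""
        self._require(inputs, _CONTROLLING)
        b = self.coefficients
        return (
            b["intercept"]
            + sum(b[v] * np.asarray(inputs[v], dtype=float) for v in _CONTROLLING)
        )

    def omega(self, inputs: Mapping) -> np.ndarray:
        """Random-effect part: the influent-load terms."""
        self._require(inputs, ("Q",) + _LOAD_INDICATORS)
        L = loads_from_records(inputs)
        b = self.coefficients
        out = b["L_TN"] * L["L_TN"] + b["L_TP"] * L["L_TP"]
        out = out + b["L_BOD"] * L[f"L_{self.third_load}"]
        return out

    def linear_predictor(self, inputs: Mapping) -> np.ndarray:
        """X = tau + omega; raises KeyError naming any missing input."""
        self._require(inputs, REQUIRED_INPUTS)
        return self.tau(inputs) + self.omega(inputs)

    # -- probability and classification -------------------------------
    @staticmethod
    def probability(X) -> np.ndarray:
        """p = exp(X)/(1+exp(X)), computed overflow-safely."""
        return expit(np.asarray(X, dtype=float))

    def predict_proba(self, inputs: Mapping) -> np.ndarray:
        """Probability of the positive class (bulking by default)."""
        return self.probability(self.linear_predictor(inputs))

    def classify(self, p, threshold: float | None = None) -> np.ndarray:
        """Map probabilities to labels: 0 = bulking, 1 = no bulking."""
        thr = self.threshold if threshold is None else threshold
        p = np.asarray(p, dtype=float)
        bulking = p >= thr if self.positive_class == "bulking" else p < thr
        return np.where(bulking, 0, 1)

    def predict_label(self, inputs: Mapping) -> np.ndarray:
        return self.classify(self.predict_proba(inputs))

    # -- design matrix helper ------------------------------------------
    def design_matrix(
        self, records: pd.DataFrame, lag: int = 1
    ) -> tuple[pd.DataFrame, pd.Series | None]:
        """Lagged predictor columns matching the sensor's terms.

        Returns the seven-column frame (T, MLSS, DO, mPIX, L_TN, L_TP,
        L_BOD) aligned so that row t holds values from record t-lag, plus
        the binary bulking label of record t when an SVI column exists.
        """
        from .preprocess import binarize_svi

        lagged = records.shift(lag)
        cols = {v: lagged[v].astype(float) for v in _CONTROLLING}
        cols.update(loads_from_records(lagged))
        X = pd.DataFrame(cols).iloc[lag:]
        y = None
        if "SVI" in records.columns:
            y = pd.Series(
                binarize_svi(records["SVI"]), index=records.index, name="bulking_label"
            ).iloc[lag:]
        ok = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
        X = X.loc[ok]
        if y is not None:
            y = y.loc[X.index]
        return X, y

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "coefficients": dict(self.coefficients),
            "third_load": self.third_load,
            "positive_class": self.positive_class,
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LogitBulkingSensor":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            coefficients=dict(raw["coefficients"]),
            third_load=raw.get("third_load", "BOD"),
            positive_class=raw.get("positive_class", "bulking"),
            threshold=float(raw.get("threshold", 0.5)),
        )

    @classmethod
    def default(cls) -> "LogitBulkingSensor":
        """The shipped full-scale plant model."""
        return cls()
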