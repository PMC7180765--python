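"""Shared domain types for the bulking soft-sensor toolkit.

The vocabulary follows activated-sludge practice: influent *quality
indicators* (BOD, TN, TP, ...), bioreactor *operating parameters*
(T, DO, MLSS, ...), the coagulant dosage m_PIX, the influent flow Q,
and the sludge volumetric index SVI (cm3/g) whose exceedance of a limit
value marks bulking.  Class encoding throughout the package: label 0 =
bulking, label 1 = no bulking.  SPEC is the correct-classification rate
among bulking records and SENS among non-bulking records — note this is
swapped relative to the usual clinical sensitivity/specificity wording;
the toolkit follows the convention of its source domain and keeps it
consistent everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "VariableSpec",
    "WeightConfig",
    "VariableSet",
    "FitMetrics",
    "WeightVector",
    "TrainConfig",
    "DEFAULT_VARIABLES",
    "LETTER_CODES",
    "RECORD_COLUMNS",
]

#: Letter shorthand used in fit tables for predictor terms.
LETTER_CODES: dict[str, str] = {
    "A": "BOD",
    "B": "TN",
    "C": "TP",
    "D": "T",
    "E": "MLSS",
    "F": "DO",
    "G": "mPIX",
}
_NAME_TO_LETTER = {v: k for k, v in LETTER_CODES.items()}

#: Column order of the standard plant-records CSV.
RECORD_COLUMNS = [
    "Q", "BOD", "COD", "TSS", "NNH4", "TN", "TP",
    "T", "DO", "MLSS", "MLSSR", "WAS", "RAS", "mPIX", "SVI", "season",
]


@dataclass(frozen=True)
class VariableSpec:
    """One measurable plant quantity.

    cost_weight is the ordinal measurement-cost weight K (0 = cheapest);
    duration_flag is 1 when the laboratory determination takes longer than
    24 h; controllable marks variables an operator can adjust to steer SVI.
    """

    name: str
    category: str  # quality | operational | flow | dosage
    cost_weight: int = 0
    duration_flag: int = 0
    controllable: bool = False

    def __post_init__(self) -> None:
        if self.cost_weight < 0:
            raise ValueError(f"cost_weight must be >= 0, got {self.cost_weight}")
        if self.duration_flag not in (0, 1):
            raise ValueError(f"duration_flag must be 0 or 1, got {self.duration_flag}")
        if self.category not in ("quality", "operational", "flow", "dosage"):
            raise ValueError(f"unknown category {self.category!r}")


DEFAULT_VARIABLES: dict[str, VariableSpec] = {
    "Q": VariableSpec("Q", "flow"),
    "BOD": VariableSpec("BOD", "quality", cost_weight=1, duration_flag=1),
    "COD": VariableSpec("COD", "quality"),
    "TSS": VariableSpec("TSS", "quality"),
    "NNH4": VariableSpec("NNH4", "quality"),
    "TN": VariableSpec("TN", "quality", cost_weight=3),
    "TP": VariableSpec("TP", "quality", cost_weight=2),
    "T": VariableSpec("T", "operational", cost_weight=1, controllable=True),
    "DO": VariableSpec("DO", "operational", cost_weight=2, controllable=True),
    "MLSS": VariableSpec("MLSS", "operational", cost_weight=3, controllable=True),
    "MLSSR": VariableSpec("MLSSR", "operational"),
    "WAS": VariableSpec("WAS", "operational"),
    "RAS": VariableSpec("RAS", "operational"),
    "mPIX": VariableSpec("mPIX", "dosage", controllable=True),
}


@dataclass(frozen=True)
class WeightConfig:
    """Configuration of the cost/duration/controllability weight system.

    Defaults encode the cost orderings K(TN) > K(TP) > K(BOD) and
    K(MLSS) > K(DO) > K(T) with weights 3/2/1, a denominator count of
    three indicators on each side, BOD as the only long-duration
    determination, and MLSS, DO, T, m_PIX as controllable.
    ``modelled_indicators`` lists indicators whose value may be supplied
    by a statistical surrogate, which forces their duration penalty to 0.
    """

    quality_costs: Mapping[str, int] = field(
        default_factory=lambda: {"BOD": 1, "TP": 2, "TN": 3}
    )
    operational_costs: Mapping[str, int] = field(
        default_factory=lambda: {"T": 1, "DO": 2, "MLSS": 3}
    )
    quality_max_count: int = 3
    operational_max_count: int = 3
    duration_flags: Mapping[str, int] = field(
        default_factory=lambda: {"BOD": 1, "TN": 0, "TP": 0}
    )
    modelled_indicators: frozenset[str] = frozenset()
    controllable: frozenset[str] = frozenset({"MLSS", "DO", "T", "mPIX"})
    aggregation: str = "sum"  # sum | min (within each block)

    def __post_init__(self) -> None:
        object.__setattr__(self, "quality_costs", dict(self.quality_costs))
        object.__setattr__(self, "operational_costs", dict(self.operational_costs))
        object.__setattr__(self, "duration_flags", dict(self.duration_flags))
        object.__setattr__(self, "modelled_indicators", frozenset(self.modelled_indicators))
        object.__setattr__(self, "controllable", frozenset(self.controllable))
        if sum(self.quality_costs.values()) <= 0:
            raise ValueError("quality cost denominator must be strictly positive")
        if sum(self.operational_costs.values()) <= 0:
            raise ValueError("operational cost denominator must be strictly positive")
        if self.quality_max_count < 1 or self.operational_max_count < 1:
            raise ValueError("max counts must be >= 1")
        if self.aggregation not in ("sum", "min"):
            raise ValueError(f"aggregation must be 'sum' or 'min', got {self.aggregation!r}")

    @property
    def quality_indicators(self) -> frozenset[str]:
        return frozenset(self.quality_costs)

    @property
    def operational_parameters(self) -> frozenset[str]:
        return frozenset(self.operational_costs)

    def with_modelled(self, *indicators: str) -> "WeightConfig":
        return replace(self, modelled_indicators=self.modelled_indicators | set(indicators))

    @classmethod
    def from_yaml(cls, path) -> "WeightConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = raw.get("weights", raw)
        kwargs = {}
        for key in (
            "quality_costs", "operational_costs", "quality_max_count",
            "operational_max_count", "duration_flags", "aggregation",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("modelled_indicators", "controllable"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        payload = {
            "weights": {
                "quality_costs": dict(self.quality_costs),
                "operational_costs": dict(self.operational_costs),
                "quality_max_count": self.quality_max_count,
                "operational_max_count": self.operational_max_count,
                "duration_flags": dict(self.duration_flags),
                "modelled_indicators": sorted(self.modelled_indicators),
                "controllable": sorted(self.controllable),
                "aggregation": self.aggregation,
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _parse_term(token: str) -> str:
    """Translate a single term token; letters map through LETTER_CODES."""
    token = token.strip()
    if "/" in token:
        num, den = (t.strip() for t in token.split("/", 1))
        return f"{_parse_base(num)}/{_parse_base(den)}"
    return _parse_base(token)


def _parse_base(token: str) -> str:
    if token in LETTER_CODES:
        return LETTER_CODES[token]
    if token in DEFAULT_VARIABLES:
        return token
    raise ValueError(f"unknown variable token {token!r}")


@dataclass(frozen=True)
class VariableSet:
    """A candidate combination of predictor terms.

    Each member is either a plain variable name ("MLSS") or a ratio term
    ("BOD/TN"); ratio terms contribute both constituents to the cost and
    duration accounting.  ``lag`` is the record offset applied to the
    predictors relative to the response.
    """

    members: tuple[str, ...] = ()
    lag: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @classmethod
    def from_string(cls, text: str, lag: int = 1) -> "VariableSet":
        """Parse 'E,D' / 'MLSS,T' / 'A/B,D' style combination labels."""
        tokens = [t for t in (s.strip() for s in text.split(",")) if t]
        return cls(tuple(_parse_term(t) for t in tokens), lag=lag)

    def variables(self) -> frozenset[str]:
        """All base variables appearing in the set (ratio constituents included)."""
        out: set[str] = set()
        for m in self.members:
            out.update(m.split("/"))
        return frozenset(out)

    def quality_indicators(self, cfg: WeightConfig) -> frozenset[str]:
        """Quality indicators in the set: configured costs plus any variable
        registered with the quality category (so an unpriced indicator is
        seen — and rejected — by the cost functions rather than ignored)."""
        quality = cfg.quality_indicators | {
            n for n, s in DEFAULT_VARIABLES.items() if s.category == "quality"
        }
        return self.variables() & quality

    def operational_parameters(self, cfg: WeightConfig) -> frozenset[str]:
        operational = cfg.operational_parameters | {
            n for n, s in DEFAULT_VARIABLES.items() if s.category == "operational"
        }
        return self.variables() & operational

    def label(self) -> str:
        """Letter shorthand ('E,D') where available, plain names otherwise."""

        def enc(term: str) -> str:
            if "/" in term:
                a, b = term.split("/")
                return f"{_NAME_TO_LETTER.get(a, a)}/{_NAME_TO_LETTER.get(b, b)}"
            return _NAME_TO_LETTER.get(term, term)

        return ",".join(enc(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass(frozen=True)
class FitMetrics:
    """SENS/SPEC pair plus the confusion counts they derive from.

    spec = correct / total among bulking records (label 0);
    sens = correct / total among non-bulking records (label 1).
    """

    n_bulk_correct: int
    n_bulk: int
    n_nonbulk_correct: int
    n_nonbulk: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_bulk_correct <= self.n_bulk):
            raise ValueError("inconsistent bulking confusion counts")
        if not (0 <= self.n_nonbulk_correct <= self.n_nonbulk):
            raise ValueError("inconsistent non-bulking confusion counts")

    @property
    def spec(self) -> float:
        return self.n_bulk_correct / self.n_bulk

    @property
    def sens(self) -> float:
        return self.n_nonbulk_correct / self.n_nonbulk

    @property
    def n_test(self) -> int:
        return self.n_bulk + self.n_nonbulk


@dataclass(frozen=True)
class WeightVector:
    """Components of the cumulative weight for one variable combination."""

    delta: Fraction
    f_delta: Fraction
    f_t: int
    lambda_: Fraction
    f_lambda: Fraction
    F_S: int
    w_tot: Fraction

    def as_dict(self) -> dict[str, float]:
        return {
            "delta": float(self.delta),
            "f_delta": float(self.f_delta),
            "f_t": self.f_t,
            "lambda": float(self.lambda_),
            "f_lambda": float(self.f_lambda),
            "F_S": self.F_S,
            "w_tot": float(self.w_tot),
        }


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 75/25 split, tree cap, MLP and SVM search grids."""

    split_fraction: float = 0.75
    rng_seed: int = 0
    max_trees: int = 300
    tree_grid: tuple[int, ...] = (25, 50, 100, 200, 300)
    mlp_activations: tuple[str, ...] = ("linear", "exponential", "logistic", "sine", "tanh")
    svm_C_grid: tuple[float, ...] = (10.0, 100.0, 1000.0)
    svm_gamma_grid: tuple[float, ...] = (0.1, 0.25, 0.5)
    significance_alpha: float = 0.05
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not self.tree_grid or not self.svm_C_grid or not self.svm_gamma_grid:
            raise ValueError("search grids must be non-empty")
        if any(t > self.max_trees for t in self.tree_grid):
            object.__setattr__(
                self, "tree_grid",
                tuple(t for t in self.tree_grid if t <= self.max_trees),
            )
        if any(c <= 0 for c in self.svm_C_grid) or any(g <= 0 for g in self.svm_gamma_grid):
            raise ValueError("SVM grids must be positive")

    def mlp_hidden_range(self, j: int) -> range:
        """Hidden-layer sizes explored for j inputs: j .. 2*j + 1."""
        return range(j, 2 * j + 2)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = raw.get("train", raw)
        kwargs = {}
        for f_ in (
            "split_fraction", "rng_seed", "max_trees", "significance_alpha", "threshold",
        ):
            if f_ in raw:
                kwargs[f_] = raw[f_]
        for f_ in ("tree_grid", "mlp_activations", "svm_C_grid", "svm_gamma_grid"):
            if f_ in raw:
                kwargs[f_] = tuple(raw[f_])
        return cls(**kwargs)
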