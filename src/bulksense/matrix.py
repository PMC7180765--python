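"""Method-selection matrices over cost-level cells with feasibility masks.

Candidate predictor combinations are binned by their cost levels
(f(delta), f(lambda)) — the realized levels with the default 1/2/3
weights are {0, 1/6, ..., 6/6} on each side.  Per cell the winning
classifier family from a fit table is recorded; a "logit preferred"
mode overrides the winner with LR-VG (logistic, both SENS and SPEC
> 0.8) or LR-EX (> 0.9) where the logistic model qualifies.  Duration
and controllability constraints mask cells: a cell is infeasible (X)
only when *every* combination it contains violates the active
constraint.  Rows index f(delta), columns f(lambda); the printed-layout
writer transposes so quality cost levels run across columns under their
duration header.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from . import weights as W
from .bench import SIMPLICITY_ORDER, _family_key, _row_family_metrics, FAMILIES
from .types import VariableSet, WeightConfig, WeightVector

__all__ = [
    "Cell",
    "SelectionMatrix",
    "build_case_matrix",
    "build_method_matrix",
    "apply_feasibility",
    "INFEASIBLE",
]

INFEASIBLE = "X"


def _levels(costs: dict[str, int]) -> list[Fraction]:
    """All cost fractions achievable by subsets of the configured weights."""
    total = sum(costs.values())
    sums = {0}
    for k in costs.values():
        sums |= {s + k for s in sums}
    return sorted(Fraction(s, total) for s in sums)


@dataclass
class Cell:
    """One (f(delta), f(lambda)) cell of a selection matrix."""

    combos: list[str] = field(default_factory=list)
    weight_vectors: dict[str, WeightVector] = field(default_factory=dict)
    method: str | None = None
    per_combo_method: dict[str, str] = field(default_factory=dict)
    mask_ft: int = 1  # 1 = feasible under the duration constraint
    mask_fs: int = 1  # 1 = feasible under the controllability constraint

    @property
    def mask(self) -> int:
        """Overall feasibility: product of the constraint components."""
        return self.mask_ft * self.mask_fs

    def display(self) -> str:
        if self.mask == 0:
            return INFEASIBLE
        if self.method is not None:
            return self.method
        return "-" if self.combos else INFEASIBLE


@dataclass
class SelectionMatrix:
    row_levels: list[Fraction]  # f(delta)
    col_levels: list[Fraction]  # f(lambda)
    cells: dict[tuple[Fraction, Fraction], Cell]

    def cell(self, f_delta, f_lambda) -> Cell:
        return self.cells[(Fraction(f_delta), Fraction(f_lambda))]

    def to_frame(self) -> pd.DataFrame:
        """Method grid, rows f(delta) x columns f(lambda), X where infeasible."""
        data = {
            str(c): [self.cells[(r, c)].display() for r in self.row_levels]
            for c in self.col_levels
        }
        return pd.DataFrame(data, index=[str(r) for r in self.row_levels])

    def to_printed_frame(self, cfg: WeightConfig | None = None) -> pd.DataFrame:
        """Transposed layout: quality cost levels as columns, with an
        f(t) header row marking levels only reachable through a
        long-duration indicator."""
        cfg = cfg or WeightConfig()
        frame = self.to_frame().T  # rows f(lambda), columns f(delta)
        header = [str(_level_ft(Fraction(c), cfg)) for c in frame.columns]
        frame = pd.concat(
            [pd.DataFrame([header], columns=frame.columns, index=["f(t)"]), frame]
        )
        return frame

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown()

    def to_csv(self, path) -> None:
        rows = []
        for (r, c), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "f_delta": str(r),
                    "f_lambda": str(c),
                    "method": cell.method if cell.method is not None else "",
                    "combos": ";".join(cell.combos),
                    "mask_ft": cell.mask_ft,
                    "mask_fs": cell.mask_fs,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SelectionMatrix":
        df = pd.read_csv(path, keep_default_na=False)
        cells: dict[tuple[Fraction, Fraction], Cell] = {}
        for _, row in df.iterrows():
            key = (Fraction(row["f_delta"]), Fraction(row["f_lambda"]))
            combos = [c for c in str(row["combos"]).split(";") if c]
            cells[key] = Cell(
                combos=combos,
                method=row["method"] or None,
                mask_ft=int(row["mask_ft"]),
                mask_fs=int(row["mask_fs"]),
            )
        rows = sorted({k[0] for k in cells})
        cols = sorted({k[1] for k in cells})
        return cls(rows, cols, cells)

    def __eq__(self, other) -> bool:  # structural equality for round-trips
        if not isinstance(other, SelectionMatrix):
            return NotImplemented
        if (self.row_levels, self.col_levels) != (other.row_levels, other.col_levels):
            return False
        for key, cell in self.cells.items():
            o = other.cells.get(key)
            if o is None:
                return False
            if (cell.combos, cell.method, cell.mask_ft, cell.mask_fs) != (
                o.combos, o.method, o.mask_ft, o.mask_fs
            ):
                return False
        return True


def _level_ft(f_delta_level: Fraction, cfg: WeightConfig) -> int:
    """1 if every quality subset achieving this cost level carries the
    duration penalty, else 0 (level 0 — no indicators — is 0)."""
    names = sorted(cfg.quality_costs)
    total = sum(cfg.quality_costs.values())
    achieving = []
    for bits in range(2 ** len(names)):
        subset = [names[i] for i in range(len(names)) if bits >> i & 1]
        if Fraction(sum(cfg.quality_costs[n] for n in subset), total) == f_delta_level:
            achieving.append(subset)
    if not achieving:
        return 0
    flags = [
        any(
            cfg.duration_flags.get(n, 0) == 1 and n not in cfg.modelled_indicators
            for n in subset
        )
        for subset in achieving
    ]
    return int(all(flags))


def _empty_matrix(cfg: WeightConfig) -> SelectionMatrix:
    rows = _levels(dict(cfg.quality_costs))
    cols = _levels(dict(cfg.operational_costs))
    cells = {(r, c): Cell() for r in rows for c in cols}
    return SelectionMatrix(rows, cols, cells)


def build_case_matrix(
    combinations: Sequence[VariableSet], cfg: WeightConfig | None = None
) -> SelectionMatrix:
    """Bin combinations into (f(delta), f(lambda)) cells with their
    weight vectors; cells may hold several combinations."""
    cfg = cfg or WeightConfig()
    mat = _empty_matrix(cfg)
    for vset in combinations:
        wv = W.w_tot(vset, cfg)
        key = (wv.f_delta, wv.f_lambda)
        cell = mat.cells[key]
        label = vset.label() if vset.members else "(empty)"
        cell.combos.append(label)
        cell.weight_vectors[label] = wv
    return mat


def build_method_matrix(
    fit_table: pd.DataFrame,
    cfg: WeightConfig | None = None,
    mode: str = "best",
    families: Sequence[str] = FAMILIES,
    lag: int = 1,
) -> SelectionMatrix:
    """Selection matrix from a fit table.

    mode="best": per cell, the family maximizing min(SENS, SPEC) over
    the union of the cell's fit rows (ties by SENS+SPEC, then the fixed
    simplicity order).  mode="logit_preferred": the cell becomes LR-EX
    when the logistic model reaches SENS and SPEC > 0.9 in some row of
    the cell, LR-VG when > 0.8, and otherwise falls back to the best
    mode.  Cells no combination occupies are infeasible (X).
    """
    if mode not in ("best", "logit_preferred"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or WeightConfig()
    combos = [VariableSet.from_string(c, lag=lag) for c in fit_table["combo"]]
    mat = build_case_matrix(combos, cfg)

    # fit tables may list members in any order; key rows by the canonical label
    by_label = {
        VariableSet.from_string(row["combo"], lag=lag).label(): row
        for _, row in fit_table.iterrows()
    }
    for cell in mat.cells.values():
        if not cell.combos:
            continue
        scored = []
        lr_best: tuple[float, float] | None = None
        for label in cell.combos:
            row = by_label[label]
            for fam, se, sp in _row_family_metrics(row, families):
                scored.append((-min(se, sp), -(se + sp), _family_key(fam), fam, label))
                if fam == "LR":
                    if lr_best is None or min(se, sp) > min(lr_best):
                        lr_best = (se, sp)
        if not scored:
            continue
        scored.sort()
        best_fam = scored[0][3]
        for label in cell.combos:
            row_scores = [s for s in scored if s[4] == label]
            cell.per_combo_method[label] = min(row_scores)[3] if row_scores else ""
        cell.method = best_fam
        if mode == "logit_preferred" and lr_best is not None:
            se, sp = lr_best
            if se > 0.9 and sp > 0.9:
                cell.method = "LR-EX"
            elif se > 0.8 and sp > 0.8:
                cell.method = "LR-VG"
    return mat


def apply_feasibility(
    matrix: SelectionMatrix,
    cfg: WeightConfig | None = None,
    use_ft: bool = False,
    use_FS: bool = False,
    lag: int = 1,
) -> SelectionMatrix:
    """Mask cells whose every combination violates an active constraint.

    The duration constraint (use_ft) masks a cell when all its members
    have f(t) = 1; the controllability constraint (use_FS) when all have
    F(S) = 1.  Masking is monotone: enabling a constraint never unmasks.
    """
    cfg = cfg or WeightConfig()
    out = copy.deepcopy(matrix)
    for cell in out.cells.values():
        if not cell.combos:
            continue
        vsets = {
            label: VariableSet.from_string(label, lag=lag)
            for label in cell.combos
            if label != "(empty)"
        }
        # the empty combination has f(t)=0 but F(S)=1
        fts = [W.f_t(v, cfg) for v in vsets.values()] + (
            [0] if "(empty)" in cell.combos else []
        )
        fss = [W.F_S(v, cfg) for v in vsets.values()] + (
            [1] if "(empty)" in cell.combos else []
        )
        if use_ft and fts and all(f == 1 for f in fts):
            cell.mask_ft = 0
        if use_FS and fss and all(f == 1 for f in fss):
            cell.mask_fs = 0
    return out
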