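"""Cascaded ANFIS: pair selection, level-wise training, and booster fusion.

A cascade chains two-input Sugeno units in levels.  At each level every
input variable is matched with its best partner by exhaustive screening:
each unordered pair of current inputs gets a fresh unit trained for a small
number of hybrid passes, and the pair with the lowest screening RMSE wins
for each input.  The chosen units are trained fully, their outputs become
the next level's inputs, and the process repeats until a unit reaches the
target error, the level cap is hit, or a single unit remains.

The fusion variant fixes the structure instead of screening: three scalar
base-classifier outputs enter a two-level cascade whose first level holds
units for the pre-assigned pairs (booster1, booster2) and (booster2,
booster3), and whose second level combines the two level-1 outputs.  Class
labels are encoded as integer scalars for training and decoded by
nearest-code rounding at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .anfis import (
    AnfisUnit,
    TrainReport,
    forward_batch,
    init_unit,
    train_hybrid,
    unit_from_json,
    unit_to_json,
)

__all__ = [
    "PairSelectionResult",
    "CascadeModel",
    "FusionModel",
    "select_pairs",
    "train_cascade",
    "train_fusion",
    "predict_fusion",
]


@dataclass
class PairSelectionResult:
    """Matched input pairs and the screening RMSE of every candidate pair."""

    pairs: list          # distinct unordered pairs, as sorted (i, j) tuples
    screening_rmse: dict  # {(i, j): rmse} for every candidate pair evaluated


def _column_range(col: np.ndarray) -> tuple[float, float]:
    return float(col.min()), float(col.max())


def _fit_pair(
    X: np.ndarray,
    y: np.ndarray,
    i: int,
    j: int,
    iterations: int,
    target_error: float = 0.0,
    learning_rate: float = 0.01,
) -> tuple[AnfisUnit, TrainReport]:
    sub = X[:, [i, j]]
    unit = init_unit(_column_range(sub[:, 0]), _column_range(sub[:, 1]))
    return train_hybrid(
        unit, sub, y,
        iterations=iterations,
        target_error=target_error,
        learning_rate=learning_rate,
    )


def select_pairs(X, y, screening_iterations: int = 1) -> PairSelectionResult:
    """Exhaustive pair screening: best partner per input by lowest RMSE.

    Every unordered pair (i, j) is fitted for ``screening_iterations``
    hybrid passes; input i's matched pair is its lowest-RMSE pair.
    Duplicate unordered pairs are reported once.  Fully deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    d = X.shape[1]
    if d < 2:
        raise ValueError("pair selection needs at least 2 inputs")
    rmse: dict[tuple[int, int], float] = {}
    for i in range(d):
        for j in range(i + 1, d):
            _, rep = _fit_pair(X, y, i, j, iterations=screening_iterations)
            rmse[(i, j)] = min(rep.rmse_history)
    pairs: list[tuple[int, int]] = []
    for i in range(d):
        candidates = [(r, pr) for pr, r in rmse.items() if i in pr]
        # ties break on the lexicographically smallest pair
        best = min(candidates, key=lambda t: (t[0], t[1]))[1]
        if best not in pairs:
            pairs.append(best)
    return PairSelectionResult(pairs=pairs, screening_rmse=rmse)


@dataclass
class CascadeModel:
    """Levels of (pair, unit); the final unit's output is the model output.

    ``levels[l]`` is a list of ((i, j), AnfisUnit) where the indices refer
    to the previous level's outputs (level 0 indexes the raw input
    columns).  ``class_codes`` is empty for regression.
    """

    levels: list
    target_error: float
    class_codes: list = field(default_factory=list)
    reports: list = field(default_factory=list)  # TrainReport per unit, same shape

    @property
    def final_unit(self) -> AnfisUnit:
        return self.levels[-1][0][1]

    def forward(self, X) -> np.ndarray:
        """Continuous cascade output for an (n, d) input array."""
        current = np.asarray(X, dtype=np.float64)
        if current.ndim == 1:
            current = current[None, :]
        for level in self.levels:
            outs = [
                forward_batch(unit, current[:, i], current[:, j])
                for (i, j), unit in level
            ]
            current = np.column_stack(outs)
        return current[:, 0]


def train_cascade(
    X,
    y,
    target_error: float,
    max_levels: int = 10,
    unit_iterations: int = 100,
    screening_iterations: int = 1,
    learning_rate: float = 0.01,
) -> CascadeModel:
    """Level-wise cascade construction with pair screening.

    Level 1 consumes X's columns; each later level consumes the previous
    level's unit outputs.  Construction stops when the best unit reaches
    ``target_error``, ``max_levels`` is hit, or only one unit remains; the
    final level is then reduced to its best-RMSE unit, whose output is the
    model output.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    model = CascadeModel(levels=[], target_error=float(target_error))
    current = X
    for level_idx in range(max_levels):
        sel = select_pairs(current, y, screening_iterations)
        level, reports, outputs = [], [], []
        for pair in sel.pairs:
            unit, rep = _fit_pair(
                current, y, *pair,
                iterations=unit_iterations,
                target_error=target_error,
                learning_rate=learning_rate,
            )
            out = forward_batch(unit, current[:, pair[0]], current[:, pair[1]])
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(
                    f"non-finite unit output at cascade level {level_idx + 1}"
                )
            level.append((pair, unit))
            reports.append(rep)
            outputs.append(out)
        model.levels.append(level)
        model.reports.append(reports)
        best_idx = int(np.argmin([min(r.rmse_history) for r in reports]))
        best_rmse = min(reports[best_idx].rmse_history)
        done = (
            best_rmse <= target_error
            or len(level) == 1
            or level_idx == max_levels - 1
        )
        if done:
            # reduce the last level to its best unit: the model output
            model.levels[-1] = [level[best_idx]]
            model.reports[-1] = [reports[best_idx]]
            break
        current = np.column_stack(outputs)
    return model


# ---------------------------------------------------------------------------
# booster fusion: the fixed two-level structure
# ---------------------------------------------------------------------------

FUSION_PAIRS = [(0, 1), (1, 2)]  # (booster1, booster2), (booster2, booster3)


@dataclass
class FusionModel(CascadeModel):
    """Two-level cascade over three base-classifier outputs, fixed pairs."""

    def predict(self, booster_preds) -> np.ndarray:
        return predict_fusion_batch(self, booster_preds)


def encode_classes(labels, class_codes) -> np.ndarray:
    """Class labels -> scalar targets (their integer code values)."""
    codes = np.asarray(class_codes)
    label_arr = np.asarray(labels)
    pos = {c: k for k, c in enumerate(codes.tolist())}
    try:
        idx = np.array([pos[v] for v in label_arr.tolist()])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class_codes") from exc
    return codes[idx].astype(np.float64)


def train_fusion(
    booster_preds,
    y_class,
    class_codes,
    unit_iterations: int = 100,
    target_error: float = 0.0,
    learning_rate: float = 0.01,
) -> FusionModel:
    """Train the two-level fusion on three base-classifier output columns.

    Columns must be ordered (booster1, booster2, booster3); level 1 trains
    the pre-assigned pairs (1,2) and (2,3) against the scalar-encoded class
    target, level 2 trains one unit on the two level-1 outputs.  Input
    ranges of the level-2 unit are re-estimated from the level-1 outputs.
    """
    P = np.asarray(booster_preds, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("booster_preds must be n x 3")
    class_codes = list(class_codes)
    present = set(np.asarray(y_class).tolist())
    missing = [c for c in class_codes if c not in present]
    if missing:
        warnings.warn(f"classes absent from training data: {missing}")
    y = encode_classes(y_class, class_codes)

    model = FusionModel(
        levels=[], target_error=float(target_error), class_codes=class_codes
    )
    level1, reports1, outs = [], [], []
    for pair in FUSION_PAIRS:
        unit, rep = _fit_pair(
            P, y, *pair,
            iterations=unit_iterations,
            target_error=target_error,
            learning_rate=learning_rate,
        )
        level1.append((pair, unit))
        reports1.append(rep)
        outs.append(forward_batch(unit, P[:, pair[0]], P[:, pair[1]]))
    model.levels.append(level1)
    model.reports.append(reports1)

    Z = np.column_stack(outs)
    unit2, rep2 = _fit_pair(
        Z, y, 0, 1,
        iterations=unit_iterations,
        target_error=target_error,
        learning_rate=learning_rate,
    )
    model.levels.append([((0, 1), unit2)])
    model.reports.append([rep2])
    return model


def decode_to_class(values, class_codes) -> np.ndarray:
    """Continuous outputs -> nearest class code (ties to the lower index)."""
    codes = np.asarray(class_codes, dtype=np.float64)
    v = np.atleast_1d(np.asarray(values, dtype=np.float64))
    dist = np.abs(v[:, None] - codes[None, :])
    # argmin takes the first minimum, i.e. the lower index on ties
    idx = dist.argmin(axis=1)
    return np.asarray(class_codes)[idx]


def predict_fusion_batch(model: FusionModel, booster_preds) -> np.ndarray:
    cont = model.forward(np.asarray(booster_preds, dtype=np.float64))
    return decode_to_class(cont, model.class_codes)


def predict_fusion(model: FusionModel, booster_preds_row):
    """Single-row prediction -> class code."""
    return predict_fusion_batch(model, np.asarray(booster_preds_row)[None, :])[0]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def cascade_to_json(model: CascadeModel) -> dict:
    return {
        "kind": "fusion" if isinstance(model, FusionModel) else "cascade",
        "target_error": model.target_error,
        "class_codes": [int(c) if isinstance(c, (int, np.integer)) else c
                        for c in model.class_codes],
        "levels": [
            [{"pair": list(pair), "unit": unit_to_json(unit)} for pair, unit in level]
            for level in model.levels
        ],
    }


def cascade_from_json(obj: dict) -> CascadeModel:
    cls = FusionModel if obj.get("kind") == "fusion" else CascadeModel
    model = cls(levels=[], target_error=obj["target_error"],
                class_codes=list(obj.get("class_codes", [])))
    for level in obj["levels"]:
        model.levels.append(
            [(tuple(e["pair"]), unit_from_json(e["unit"])) for e in level]
        )
    return model


def save_cascade(model: CascadeModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(cascade_to_json(model), fh)


def load_cascade(path) -> CascadeModel:
    with open(path) as fh:
        return cascade_from_json(json.load(fh))
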