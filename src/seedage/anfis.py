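"""Two-input first-order Sugeno ANFIS with hybrid learning.

The unit is a five-layer adaptive network: Gaussian memberships (layer 1),
product-rule firing strengths (layer 2), normalization (layer 3), linear
consequents weighted by the normalized firings (layer 4) and their sum
(layer 5).  Each input carries 3 Gaussian membership functions, giving the
full 3 x 3 = 9 rule grid; rule k = 3*i + j combines MF i of input 1 with MF
j of input 2, and its consequent is f_k = p_k*x1 + q_k*x2 + r_k.

Training alternates the classic hybrid passes: the consequent coefficients
are the solution of a linear least-squares problem given fixed premises
(forward pass), and the premise centers/widths take one full-batch gradient
descent step on the squared error given fixed consequents (backward pass).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

N_MFS = 3          # Gaussian MFs per input
N_RULES = N_MFS * N_MFS
SIGMA_FLOOR = 1e-8
RIDGE_LAMBDA = 1e-6

__all__ = [
    "AnfisUnit",
    "TrainReport",
    "init_unit",
    "forward",
    "lse_consequents",
    "gd_premise",
    "train_hybrid",
    "unit_to_json",
    "unit_from_json",
]


@dataclass
class AnfisUnit:
    """Parameters of one two-input one-output Sugeno fuzzy unit.

    centers/sigmas: shape (2, 3) — row 0 for input 1, row 1 for input 2.
    coeffs: shape (9, 3) — columns are (p, q, r) of each rule's consequent.
    input_ranges: (2, 2) — the (min, max) per input recorded at init time.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    coeffs: np.ndarray
    input_ranges: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(2, N_MFS)
        self.sigmas = np.asarray(self.sigmas, dtype=np.float64).reshape(2, N_MFS)
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).reshape(N_RULES, 3)
        self.input_ranges = np.asarray(self.input_ranges, dtype=np.float64).reshape(2, 2)
        if (self.sigmas <= SIGMA_FLOOR / 2).any():
            raise ValueError("sigma below floor")

    def copy(self) -> "AnfisUnit":
        return AnfisUnit(
            self.centers.copy(),
            self.sigmas.copy(),
            self.coeffs.copy(),
            self.input_ranges.copy(),
        )


@dataclass
class TrainReport:
    """RMSE trajectory of a hybrid-learning run (one entry per LSE pass)."""

    rmse_history: list = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def init_unit(x1_range, x2_range) -> AnfisUnit:
    """Grid-partition initialization over the recorded input ranges.

    3 centers equally spaced over each [min, max]; sigma = spacing / 2;
    all consequents zero.  A degenerate range (max == min) is widened by
    1e-6 with a warning.
    """
    ranges = []
    for r in (x1_range, x2_range):
        lo, hi = float(r[0]), float(r[1])
        if hi < lo:
            raise ValueError(f"range ({lo}, {hi}) has max < min")
        if hi == lo:
            warnings.warn(f"degenerate input range ({lo}, {hi}); widening by 1e-6")
            lo -= 5e-7
            hi += 5e-7
        ranges.append((lo, hi))
    centers = np.array([np.linspace(lo, hi, N_MFS) for lo, hi in ranges])
    spacing = np.array([(hi - lo) / (N_MFS - 1) for lo, hi in ranges])
    sigmas = np.repeat(spacing[:, None] / 2.0, N_MFS, axis=1)
    return AnfisUnit(centers, sigmas, np.zeros((N_RULES, 3)), np.array(ranges))


def _memberships(unit: AnfisUnit, x1: np.ndarray, x2: np.ndarray):
    mu1 = np.exp(-((x1[:, None] - unit.centers[0]) ** 2) / (2 * unit.sigmas[0] ** 2))
    mu2 = np.exp(-((x2[:, None] - unit.centers[1]) ** 2) / (2 * unit.sigmas[1] ** 2))
    return mu1, mu2


def _firings(unit: AnfisUnit, x1: np.ndarray, x2: np.ndarray):
    """Raw and normalized rule firing strengths, with underflow fallback.

    Returns (w, wbar, wsum, underflow_mask); rows whose total firing
    underflows to 0 get the uniform wbar = 1/9 so the forward pass stays
    defined far outside the training range.
    """
    mu1, mu2 = _memberships(unit, x1, x2)
    w = (mu1[:, :, None] * mu2[:, None, :]).reshape(len(x1), N_RULES)
    wsum = w.sum(axis=1)
    under = wsum == 0.0
    if under.any():
        warnings.warn(f"{int(under.sum())} sample(s) with zero total firing; "
                      "using uniform normalized firings")
    wbar = np.empty_like(w)
    ok = ~under
    wbar[ok] = w[ok] / wsum[ok, None]
    wbar[under] = 1.0 / N_RULES
    return w, wbar, wsum, under


def _consequent_values(unit: AnfisUnit, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    p, q, r = unit.coeffs[:, 0], unit.coeffs[:, 1], unit.coeffs[:, 2]
    return x1[:, None] * p + x2[:, None] * q + r


def forward_batch(unit: AnfisUnit, x1, x2) -> np.ndarray:
    """Layer-5 outputs for arrays of inputs."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
    x2 = np.atleast_1d(np.asarray(x2, dtype=np.float64))
    _, wbar, _, _ = _firings(unit, x1, x2)
    return (wbar * _consequent_values(unit, x1, x2)).sum(axis=1)


def forward(unit: AnfisUnit, x1: float, x2: float):
    """Single-sample forward pass -> (output, normalized firings (9,))."""
    x1a = np.array([float(x1)])
    x2a = np.array([float(x2)])
    _, wbar, _, _ = _firings(unit, x1a, x2a)
    out = (wbar * _consequent_values(unit, x1a, x2a)).sum(axis=1)
    return float(out[0]), wbar[0]


def _design_matrix(wbar: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n = len(x1)
    A = np.empty((n, N_RULES * 3))
    A[:, 0::3] = wbar * x1[:, None]
    A[:, 1::3] = wbar * x2[:, None]
    A[:, 2::3] = wbar
    return A


def lse_consequents(unit: AnfisUnit, X, y) -> AnfisUnit:
    """Least-squares estimate of all 27 consequent coefficients.

    Solves min ||A theta - y|| with premises fixed; a rank-deficient or
    underdetermined system falls back to ridge (lambda = 1e-6) with a
    warning.  Returns an updated copy.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    x1, x2 = X[:, 0], X[:, 1]
    _, wbar, _, _ = _firings(unit, x1, x2)
    A = _design_matrix(wbar, x1, x2)
    ncols = A.shape[1]
    theta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < ncols:
        warnings.warn(
            f"rank-deficient consequent system (rank {rank} < {ncols}); "
            f"ridge fallback lambda={RIDGE_LAMBDA}"
        )
        theta = np.linalg.solve(
            A.T @ A + RIDGE_LAMBDA * np.eye(ncols), A.T @ y
        )
    out = unit.copy()
    out.coeffs = theta.reshape(N_RULES, 3)
    return out


def gd_premise(unit: AnfisUnit, X, y, learning_rate: float) -> AnfisUnit:
    """One full-batch gradient-descent step on the premise parameters.

    Minimizes E = 1/2 sum e_t^2 with e = output - target, differentiating
    through the firing normalization; consequents stay fixed.  Sigmas are
    clamped at the positivity floor after the step.
    """
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    x1, x2 = X[:, 0], X[:, 1]
    w, wbar, wsum, under = _firings(unit, x1, x2)
    f = _consequent_values(unit, x1, x2)
    out = (wbar * f).sum(axis=1)
    e = out - y
    # dE/dw_k = e * (f_k - out) / wsum; underflow rows contribute nothing
    # (their wbar is the constant uniform fallback).
    G = np.zeros_like(w)
    ok = ~under
    G[ok] = (e[ok] * 1.0)[:, None] * (f[ok] - out[ok, None]) * w[ok] / wsum[ok, None]
    G3 = G.reshape(len(x1), N_MFS, N_MFS)
    G1 = G3.sum(axis=2)  # (n, 3): accumulated over rules sharing MF i of input 1
    G2 = G3.sum(axis=1)  # (n, 3): accumulated over rules sharing MF j of input 2
    out_unit = unit.copy()
    for axis, (xv, Gax) in enumerate(((x1, G1), (x2, G2))):
        c = unit.centers[axis]
        s = unit.sigmas[axis]
        d = xv[:, None] - c  # (n, 3)
        grad_c = (Gax * d / s**2).sum(axis=0)
        grad_s = (Gax * d**2 / s**3).sum(axis=0)
        out_unit.centers[axis] = c - learning_rate * grad_c
        out_unit.sigmas[axis] = np.maximum(s - learning_rate * grad_s, SIGMA_FLOOR)
    return out_unit


def _rmse(unit: AnfisUnit, X, y) -> float:
    pred = forward_batch(unit, X[:, 0], X[:, 1])
    return float(np.sqrt(np.mean((pred - np.asarray(y).ravel()) ** 2)))


def train_hybrid(
    unit: AnfisUnit,
    X,
    y,
    iterations: int = 100,
    target_error: float = 0.0,
    learning_rate: float = 0.01,
):
    """Alternate LSE (consequents) and GD (premises) passes.

    RMSE is recorded immediately after each LSE pass; training stops early
    once it reaches ``target_error``.  The parameters returned are the best
    (lowest recorded RMSE) seen, guarding against a GD overshoot on the
    final iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    report = TrainReport()
    best_rmse = np.inf
    best_unit = unit.copy()
    current = unit
    for it in range(iterations):
        current = lse_consequents(current, X, y)
        rmse = _rmse(current, X, y)
        if not np.isfinite(rmse):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it + 1}"
            )
        report.rmse_history.append(rmse)
        report.iterations_run = it + 1
        if rmse < best_rmse:
            best_rmse = rmse
            best_unit = current.copy()
        if rmse <= target_error:
            report.converged = True
            break
        if it < iterations - 1:
            current = gd_premise(current, X, y, learning_rate)
    return best_unit, report


# ---------------------------------------------------------------------------
# serialization — plain JSON, exact float round trip via repr
# ---------------------------------------------------------------------------

def unit_to_json(unit: AnfisUnit) -> dict:
    return {
        "mfs": [
            [{"c": c, "sigma": s} for c, s in zip(unit.centers[i], unit.sigmas[i])]
            for i in range(2)
        ],
        "rules": [
            {"p": p, "q": q, "r": r} for p, q, r in unit.coeffs
        ],
        "input_ranges": unit.input_ranges.tolist(),
    }


def unit_from_json(obj: dict) -> AnfisUnit:
    centers = np.array([[mf["c"] for mf in row] for row in obj["mfs"]])
    sigmas = np.array([[mf["sigma"] for mf in row] for row in obj["mfs"]])
    coeffs = np.array([[r["p"], r["q"], r["r"]] for r in obj["rules"]])
    return AnfisUnit(centers, sigmas, coeffs, np.array(obj["input_ranges"]))


def save_unit(unit: AnfisUnit, path) -> None:
    with open(path, "w") as fh:
        json.dump(unit_to_json(unit), fh)


def load_unit(path) -> AnfisUnit:
    with open(path) as fh:
        return unit_from_json(json.load(fh))
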