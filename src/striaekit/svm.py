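"""Linear-kernel support vector machine for severity classification.

The classifier solves the standard maximal-margin problem: a separating
hyperplane ``w . x + b = 0`` is found by maximizing the dual

    Q(alpha) = sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j (x_i . x_j)

subject to ``sum_i alpha_i y_i = 0`` and ``0 <= alpha_i <= C`` (soft-margin
box; hard margin as C grows).  The weight vector is recovered as
``w = sum_i alpha_i y_i x_i`` and the bias from the support-vector condition
``y_i (w . x_i + b) = 1``, averaged over unbounded support vectors.

The dual is solved in-package with SMO-style pairwise updates (deterministic
working-set choice, no randomness), which keeps the optimizer transparent
and easy to check against a brute-force quadratic program on small problems
(:func:`solve_dual_qp`).  Three severity classes are handled one-vs-rest:
the class whose binary machine reports the largest decision value wins, with
ties broken by the fixed class order mild < moderate < severe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConvergenceError",
    "CLASS_ORDER",
    "ABLATION_SUBSETS",
    "BinaryLinearSVM",
    "OneVsRestSVM",
    "EvalReport",
    "solve_dual_qp",
    "stratified_split",
    "evaluate",
    "ablation_study",
]

CLASS_ORDER = ("mild", "moderate", "severe")

#: The five feature-subset ablation rows: three 3-feature combinations around
#: color difference, the 4 photo-only features, and all five with elasticity.
ABLATION_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("C", "W", "A"),
    ("C", "D", "A"),
    ("C", "D", "W"),
    ("C", "D", "W", "A"),
    ("C", "D", "W", "A", "E"),
)


class ConvergenceError(RuntimeError):
    """Raised when the dual solver fails to converge within its budget."""


def _class_key(label: str):
    try:
        return (0, CLASS_ORDER.index(label))
    except ValueError:
        return (1, label)


def _smo_solve(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float]:
    """Solve the dual by deterministic pairwise (SMO) updates.

    Each iteration optimizes one pair of multipliers analytically on its
    feasible segment.  The first index is the most violating one among those
    still allowed to move up (``alpha < C`` on the positive side, ``alpha >
    0`` on the negative side); the partner is chosen by the second-order
    rule — the down-movable index giving the largest guaranteed objective
    gain — which avoids the slow tail of purely first-order pair selection.
    The solver stops when the KKT gap falls below ``tol``.  Returns the
    multipliers ``alpha`` and the bias.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_iter is None:
        max_iter = 50_000 + 500 * n
    alpha = np.zeros(n)
    g = -y.copy()  # G_i = f(x_i) - y_i with f = 0 initially (bias-free)
    diag = np.diag(K).copy()

    pos = y > 0
    q_prev = -np.inf
    stationary = False
    for it_count in range(max_iter):
        if it_count and it_count % 2000 == 0:
            # refresh the incrementally-updated gradient: float drift over
            # many pair updates can otherwise keep the KKT gap from closing
            g = K @ (alpha * y) - y
            # dual objective Q = sum(alpha) - 1/2 v'Kv with v = alpha*y;
            # degenerate problems can crawl toward the optimum with the gap
            # stuck at rounding scale — detect a numerically stationary Q
            v = alpha * y
            q = float(alpha.sum() - 0.5 * v @ (g + y))
            stationary = q - q_prev <= 1e-8 * (1.0 + abs(q))
            q_prev = q
        up = (pos & (alpha < C)) | (~pos & (alpha > 0))
        down = (~pos & (alpha < C)) | (pos & (alpha > 0))
        if not up.any() or not down.any():
            break
        i = int(np.argmin(np.where(up, g, np.inf)))
        gap = float(np.where(down, g, -np.inf).max()) - g[i]
        if gap < tol:  # KKT gap closed
            break
        if stationary:
            if gap < 1e-3:  # at the numerical floor; the iterate is optimal
                break
            raise ConvergenceError(
                f"SMO stalled with KKT gap {gap:.2e} after {it_count} iterations"
            )
        # second-order partner: maximal gain b^2 / a over violating down-set
        bvec = g - g[i]
        avec = np.maximum(diag[i] + diag - 2.0 * K[:, i], 1e-12)
        gain = np.where(down & (bvec > 0), bvec * bvec / avec, -np.inf)
        j = int(np.argmax(gain))
        yi, yj = y[i], y[j]
        s = yi * yj
        ai, aj = alpha[i], alpha[j]
        if s < 0:
            lo, hi = max(0.0, aj - ai), min(C, C + aj - ai)
        else:
            lo, hi = max(0.0, ai + aj - C), min(C, ai + aj)
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta > 0.0:
            aj_new = float(np.clip(aj + yj * (g[i] - g[j]) / eta, lo, hi))
        else:
            # flat direction (duplicate points): move to the better endpoint
            aj_new = hi if yj * (g[i] - g[j]) > 0 else lo
        if aj_new == aj:
            break  # no feasible progress on the worst pair: done
        ai_new = ai + s * (aj - aj_new)
        # snap to the exact box bounds so roundoff residue cannot corrupt the
        # working-set membership on later iterations
        if ai_new < 1e-12:
            ai_new = 0.0
        elif ai_new > C - 1e-12:
            ai_new = C
        if aj_new < 1e-12:
            aj_new = 0.0
        elif aj_new > C - 1e-12:
            aj_new = C
        di, dj = yi * (ai_new - ai), yj * (aj_new - aj)
        g += di * K[:, i] + dj * K[:, j]
        alpha[i], alpha[j] = ai_new, aj_new
    else:
        raise ConvergenceError(f"SMO did not converge within {max_iter} iterations")

    unbounded = (alpha > 1e-8) & (alpha < C - 1e-8)
    if unbounded.any():
        b = float(-g[unbounded].mean())  # y_i - f_i averaged over free SVs
    else:
        up = (pos & (alpha < C)) | (~pos & (alpha > 0))
        down = (~pos & (alpha < C)) | (pos & (alpha > 0))
        lo_g = g[up].min() if up.any() else 0.0
        hi_g = g[down].max() if down.any() else 0.0
        b = float(-0.5 * (lo_g + hi_g))
    return alpha, b


def solve_dual_qp(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Brute-force dual solve via a generic constrained quadratic program.

    Reference implementation for small problems only (the production path is
    :class:`BinaryLinearSVM`): maximizes Q(alpha) with scipy's SLSQP under
    the equality constraint ``sum alpha_i y_i = 0`` and box ``[0, C]``, then
    recovers (w, b) the same way.  Returns (w, b).
    """
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    H = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_q(a):
        return 0.5 * a @ H @ a - a.sum()

    def neg_q_grad(a):
        return H @ a - np.ones(n)

    res = minimize(
        neg_q,
        x0=np.full(n, min(C, 1.0) / 2.0),
        jac=neg_q_grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    if not res.success:
        raise ConvergenceError(f"QP reference failed: {res.message}")
    alpha = res.x
    w = (alpha * y) @ X
    unbounded = (alpha > 1e-6) & (alpha < C - 1e-6)
    sv = unbounded if unbounded.any() else alpha > 1e-6
    b = float(np.mean(y[sv] - X[sv] @ w))
    return w, b


@dataclass
class BinaryLinearSVM:
    """One linear-kernel binary machine trained on +/-1 labels."""

    reg_bound: float = 1.0
    tol: float = 1e-6
    max_iter: int | None = None  # default budget scales with problem size
    w: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    b: float = 0.0
    alpha: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    support_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("binary labels must be -1/+1")
        if len(set(y)) < 2:
            raise ValueError("training needs both classes present")
        K = X @ X.T
        alpha, b_smo = _smo_solve(K, y, self.reg_bound, self.tol, self.max_iter)
        self.alpha = alpha
        self.w = (alpha * y) @ X
        self.support_ = np.flatnonzero(alpha > 1e-8)
        unbounded = (alpha > 1e-8) & (alpha < self.reg_bound - 1e-8)
        if unbounded.any():
            # bias from the support-vector condition y_i (w.x_i + b) = 1
            self.b = float(np.mean(y[unbounded] - X[unbounded] @ self.w))
        else:
            self.b = float(b_smo)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b


class OneVsRestSVM:
    """Multiclass severity classifier: one binary machine per class.

    Features are standardized to train-set mean/SD by default (the raw
    features mix pixel widths with [0, 1] ratios).  Prediction takes the
    class with the maximal decision value; exact ties go to the earliest
    class in mild < moderate < severe order.
    """

    def __init__(
        self,
        reg_bound: float = 1.0,
        standardize: bool = True,
        feature_subset: Sequence[str] | None = None,
    ) -> None:
        self.reg_bound = float(reg_bound)
        self.standardize = bool(standardize)
        self.feature_subset = tuple(feature_subset) if feature_subset else None
        self.classes_: tuple[str, ...] = ()
        self.machines_: dict[str, BinaryLinearSVM] = {}
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "OneVsRestSVM":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (photos x features)")
        if np.isnan(X).any():
            raise ValueError("feature matrix contains missing values")
        self.classes_ = tuple(sorted(set(labels.tolist()), key=_class_key))
        if len(self.classes_) < 2:
            raise ValueError("training needs at least two distinct labels")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_
        self.machines_ = {}
        for cls in self.classes_:
            y = np.where(labels == cls, 1.0, -1.0)
            self.machines_[cls] = BinaryLinearSVM(reg_bound=self.reg_bound).fit(Z, y)
        return self

    def _check_arity(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"feature arity mismatch: model expects {self.mean_.shape[0]}, got {X.shape[1]}"
            )
        return X

    def decision_values(self, X: np.ndarray) -> pd.DataFrame:
        X = self._check_arity(X)
        Z = (X - self.mean_) / self.scale_
        return pd.DataFrame(
            {cls: self.machines_[cls].decision_function(Z) for cls in self.classes_}
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        dv = self.decision_values(X)
        # idxmax returns the first (class-order) column on exact ties
        return dv.idxmax(axis=1).to_numpy()

    # -- persistence ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "scheme": "one-vs-rest",
            "kernel": "linear",
            "reg_bound": self.reg_bound,
            "standardize": self.standardize,
            "feature_subset": list(self.feature_subset) if self.feature_subset else None,
            "classes": list(self.classes_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "machines": {
                cls: {
                    "w": m.w.tolist(),
                    "b": m.b,
                    "alpha": m.alpha.tolist(),
                    "support": m.support_.tolist(),
                }
                for cls, m in self.machines_.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "OneVsRestSVM":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        model = cls(
            reg_bound=payload["reg_bound"],
            standardize=payload["standardize"],
            feature_subset=payload["feature_subset"],
        )
        model.classes_ = tuple(payload["classes"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        for cls_name, m in payload["machines"].items():
            machine = BinaryLinearSVM(reg_bound=payload["reg_bound"])
            machine.w = np.asarray(m["w"], dtype=float)
            machine.b = float(m["b"])
            machine.alpha = np.asarray(m["alpha"], dtype=float)
            machine.support_ = np.asarray(m["support"], dtype=int)
            model.machines_[cls_name] = machine
        return model


@dataclass(frozen=True)
class EvalReport:
    """Held-out recognition rate of one trained model."""

    feature_subset: tuple[str, ...]
    recognition_rate: float  # percent, 2 decimals
    n_train: int
    n_test: int
    per_class: Mapping[str, tuple[int, int]]  # label -> (correct, total)


def stratified_split(
    labels: Sequence[str],
    train_fraction: float = 0.8,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split: round(train_fraction * n) to train, rest to test.

    With the rounding rule, class sizes (80, 76, 86) at fraction 0.8 give
    train/test counts (64/16, 61/15, 69/17).  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(set(labels.tolist()), key=_class_key):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 photos")
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def evaluate(
    model: OneVsRestSVM, X_test: np.ndarray, labels_test: Sequence[str], n_train: int = 0
) -> EvalReport:
    """Recognition rate (% correct, 2 decimals) of a model on held-out photos."""
    labels_test = np.asarray(labels_test)
    if len(labels_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    per_class = {}
    for cls in sorted(set(labels_test.tolist()), key=_class_key):
        sel = labels_test == cls
        per_class[cls] = (int((pred[sel] == cls).sum()), int(sel.sum()))
    correct = int((pred == labels_test).sum())
    return EvalReport(
        feature_subset=model.feature_subset or (),
        recognition_rate=round(100.0 * correct / len(labels_test), 2),
        n_train=n_train,
        n_test=len(labels_test),
        per_class=per_class,
    )


def ablation_study(
    features: pd.DataFrame,
    subsets: Sequence[Sequence[str]] = ABLATION_SUBSETS,
    n_repeats: int = 1,
    seed: int = 0,
    reg_bound: float = 1.0,
    train_fraction: float = 0.8,
    standardize: bool = True,
    label_col: str = "label",
) -> tuple[pd.DataFrame, dict[str, list[EvalReport]]]:
    """Recognition rates for feature subsets over repeated stratified splits.

    ``features`` must carry the label column and every feature a subset
    references; rows missing a referenced feature are refused (error), never
    imputed.  The same split seeds are shared across subsets so subset
    comparisons are paired.  Returns a summary table
    (subset, mean_rate, sd_rate, n_repeats, n_photos) and the raw per-repeat
    reports keyed by subset name.
    """
    if label_col not in features.columns:
        raise ValueError(f"missing label column {label_col!r}")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(2**31, size=n_repeats)
    rows, details = [], {}
    for subset in subsets:
        subset = tuple(subset)
        missing = [c for c in subset if c not in features.columns]
        if missing:
            raise ValueError(f"subset references missing features: {missing}")
        sub = features[list(subset) + [label_col]]
        if sub[list(subset)].isna().any().any():
            bad = int(sub[list(subset)].isna().any(axis=1).sum())
            raise ValueError(
                f"{bad} rows lack values for subset {'+'.join(subset)}; "
                "drop them explicitly before the ablation"
            )
        X = sub[list(subset)].to_numpy(dtype=float)
        labels = sub[label_col].to_numpy()
        reports = []
        for r in range(n_repeats):
            tr, te = stratified_split(labels, train_fraction, seed=int(split_seeds[r]))
            model = OneVsRestSVM(
                reg_bound=reg_bound, standardize=standardize, feature_subset=subset
            ).fit(X[tr], labels[tr])
            reports.append(evaluate(model, X[te], labels[te], n_train=len(tr)))
        name = "+".join(subset)
        details[name] = reports
        rates = np.array([rep.recognition_rate for rep in reports])
        rows.append(
            {"subset": name, "mean_rate": round(float(rates.mean()), 2),
             "sd_rate": round(float(rates.std(ddof=1)) if n_repeats > 1 else 0.0, 2),
             "n_repeats": n_repeats, "n_photos": len(labels)}
        )
    return pd.DataFrame(rows), details
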