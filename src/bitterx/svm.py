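"""RBF-kernel SVM training with Platt sigmoid probability calibration.

The classifier is a standard soft-margin SVM with a Gaussian kernel
exp(−γ‖u−v‖²).  Decision values g(x) are mapped to class-membership
probabilities with Platt's sigmoid

    P(y=+1 | g) = 1 / (1 + exp(A·g + B)),

where (A, B) minimize the negative log-likelihood of the training data
against Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t− = 1/(N− + 2).
Because calibration requires decision values independent of their labels,
the sigmoid is fitted on out-of-fold decision values from a stratified
cross-validation, never on in-sample margins.

The fit uses the numerically stable Newton iteration with backtracking
line search (the Lin–Weng–Keerthi formulation), which avoids the overflow
of the naive gradient descent on separable data.

Trained models serialize to a plain-text bundle directory (config, feature
list, per-feature scaling, support vectors, sigmoid parameters) and reload
bit-stably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Optimized hyperparameters of the two deployed models.
BITTERANT_SVM = {"C": 32.0, "gamma": 0.015625}
PAIR_SVM = {"C": 8.0, "gamma": 0.125}


class PlattConvergenceError(RuntimeError):
    pass


@dataclass
class SVMConfig:
    C: float
    gamma: float
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class PlattParams:
    A: float
    B: float


def cv_decision_values(
    X: np.ndarray, y: np.ndarray, config: SVMConfig
) -> np.ndarray:
    """Out-of-fold SVM decision values g_i under stratified, seeded CV.

    Every sample is scored by a model whose training fold excluded it, so
    the decision values are independent of their own labels — the
    precondition for unbiased sigmoid calibration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    g = np.empty(y.size)
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a CV training fold contains a single class; use fewer folds"
            )
        clf = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
        clf.fit(X[train_idx], y[train_idx])
        g[test_idx] = clf.decision_function(X[test_idx])
    return g


def fit_platt(
    g: np.ndarray,
    y: np.ndarray,
    max_iter: int = 200,
    min_step: float = 1e-10,
    sigma: float = 1e-12,
    grad_tol: float = 1e-8,
) -> PlattParams:
    """Fit the sigmoid parameters (A, B) by penalized maximum likelihood.

    Newton iteration with backtracking on the negative log-likelihood,
    evaluated in the overflow-safe branch form.  Converges when the
    per-sample gradient norm falls below ``grad_tol`` (the objective is a
    sum over samples, so the tolerance is scaled by n to stay attainable
    in double precision at any dataset size).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit the sigmoid")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    def objective(a: float, b: float) -> float:
        fapb = g * a + b
        # stable: log(1+exp(-|z|)) + max(z,0) pattern
        pos = fapb >= 0
        val = np.empty_like(fapb)
        val[pos] = t[pos] * fapb[pos] + np.log1p(np.exp(-fapb[pos]))
        val[~pos] = (t[~pos] - 1.0) * fapb[~pos] + np.log1p(np.exp(fapb[~pos]))
        return float(val.sum())

    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))
    fval = objective(A, B)
    for _ in range(max_iter):
        fapb = g * A + B
        pos = fapb >= 0
        p = np.empty_like(fapb)
        q = np.empty_like(fapb)
        ez = np.exp(-np.abs(fapb))
        p[pos] = ez[pos] / (1.0 + ez[pos])
        q[pos] = 1.0 / (1.0 + ez[pos])
        p[~pos] = 1.0 / (1.0 + ez[~pos])
        q[~pos] = ez[~pos] / (1.0 + ez[~pos])
        d1 = t - p
        d2 = p * q
        grad_a = float(np.dot(g, d1))
        grad_b = float(d1.sum())
        grad_norm = max(abs(grad_a), abs(grad_b)) / y.size
        if grad_norm < grad_tol:
            return PlattParams(A=A, B=B)
        h11 = float(np.dot(g * g, d2)) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float(np.dot(g, d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * grad_a - h21 * grad_b) / det
        dB = -(-h21 * grad_a + h11 * grad_b) / det
        gd = grad_a * dA + grad_b * dB
        step = 1.0
        while step >= min_step:
            new_a, new_b = A + step * dA, B + step * dB
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                A, B, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            if grad_norm < 1e-6:  # stalled by float precision at the optimum
                return PlattParams(A=A, B=B)
            raise PlattConvergenceError(
                f"line search failed at f={fval:.6g}, grad=({grad_a:.3g},{grad_b:.3g})"
            )
    raise PlattConvergenceError(
        f"no convergence in {max_iter} iterations; final f={fval:.6g}"
    )


def platt_probability(g: np.ndarray | float, p: PlattParams) -> np.ndarray | float:
    """Overflow-safe evaluation of 1 / (1 + exp(A·g + B))."""
    z = np.asarray(p.A * np.asarray(g, dtype=float) + p.B)
    out = np.where(
        z >= 0,
        np.exp(-np.clip(z, 0, None)) / (1.0 + np.exp(-np.clip(z, 0, None))),
        1.0 / (1.0 + np.exp(np.clip(z, None, 0))),
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class TrainedModel:
    """A fitted RBF-SVM + Platt sigmoid + feature scaling, ready to score.

    The decision function is kept as explicit support-vector data
    (g(x) = Σ α_i K(sv_i, x) + b) so the bundle is plain text and reload
    is bit-stable.
    """

    kind: str  # 'bitterant' or 'pair'
    feature_names: list[str]
    config: SVMConfig
    support_vectors: np.ndarray  # scaled feature space
    dual_coef: np.ndarray
    intercept: float
    platt: PlattParams
    scale_min: np.ndarray
    scale_range: np.ndarray  # max - min, zeros replaced by 1

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scale_min) / self.scale_range

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        Xs = self._scale(X)
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Xs @ self.support_vectors.T
        )
        K = np.exp(-self.config.gamma * np.clip(d2, 0.0, None))
        return K @ self.dual_coef + self.intercept

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(platt_probability(self.decision_values(X), self.platt))


def train_final_model(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    feature_names: list[str],
    kind: str = "bitterant",
) -> TrainedModel:
    """Fit scaling + SVM on all data; calibrate on out-of-fold decisions.

    Features are min-max scaled to [0, 1] on the training data; constant
    features pass through unchanged.  The sigmoid is fitted to
    cross-validated decision values of the same data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names must match X columns")
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    Xs = (X - lo) / rng_

    g_cv = cv_decision_values(Xs, y, config)
    platt = fit_platt(g_cv, y)

    clf = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    clf.fit(Xs, y)
    return TrainedModel(
        kind=kind,
        feature_names=list(feature_names),
        config=config,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        platt=platt,
        scale_min=lo,
        scale_range=rng_,
    )


# ---------------------------------------------------------------------------
# Text bundle serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "C": model.config.C,
        "gamma": model.config.gamma,
        "cv_folds": model.config.cv_folds,
        "seed": model.config.seed,
        "intercept": model.intercept,
        "platt_A": model.platt.A,
        "platt_B": model.platt.B,
        "feature_names": model.feature_names,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(d / "support_vectors.tsv", model.support_vectors, fmt="%.17g", delimiter="\t")
    np.savetxt(d / "dual_coef.tsv", model.dual_coef, fmt="%.17g")
    np.savetxt(
        d / "scaling.tsv",
        np.column_stack([model.scale_min, model.scale_range]),
        fmt="%.17g",
        delimiter="\t",
        header="min\trange",
    )


def load_model(directory: str | Path) -> TrainedModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    sv = np.loadtxt(d / "support_vectors.tsv", delimiter="\t", ndmin=2)
    dual = np.loadtxt(d / "dual_coef.tsv", ndmin=1)
    scaling = np.loadtxt(d / "scaling.tsv", delimiter="\t", ndmin=2)
    return TrainedModel(
        kind=meta["kind"],
        feature_names=list(meta["feature_names"]),
        config=SVMConfig(
            C=meta["C"], gamma=meta["gamma"], cv_folds=meta["cv_folds"], seed=meta["seed"]
        ),
        support_vectors=sv,
        dual_coef=dual,
        intercept=meta["intercept"],
        platt=PlattParams(A=meta["platt_A"], B=meta["platt_B"]),
        scale_min=scaling[:, 0],
        scale_range=scaling[:, 1],
    )
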