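"""Sparse Bayesian logistic regression with automatic relevance determination.

The base classifier (SLR) places an independent zero-mean Gaussian prior on
each weight, w_i ~ N(0, 1/alpha_i), and optimises the per-weight precisions
alpha_i by evidence (type-II likelihood) maximisation under a Laplace
approximation.  The inner loop finds the MAP weights of the penalised
logistic likelihood with a damped Newton method; the outer loop applies the
MacKay fixed-point update

    gamma_i = 1 - alpha_i * Sigma_ii,      alpha_i <- gamma_i / w_i^2,

where Sigma is the inverse Hessian at the MAP.  Weights whose precision
exceeds ``prune_alpha`` are pruned exactly to zero and removed from the
active set, which is what makes the classifier sparse: irrelevant voxels
are discarded automatically.

The iterative wrapper (iSLR) refits the base classifier on the feature
subspace left after removing all previously selected voxels, for up to
``n_iter`` stages (10 in the reference protocol).  Test probabilities are
combined multiplicatively across stages and renormalised,

    P = prod_k p_k / (prod_k p_k + prod_k (1 - p_k)),

before thresholding at 0.5 for the binary output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SLRHyper",
    "SLRModel",
    "ISLRModel",
    "fit_slr",
    "predict_slr",
    "fit_islr",
    "predict_islr",
    "combine_probabilities",
    "log_evidence",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SLRHyper:
    """Inference hyperparameters of the ARD classifier.

    prune_alpha:
        Precision above which a weight is declared irrelevant and pruned.
    intercept_alpha:
        Fixed weak precision on the intercept, which is never pruned.
    max_outer / tol:
        Evidence-update iteration cap and convergence tolerance on
        max |Delta w| across outer iterations.
    """

    prune_alpha: float = 1e8
    alpha_init: float = 1.0
    intercept_alpha: float = 1e-6
    max_outer: int = 200
    tol: float = 1e-6
    max_newton: int = 50
    newton_tol: float = 1e-8


@dataclass
class SLRModel:
    """One fitted sparse logistic stage.

    ``weights``/``alphas`` are in the model's own input feature space (length
    = number of columns it was fit on); pruned weights are exactly zero.
    ``input_features`` maps those columns back to the global feature space of
    the pipeline, and ``selected_features`` are the *global* indices of the
    surviving (non-pruned) weights.
    """

    weights: np.ndarray
    intercept: float
    alphas: np.ndarray
    input_features: np.ndarray
    converged: bool
    n_outer: int

    @property
    def selected_local(self) -> np.ndarray:
        return np.flatnonzero(self.weights != 0.0)

    @property
    def selected_features(self) -> np.ndarray:
        return self.input_features[self.selected_local]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "alphas": self.alphas.tolist(),
            "input_features": self.input_features.tolist(),
            "converged": self.converged,
            "n_outer": self.n_outer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SLRModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            alphas=np.asarray(d["alphas"], dtype=float),
            input_features=np.asarray(d["input_features"], dtype=int),
            converged=bool(d["converged"]),
            n_outer=int(d["n_outer"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _neg_log_posterior(Xa: np.ndarray, y: np.ndarray, w: np.ndarray, alphas: np.ndarray) -> float:
    z = Xa @ w
    # -sum log p(y|z) written stably as sum log(1+exp(-sign*z))
    s = np.where(y == 1, -z, z)
    ll = np.sum(np.logaddexp(0.0, s))
    return float(ll + 0.5 * np.sum(alphas * w * w))


def _newton_map(
    Xa: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    alphas: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton MAP weights for fixed prior precisions.

    Returns (w, hessian_at_map).
    """
    obj = _neg_log_posterior(Xa, y, w, alphas)
    H = None
    for _ in range(max_iter):
        p = _sigmoid(Xa @ w)
        grad = Xa.T @ (p - y) + alphas * w
        r = np.clip(p * (1.0 - p), 1e-10, None)
        H = (Xa.T * r) @ Xa
        H[np.diag_indices_from(H)] += alphas
        try:
            step = cho_solve(cho_factor(H), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(H.shape[0]), grad)
        scale = 1.0
        for _ in range(25):
            w_new = w - scale * step
            obj_new = _neg_log_posterior(Xa, y, w_new, alphas)
            if obj_new <= obj:
                break
            scale *= 0.5
        if obj - obj_new < tol and np.max(np.abs(w_new - w)) < tol:
            w = w_new
            obj = obj_new
            break
        w = w_new
        obj = obj_new
    p = _sigmoid(Xa @ w)
    r = np.clip(p * (1.0 - p), 1e-10, None)
    H = (Xa.T * r) @ Xa
    H[np.diag_indices_from(H)] += alphas
    return w, H


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes, coded 0/1")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    return X, y


def fit_slr(
    X: np.ndarray,
    y: np.ndarray,
    hyper: SLRHyper | None = None,
    input_features: np.ndarray | None = None,
) -> SLRModel:
    """Fit the ARD sparse logistic classifier.

    Deterministic: the optimisation starts from w = 0, alpha = ``alpha_init``
    and involves no randomness.
    """
    hyper = hyper or SLRHyper()
    X, y = _validate_xy(X, y)
    n, d = X.shape
    if input_features is None:
        input_features = np.arange(d)
    else:
        input_features = np.asarray(input_features, dtype=int)
        if input_features.size != d:
            raise ValueError("input_features length must match X columns")

    # column layout: d features then the intercept (never pruned)
    Xfull = np.hstack([X, np.ones((n, 1))])
    alphas = np.full(d + 1, hyper.alpha_init)
    alphas[-1] = hyper.intercept_alpha
    active = np.arange(d + 1)
    w_active = np.zeros(d + 1)
    w_prev = np.zeros(d + 1)
    converged = False
    n_outer = 0

    for n_outer in range(1, hyper.max_outer + 1):
        Xa = Xfull[:, active]
        w_active, H = _newton_map(
            Xa, y, w_active, alphas[active], hyper.max_newton, hyper.newton_tol
        )
        try:
            sigma_diag = np.diag(cho_solve(cho_factor(H), np.eye(H.shape[0])))
        except np.linalg.LinAlgError:
            sigma_diag = np.diag(np.linalg.pinv(H))
        gamma = 1.0 - alphas[active] * sigma_diag
        gamma = np.clip(gamma, 1e-12, 1.0)
        w_sq = np.clip(w_active**2, 1e-300, None)
        new_alpha = gamma / w_sq
        # the intercept keeps its fixed weak prior
        is_intercept = active == d
        new_alpha[is_intercept] = hyper.intercept_alpha
        alphas[active] = np.minimum(new_alpha, 10.0 * hyper.prune_alpha)

        keep = (alphas[active] <= hyper.prune_alpha) | is_intercept
        w_full = np.zeros(d + 1)
        w_full[active] = w_active
        if np.max(np.abs(w_full - w_prev)) < hyper.tol:
            active = active[keep]
            w_active = w_active[keep]
            converged = True
            break
        w_prev = w_full
        active = active[keep]
        w_active = w_active[keep]

    w_map = np.zeros(d + 1)
    w_map[active] = w_active
    return SLRModel(
        weights=w_map[:d],
        intercept=float(w_map[d]),
        alphas=alphas[:d].copy(),
        input_features=input_features,
        converged=converged,
        n_outer=n_outer,
    )


def predict_slr(model: SLRModel, X: np.ndarray) -> np.ndarray:
    """Per-sample probability of the positive class, clipped away from {0, 1}."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weights.size:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, model expects "
            f"{model.weights.size}"
        )
    p = _sigmoid(X @ model.weights + model.intercept)
    return np.clip(p, _EPS, 1.0 - _EPS)


def log_evidence(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    intercept_alpha: float = 1e-6,
    max_newton: int = 100,
    tol: float = 1e-10,
) -> float:
    """Laplace-approximated log marginal likelihood for fixed precisions.

    log p(D | alpha) ~= log lik(w*) - 0.5 w*' A w* + 0.5 sum log alpha
                        - 0.5 log |H(w*)|

    with w* the MAP weights and H the Hessian of the negative log posterior.
    Used as an independent check that the fixed-point updates actually climb
    the evidence surface.
    """
    X, y = _validate_xy(X, y)
    n, d = X.shape
    Xfull = np.hstack([X, np.ones((n, 1))])
    a = np.concatenate([np.asarray(alphas, dtype=float), [intercept_alpha]])
    if a.size != d + 1 or np.any(a <= 0):
        raise ValueError("alphas must be positive, one per feature")
    w, H = _newton_map(Xfull, y, np.zeros(d + 1), a, max_newton, tol)
    z = Xfull @ w
    s = np.where(y == 1, -z, z)
    loglik = -float(np.sum(np.logaddexp(0.0, s)))
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian not positive definite")
    return loglik - 0.5 * float(np.sum(a * w * w)) + 0.5 * float(np.sum(np.log(a))) - 0.5 * logdet


@dataclass
class ISLRModel:
    """Ordered stages of the iterative sparse classifier.

    Stage k was fit on the global feature space minus every feature selected
    by stages 1..k-1, so the per-stage ``selected_features`` sets are pairwise
    disjoint.
    """

    stages: list[SLRModel] = field(default_factory=list)
    n_features: int = 0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for st in self.stages:
            sel = set(st.selected_features.tolist())
            if seen & sel:
                raise ValueError("stage selected-feature sets must be disjoint")
            seen |= sel

    @property
    def selected_features(self) -> np.ndarray:
        if not self.stages:
            return np.empty(0, dtype=int)
        return np.concatenate([st.selected_features for st in self.stages])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"n_features": self.n_features, "stages": [st.to_dict() for st in self.stages]},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ISLRModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            stages=[SLRModel.from_dict(s) for s in d["stages"]],
            n_features=int(d["n_features"]),
        )


def fit_islr(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 10,
    hyper: SLRHyper | None = None,
) -> ISLRModel:
    """Fit the iterative wrapper: refit on the unselected feature residue.

    Stops early (shorter stage list) when no features remain or a stage after
    the first selects none.  The first stage is always kept so a fitted model
    can predict, even when it reduces to the intercept.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X, y = _validate_xy(X, y)
    d = X.shape[1]
    remaining = np.arange(d)
    stages: list[SLRModel] = []
    for _ in range(n_iter):
        if remaining.size == 0:
            break
        stage = fit_slr(X[:, remaining], y, hyper=hyper, input_features=remaining)
        if stage.selected_features.size == 0 and stages:
            break
        stages.append(stage)
        remaining = np.setdiff1d(remaining, stage.selected_features)
        if stage.selected_features.size == 0:
            break
    return ISLRModel(stages=stages, n_features=d)


def combine_probabilities(stage_probs: np.ndarray, scheme: str = "normalized") -> np.ndarray:
    """Combine per-stage probabilities multiplicatively.

    ``"normalized"`` (default): P = prod p / (prod p + prod (1-p)), computed
    in log space.  ``"product"``: the raw product of stage probabilities.
    Both agree on the binary decision when thresholds are matched to the
    scheme; the normalised form keeps P interpretable as a probability.
    """
    sp = np.atleast_2d(np.asarray(stage_probs, dtype=float))
    sp = np.clip(sp, _EPS, 1.0 - _EPS)
    if scheme == "normalized":
        log_p = np.sum(np.log(sp), axis=0)
        log_q = np.sum(np.log1p(-sp), axis=0)
        P = 1.0 / (1.0 + np.exp(log_q - log_p))
    elif scheme == "product":
        P = np.exp(np.sum(np.log(sp), axis=0))
    else:
        raise ValueError("scheme must be 'normalized' or 'product'")
    return np.clip(P, _EPS, 1.0 - _EPS)


def predict_islr(
    model: ISLRModel,
    X: np.ndarray,
    scheme: str = "normalized",
) -> tuple[np.ndarray, np.ndarray]:
    """Combined probability and binary label of each sample.

    Each stage scores the sample on its own input subspace; the per-stage
    probabilities are multiplied (see :func:`combine_probabilities`) and the
    label is ``P > 0.5``.
    """
    if not model.stages:
        raise ValueError("model has no stages")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"X must have {model.n_features} features")
    stage_probs = np.vstack(
        [predict_slr(st, X[:, st.input_features]) for st in model.stages]
    )
    P = combine_probabilities(stage_probs, scheme=scheme)
    return P, (P > 0.5).astype(int)
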