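"""L1/L2-regularized hinge-loss linear classifiers over fingerprint rows.

The classifier is a plain linear score f(x) = w.x (optionally + bias)
whose sign predicts interaction.  Training minimizes

    R(w) + C * sum_i max(1 - y_i * f(x_i), 0)

with R(w) = ||w||_1 (sparsity-inducing, "L1SVM") or R(w) = 0.5*||w||_2^2
("L2SVM").  Applied to compact fingerprints these are the minwise-hashing
variants MH-L1SVM / MH-L2SVM; applied to raw tensor features they are the
direct L1SVM / L2SVM.

Solvers
-------
* L2 + hinge is delegated to scikit-learn's :class:`~sklearn.svm.LinearSVC`
  (liblinear dual coordinate descent), the standard tool for exactly this
  problem.
* L1 + hinge is an exact linear program (split w = u - v, slack xi per
  example) solved with scipy's HiGHS backend.  At desk scale this gives
  the true optimum rather than an approximate coordinate-descent path.
* :func:`reference_subgradient` is a deliberately simple projected
  subgradient solver kept as an independent check of both objectives on
  small instances; it is not a production path.

The squared L2 regularizer (rather than the unsquared norm) and the
placement of C on the loss term follow the convention of liblinear-style
solvers; C sweeps like 1e-5..1e5 are interpreted in that convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .exceptions import DegenerateProblemError, ValidationError
from .minhash import HashFamily

__all__ = [
    "TrainingDesign",
    "LinearModel",
    "hinge_objective",
    "train_linear_svm",
    "decision_scores",
    "reference_subgradient",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "cpihash-linear-model/1"


@dataclass
class TrainingDesign:
    """Sparse binary feature rows with +-1 labels and pair identities."""

    x: sparse.csr_matrix
    y: np.ndarray
    ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = sparse.csr_matrix(self.x)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape[0] != self.y.size:
            raise ValidationError(
                f"row count {self.x.shape[0]} != label count {self.y.size}"
            )
        if self.ids and len(self.ids) != self.y.size:
            raise ValidationError("ids length must match label count")
        if self.y.size and not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValidationError("labels must be +1/-1")

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def n_features(self) -> int:
        return int(self.x.shape[1])


@dataclass
class LinearModel:
    """A trained linear decision function over fingerprint coordinates."""

    weights: np.ndarray
    regularization: str
    C: float
    mode: str
    bias: float | None = None
    family: HashFamily | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.regularization not in ("l1", "l2"):
            raise ValidationError(
                f"regularization must be 'l1' or 'l2', got {self.regularization!r}"
            )
        if self.mode not in ("compact", "direct"):
            raise ValidationError(f"mode must be 'compact' or 'direct', got {self.mode!r}")
        if self.C <= 0:
            raise ValidationError(f"C must be positive, got {self.C}")
        if self.mode == "compact":
            if self.family is None:
                raise ValidationError("compact-mode model must carry its HashFamily")
            expected = self.family.ell * self.family.N
            if self.weights.size != expected:
                raise ValidationError(
                    f"compact weight length {self.weights.size} != ell*N = {expected}"
                )

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))


def _regularizer(weights: np.ndarray, regularization: str) -> float:
    if regularization == "l1":
        return float(np.abs(weights).sum())
    return 0.5 * float(weights @ weights)


def hinge_objective(model: LinearModel, design: TrainingDesign) -> float:
    """R(w) + C * sum_i max(1 - y_i (w.x_i + bias), 0)."""
    if design.n_features != model.weights.size:
        raise ValidationError(
            f"design has {design.n_features} features, model has {model.weights.size}"
        )
    scores = design.x @ model.weights
    if model.bias is not None:
        scores = scores + model.bias
    hinge = np.maximum(1.0 - design.y * scores, 0.0).sum()
    return _regularizer(model.weights, model.regularization) + model.C * float(hinge)


def decision_scores(model: LinearModel, x: sparse.spmatrix | np.ndarray) -> np.ndarray:
    """w.x (+ bias) per row; the sign is the predicted class."""
    x = sparse.csr_matrix(x)
    if x.shape[1] != model.weights.size:
        raise ValidationError(
            f"rows have {x.shape[1]} features, model has {model.weights.size}"
        )
    scores = np.asarray(x @ model.weights, dtype=np.float64).ravel()
    if model.bias is not None:
        scores = scores + model.bias
    return scores


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise DegenerateProblemError(
            "training labels contain a single class; a separating linear "
            "model is not identifiable"
        )


def _train_l2_hinge(
    design: TrainingDesign,
    C: float,
    tolerance: float,
    max_iterations: int,
    seed: int,
    fit_bias: bool,
) -> tuple[np.ndarray, float | None, bool, int]:
    clf = LinearSVC(
        penalty="l2",
        loss="hinge",
        dual=True,
        C=C,
        tol=tolerance,
        max_iter=max_iterations,
        fit_intercept=fit_bias,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(design.x, design.y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(design.x, design.y)
    weights = clf.coef_.ravel().copy()
    bias = float(clf.intercept_[0]) if fit_bias else None
    return weights, bias, converged, int(np.max(clf.n_iter_))


def _train_l1_hinge(
    design: TrainingDesign,
    C: float,
    fit_bias: bool,
) -> tuple[np.ndarray, float | None, bool, int]:
    """Exact LP: min 1.u + 1.v + C 1.xi  s.t.  Yx.(u-v) (+ y*bias) + xi >= 1."""
    n, d = design.n, design.n_features
    yx = sparse.csr_matrix(design.x.multiply(design.y[:, None]))
    blocks = [-yx, yx, -sparse.identity(n, format="csr")]
    cost = [np.ones(d), np.ones(d), np.full(n, C)]
    if fit_bias:
        ycol = sparse.csr_matrix(design.y.reshape(-1, 1))
        blocks[2:2] = [-ycol, ycol]  # bias = b_pos - b_neg, zero cost
        cost[2:2] = [np.zeros(1), np.zeros(1)]
    a_ub = sparse.hstack(blocks, format="csr")
    c = np.concatenate(cost)
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=np.full(n, -1.0),
        bounds=(0, None),
        method="highs",
    )
    if res.x is None:
        raise DegenerateProblemError(f"L1 hinge LP failed: {res.message}")
    u = res.x[:d]
    v = res.x[d : 2 * d]
    weights = u - v
    # tiny LP residues below solver precision are true zeros of the L1 path
    weights[np.abs(weights) < 1e-10] = 0.0
    bias = None
    if fit_bias:
        bias = float(res.x[2 * d] - res.x[2 * d + 1])
    return weights, bias, bool(res.status == 0), int(getattr(res, "nit", 0))


def train_linear_svm(
    design: TrainingDesign,
    regularization: str,
    C: float,
    tolerance: float = 1e-3,
    max_iterations: int = 1000,
    seed: int = 0,
    mode: str = "direct",
    family: HashFamily | None = None,
    fit_bias: bool = False,
) -> LinearModel:
    """Fit an L1- or L2-regularized hinge-loss linear model.

    Deterministic given ``seed``.  A model that hit ``max_iterations``
    before meeting ``tolerance`` is returned with ``converged=False``
    rather than silently.
    """
    if regularization not in ("l1", "l2"):
        raise ValidationError(f"regularization must be 'l1' or 'l2', got {regularization!r}")
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    _check_two_classes(design.y)
    if regularization == "l2":
        weights, bias, converged, n_iter = _train_l2_hinge(
            design, C, tolerance, max_iterations, seed, fit_bias
        )
    else:
        weights, bias, converged, n_iter = _train_l1_hinge(design, C, fit_bias)
    return LinearModel(
        weights=weights,
        bias=bias,
        regularization=regularization,
        C=C,
        mode=mode,
        family=family,
        converged=converged,
        n_iter=n_iter,
    )


def _subgradient_run(
    x: np.ndarray,
    y: np.ndarray,
    regularization: str,
    C: float,
    step0: float,
    n_iter: int,
) -> tuple[np.ndarray, float]:
    w = np.zeros(x.shape[1])
    best_w = w.copy()
    best_obj = np.inf
    for t in range(1, n_iter + 1):
        margins = y * (x @ w)
        active = margins < 1.0
        loss_grad = -C * (y[active][:, None] * x[active]).sum(axis=0)
        if regularization == "l2":
            grad = w + loss_grad
        else:
            grad = np.sign(w) + loss_grad
        norm = np.linalg.norm(grad)
        if norm == 0.0:
            break
        w = w - (step0 / np.sqrt(t)) * grad / norm
        if t % 20 == 0 or t == n_iter:
            obj = _regularizer(w, regularization) + C * float(
                np.maximum(1.0 - y * (x @ w), 0.0).sum()
            )
            if obj < best_obj:
                best_obj = obj
                best_w = w.copy()
    return best_w, best_obj


def reference_subgradient(
    design: TrainingDesign,
    regularization: str,
    C: float,
    n_iter: int = 20000,
    seed: int = 0,
) -> LinearModel:
    """Normalized subgradient descent on the primal objective.

    An independent, solver-free oracle for small instances: a short pilot
    pass picks the step scale, then a long diminishing-step run keeps the
    best iterate.  Slow, but approaches the same optimum as the
    production paths; used to cross-check them, never to train.
    """
    _check_two_classes(design.y)
    _ = seed  # deterministic; kept for signature stability
    x = design.x.toarray()
    y = design.y
    pilot = max(200, n_iter // 20)
    candidates = [10.0**e for e in range(-3, 3)]
    best_step = min(
        candidates,
        key=lambda s: _subgradient_run(x, y, regularization, C, s, pilot)[1],
    )
    best_w, _ = _subgradient_run(x, y, regularization, C, best_step, n_iter)
    return LinearModel(
        weights=best_w, regularization=regularization, C=C, mode="direct"
    )


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: LinearModel, path: str | Path) -> None:
    """Write a model as versioned JSON with sparse (index, value) weights."""
    nz = np.nonzero(model.weights)[0]
    payload = {
        "format": MODEL_FORMAT,
        "mode": model.mode,
        "regularization": model.regularization,
        "C": model.C,
        "bias": model.bias,
        "n_features": int(model.weights.size),
        "converged": model.converged,
        "weights": [[int(i), float(model.weights[i])] for i in nz],
        "family": model.family.to_dict() if model.family is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LinearModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != MODEL_FORMAT:
        raise ValidationError(
            f"unsupported model format {payload.get('format')!r}"
        )
    weights = np.zeros(int(payload["n_features"]))
    for i, value in payload["weights"]:
        weights[int(i)] = float(value)
    family = (
        HashFamily.from_dict(payload["family"])
        if payload.get("family") is not None
        else None
    )
    return LinearModel(
        weights=weights,
        bias=payload.get("bias"),
        regularization=payload["regularization"],
        C=float(payload["C"]),
        mode=payload["mode"],
        family=family,
        converged=bool(payload.get("converged", True)),
    )
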