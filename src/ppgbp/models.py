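"""The three blood-pressure regressors: MLR, linear ε-SVR, CART tree.

Each model maps the selected pulse-morphology features to one blood-pressure
target (SBP or DBP, in mmHg) and is fitted independently per target.

* Multiple linear regression is solved in closed form (least squares on the
  design matrix with intercept).
* The ε-support-vector regressor uses a linear kernel with an ε-insensitive
  (L1) loss; convergence is certified by the normalized primal–dual
  feasibility gap Δ = (J(β) + L(α)) / (J(β) + 1), where J is the primal
  objective and L the (minimization-form) dual; Δ must fall below the gap
  tolerance.  Features are standardized inside the fit so the box constraint
  C is comparable across features, while ε stays on the mmHg scale.
* The regression tree splits greedily on midpoint thresholds minimizing the
  weighted child mean-squared error, and a node becomes a leaf (is "pure")
  when its response MSE drops below the whole-sample MSE times a tolerance,
  or when depth/leaf-size limits bind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVR as _SKSVR

__all__ = [
    "TrainingSet",
    "MLRModel",
    "SVRModel",
    "TreeNode",
    "TreeModel",
    "SingularDesignError",
    "ConvergenceError",
    "fit_mlr",
    "fit_svr",
    "fit_tree",
    "predict",
    "save_model",
    "load_model",
]


class SingularDesignError(ValueError):
    """Design matrix (with intercept) is rank deficient."""


class ConvergenceError(RuntimeError):
    """SVR feasibility gap did not fall below the gap tolerance."""


@dataclass
class TrainingSet:
    """Feature matrix (m × k) with reference pressures y (mmHg)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != len(self.y):
            raise ValueError(f"X has {self.X.shape[0]} rows but y has {len(self.y)}")
        if len(self.y) < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("training data contain non-finite values")

    @property
    def m(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# multiple linear regression


@dataclass
class MLRModel:
    """h(x) = theta[0] + theta[1:] · x, fitted by least squares."""

    theta: np.ndarray
    residual_sd: float
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _check_schema(X, self.n_features)
        return self.theta[0] + X @ self.theta[1:]


def fit_mlr(train: TrainingSet) -> MLRModel:
    """Closed-form least squares; raises on a rank-deficient design."""
    design = np.column_stack([np.ones(train.m), train.X])
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise SingularDesignError(
            f"design matrix with intercept has rank < {p}; features are collinear"
        )
    theta, *_ = np.linalg.lstsq(design, train.y, rcond=None)
    residuals = train.y - design @ theta
    dof = max(train.m - p, 1)
    return MLRModel(
        theta=theta,
        residual_sd=float(np.sqrt(residuals @ residuals / dof)),
        n_features=train.X.shape[1],
    )


# ---------------------------------------------------------------------------
# linear epsilon-SVR


@dataclass
class SVRModel:
    """Linear ε-SVR with stored dual certificate.

    ``weights``/``bias`` act on the *original* feature scale; the
    standardization constants used during fitting are kept for bookkeeping.
    ``gap`` is the normalized primal–dual feasibility gap at convergence.
    """

    weights: np.ndarray
    bias: float
    epsilon: float
    C: float
    dual_coef: np.ndarray  # alpha_i - alpha_i* per training row
    primal_objective: float
    dual_objective: float  # minimization form L(alpha) = -D(alpha)
    gap: float
    gap_tol: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _check_schema(X, self.n_features)
        return X @ self.weights + self.bias


def fit_svr(
    train: TrainingSet,
    epsilon: float = 2.0,
    C: float = 1.0,
    gap_tol: float = 1e-3,
    max_iter: int = 1_000_000,
) -> SVRModel:
    """Fit a linear ε-SVR and certify convergence via the feasibility gap.

    ε defaults to 2 mmHg (on the blood-pressure scale); C applies to features
    standardized to zero mean and unit variance.
    """
    if epsilon < 0 or C <= 0 or gap_tol <= 0:
        raise ValueError("need epsilon >= 0, C > 0, gap_tol > 0")
    mean = train.X.mean(axis=0)
    scale = train.X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Z = (train.X - mean) / scale
    y = train.y

    sk = _SKSVR(kernel="linear", C=C, epsilon=epsilon, tol=min(1e-5, gap_tol * 1e-2),
                max_iter=max_iter)
    sk.fit(Z, y)

    beta = np.zeros(train.m)
    if sk.support_.size:
        beta[sk.support_] = sk.dual_coef_.ravel()
    w = Z.T @ beta
    b = float(sk.intercept_[0])

    residuals = y - (Z @ w + b)
    primal = 0.5 * w @ w + C * np.sum(np.maximum(0.0, np.abs(residuals) - epsilon))
    # maximization-form dual D; L(alpha) = -D so that J + L is the duality gap
    dual_max = -0.5 * w @ w - epsilon * np.sum(np.abs(beta)) + y @ beta
    dual_min_form = -dual_max
    gap = (primal + dual_min_form) / (primal + 1.0)
    if not np.isfinite(gap) or gap >= gap_tol:
        raise ConvergenceError(
            f"SVR did not converge: feasibility gap {gap:.3e} >= tolerance {gap_tol:.3e}"
        )

    weights = w / scale
    bias = b - float(weights @ mean)
    return SVRModel(
        weights=weights,
        bias=bias,
        epsilon=epsilon,
        C=C,
        dual_coef=beta,
        primal_objective=float(primal),
        dual_objective=float(dual_min_form),
        gap=float(gap),
        gap_tol=gap_tol,
        feature_mean=mean,
        feature_scale=scale,
        n_features=train.X.shape[1],
    )


# ---------------------------------------------------------------------------
# CART regression tree


@dataclass
class TreeNode:
    """Internal node (feature, threshold) or leaf (value = mean response)."""

    value: float
    n: int
    feature: int = -1
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class TreeModel:
    """Binary regression tree; rows with feature value > threshold go right."""

    root: TreeNode
    max_depth: int
    min_leaf: int
    purity_tol: float
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _check_schema(X, self.n_features)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.right if row[node.feature] > node.threshold else node.left
            out[i] = node.value
        return out

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Exhaustively best (feature, threshold, total child SSE) or None.

    Candidate thresholds are midpoints between sorted adjacent distinct
    values; both children must keep at least ``min_leaf`` rows.  Ties go to
    the lowest feature index, then the smallest threshold.
    """
    n, k = X.shape
    best: tuple[int, float, float] | None = None
    for j in range(k):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total_sum, total_sq = csum[-1], csq[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            nr = n - nl
            sse_l = csq[i] - csum[i] ** 2 / nl
            sse_r = (total_sq - csq[i]) - (total_sum - csum[i]) ** 2 / nr
            score = sse_l + sse_r
            thr = 0.5 * (xs[i] + xs[i + 1])
            if not xs[i] < thr < xs[i + 1]:
                # adjacent floats: the midpoint collapses onto a value and
                # would route one side empty
                continue
            if best is None or score < best[2] - 1e-12 * max(1.0, abs(best[2])):
                best = (j, thr, score)
    return best


def fit_tree(
    train: TrainingSet,
    max_depth: int = 12,
    min_leaf: int = 5,
    purity_tol: float = 1e-4,
) -> TreeModel:
    """Greedy CART fit with the relative-purity stopping rule.

    A node is declared pure (left as a leaf) when its response MSE is below
    the MSE of all training responses times ``purity_tol``.
    """
    if train.m < 2 * min_leaf:
        raise ValueError(f"need at least 2*min_leaf={2 * min_leaf} rows, got {train.m}")
    root_mse = _sse(train.y) / train.m

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y = train.y[idx]
        node = TreeNode(value=float(y.mean()), n=len(idx))
        node_mse = _sse(y) / len(y)
        if (
            depth >= max_depth
            or len(idx) < 2 * min_leaf
            or node_mse < root_mse * purity_tol
            or node_mse == 0.0
        ):
            return node
        split = best_split(train.X[idx], y, min_leaf)
        if split is None:
            return node
        j, thr, _ = split
        go_right = train.X[idx, j] > thr
        node.feature = j
        node.threshold = thr
        node.left = build(idx[~go_right], depth + 1)
        node.right = build(idx[go_right], depth + 1)
        return node

    root = build(np.arange(train.m), 0)
    return TreeModel(
        root=root,
        max_depth=max_depth,
        min_leaf=min_leaf,
        purity_tol=purity_tol,
        n_features=train.X.shape[1],
    )


# ---------------------------------------------------------------------------
# shared helpers


def _check_schema(X: np.ndarray, n_features: int) -> None:
    if X.ndim != 2 or X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} feature columns, got shape {X.shape}")


def predict(model, X: np.ndarray) -> np.ndarray:
    """Estimate blood pressure (mmHg) for each feature row."""
    if not isinstance(model, (MLRModel, SVRModel, TreeModel)):
        raise TypeError(f"unknown model type {type(model).__name__}")
    return model.predict(X)


# ---------------------------------------------------------------------------
# plain-text persistence (versioned key-value + node list)

_FORMAT_HEADER = "ppgbp-model v1"


def save_model(model, path: str | Path) -> None:
    lines = [_FORMAT_HEADER]
    if isinstance(model, MLRModel):
        lines += [
            "type mlr",
            f"n_features {model.n_features}",
            "theta " + " ".join(f"{t:.17g}" for t in model.theta),
            f"residual_sd {model.residual_sd:.17g}",
        ]
    elif isinstance(model, SVRModel):
        lines += [
            "type svr",
            f"n_features {model.n_features}",
            "weights " + " ".join(f"{w:.17g}" for w in model.weights),
            f"bias {model.bias:.17g}",
            f"epsilon {model.epsilon:.17g}",
            f"C {model.C:.17g}",
            f"gap {model.gap:.17g}",
            f"gap_tol {model.gap_tol:.17g}",
        ]
    elif isinstance(model, TreeModel):
        lines += [
            "type tree",
            f"n_features {model.n_features}",
            f"max_depth {model.max_depth}",
            f"min_leaf {model.min_leaf}",
            f"purity_tol {model.purity_tol:.17g}",
        ]
        nodes: list[TreeNode] = []

        def index(node: TreeNode) -> int:
            nodes.append(node)
            i = len(nodes) - 1
            if not node.is_leaf:
                li = index(node.left)
                ri = index(node.right)
                node_meta[i] = (li, ri)
            return i

        node_meta: dict[int, tuple[int, int]] = {}
        index(model.root)
        lines.append(f"n_nodes {len(nodes)}")
        for i, node in enumerate(nodes):
            li, ri = node_meta.get(i, (-1, -1))
            lines.append(
                f"node {i} {node.feature} {node.threshold:.17g} "
                f"{node.value:.17g} {node.n} {li} {ri}"
            )
    else:
        raise TypeError(f"cannot save model of type {type(model).__name__}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path):
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if not text or text[0] != _FORMAT_HEADER:
        raise ValueError(f"{path}: not a {_FORMAT_HEADER!r} file")
    kv: dict[str, str] = {}
    node_lines = []
    for line in text[1:]:
        key, _, rest = line.partition(" ")
        if key == "node":
            node_lines.append(rest)
        else:
            kv[key] = rest
    mtype = kv["type"]
    nf = int(kv["n_features"])
    if mtype == "mlr":
        return MLRModel(
            theta=np.array([float(v) for v in kv["theta"].split()]),
            residual_sd=float(kv["residual_sd"]),
            n_features=nf,
        )
    if mtype == "svr":
        return SVRModel(
            weights=np.array([float(v) for v in kv["weights"].split()]),
            bias=float(kv["bias"]),
            epsilon=float(kv["epsilon"]),
            C=float(kv["C"]),
            dual_coef=np.empty(0),
            primal_objective=float("nan"),
            dual_objective=float("nan"),
            gap=float(kv["gap"]),
            gap_tol=float(kv["gap_tol"]),
            feature_mean=np.zeros(nf),
            feature_scale=np.ones(nf),
            n_features=nf,
        )
    if mtype == "tree":
        raw = []
        for rest in node_lines:
            i, feat, thr, val, n, li, ri = rest.split()
            raw.append((int(i), int(feat), float(thr), float(val), int(n), int(li), int(ri)))
        raw.sort()
        nodes = [TreeNode(value=v, n=n, feature=f, threshold=t) for _, f, t, v, n, _, _ in raw]
        for (_, _, _, _, _, li, ri), node in zip(raw, nodes):
            if li >= 0:
                node.left = nodes[li]
                node.right = nodes[ri]
            else:
                node.feature = -1
        return TreeModel(
            root=nodes[0],
            max_depth=int(kv["max_depth"]),
            min_leaf=int(kv["min_leaf"]),
            purity_tol=float(kv["purity_tol"]),
            n_features=nf,
        )
    raise ValueError(f"{path}: unknown model type {mtype!r}")
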