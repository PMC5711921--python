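"""Radial-basis-function network regression of normalized BMD on normalized inputs.

The architecture search emulates an automated problem-solver: for each
candidate number of centers k on a grid, centers are placed by seeded k-means
on the training inputs, per-center Gaussian widths come from the mean
distance to the nearest centers, and the linear output layer is solved by
ridge-regularized least squares.  The k with the highest verification-set
correlation wins.  Inputs and target live in [0, 1] (min-max normalized), so
the prediction is clipped to the unit interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans


class TooSmallCohortError(ValueError):
    pass


@dataclass
class HoldoutSplit:
    """Disjoint, exhaustive train/verify/test index sets in a 2:1:1 ratio."""

    train: np.ndarray
    verify: np.ndarray
    test: np.ndarray
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.verify), len(self.test)


def split_2_1_1(n: int, seed: int) -> HoldoutSplit:
    """Seeded uniform shuffle split: ceil(n/2) train, remainder split with the
    extra participant going to the verification set."""
    if n < 8:
        raise TooSmallCohortError(f"need n >= 8 for a 2:1:1 split, got {n}")
    n_train = math.ceil(n / 2)
    rest = n - n_train
    n_verify = math.ceil(rest / 2)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return HoldoutSplit(
        train=np.sort(perm[:n_train]),
        verify=np.sort(perm[n_train:n_train + n_verify]),
        test=np.sort(perm[n_train + n_verify:]),
        seed=seed,
    )


@dataclass
class RBFNetwork:
    """Gaussian-kernel RBF regressor with a linear output layer.

    prediction(x) = clip( sum_i w_i * exp(-||x - c_i||^2 / (2 s_i^2)) + b, 0, 1 )
    """

    centers: np.ndarray          # (k, d)
    widths: np.ndarray           # (k,)
    weights: np.ndarray          # (k,)
    bias: float
    input_features: tuple[str, ...]

    def design(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(np.atleast_2d(X), self.centers, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths**2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError(
                f"expected {self.centers.shape[1]} features, got {X.shape[1]}"
            )
        raw = self.design(X) @ self.weights + self.bias
        return np.clip(raw, 0.0, 1.0)

    def predict_row(self, row: dict) -> float:
        missing = [f for f in self.input_features if f not in row]
        if missing:
            raise KeyError(f"missing features: {missing}")
        x = np.array([[row[f] for f in self.input_features]], dtype=float)
        return float(self.predict(x)[0])

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "input_features": list(self.input_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNetwork":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            widths=np.asarray(d["widths"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            input_features=tuple(d["input_features"]),
        )


@dataclass
class FitReport:
    r_train: float
    r_verify: float
    r_test: float | None
    n_centers: int
    ridge: float


@dataclass
class RBFConfig:
    k_grid: tuple[int, ...] | None = None   # default: 2..min(20, n_train // 5)
    ridge: float = 1e-6
    n_nearest_widths: int = 2
    width_scale: float = 2.0                # kernel-overlap factor on the widths
    width_floor: float = 1e-6


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _widths_from_centers(centers: np.ndarray, p: int, floor: float,
                         scale: float = 1.0) -> np.ndarray:
    """Per-center width: ``scale`` times the mean distance to the p nearest centers.

    The overlap factor > 1 widens the kernels so neighbouring basis functions
    overlap, trading a little training fit for a much smoother interpolant.
    """
    k = len(centers)
    if k == 1:
        return np.array([max(floor, scale)])
    d = cdist(centers, centers)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    take = min(p, k - 1)
    w = scale * d[:, :take].mean(axis=1)
    return np.maximum(w, floor)


def _fit_single(X, y, k, ridge, p_nearest, floor, seed,
                width_scale: float = 1.0) -> RBFNetwork | None:
    for attempt in range(3):
        km = KMeans(n_clusters=k, n_init=1, max_iter=100,
                    random_state=(seed + 1000 * attempt) % (2**31))
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == k:
            break
    else:
        return None  # degenerate even after retries; caller reduces k
    centers = km.cluster_centers_
    widths = _widths_from_centers(centers, p_nearest, floor, width_scale)
    d2 = cdist(X, centers, metric="sqeuclidean")
    phi = np.exp(-d2 / (2.0 * widths**2))
    A = np.column_stack([phi, np.ones(len(X))])
    gram = A.T @ A + ridge * np.eye(k + 1)
    coef = np.linalg.solve(gram, A.T @ y)
    return RBFNetwork(centers, widths, coef[:k], float(coef[k]),
                      input_features=())


def fit_rbf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_verify: np.ndarray,
    y_verify: np.ndarray,
    features=(),
    config: RBFConfig | None = None,
    seed: int = 0,
) -> tuple[RBFNetwork, FitReport]:
    """Architecture search over center counts, selected on the verification set.

    Returns the winning network and a report with Pearson correlations of
    prediction vs target on the training and verification sets (the test-set
    column is filled in by :func:`evaluate_on`).
    """
    config = config or RBFConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = len(X_train)
    k_grid = config.k_grid or tuple(range(2, max(3, min(20, n // 5) + 1)))
    best = None
    for k in k_grid:
        if k >= n:
            continue
        net = _fit_single(X_train, y_train, k, config.ridge,
                          config.n_nearest_widths, config.width_floor, seed + k,
                          width_scale=config.width_scale)
        if net is None:
            continue
        net.input_features = tuple(features)
        r_ver = _safe_pearson(net.predict(X_verify), y_verify)
        if best is None or r_ver > best[0]:
            r_tr = _safe_pearson(net.predict(X_train), y_train)
            best = (r_ver, k, net, r_tr)
    if best is None:
        raise TooSmallCohortError("no feasible center count in the grid")
    r_ver, k, net, r_tr = best
    return net, FitReport(r_train=r_tr, r_verify=r_ver, r_test=None,
                          n_centers=k, ridge=config.ridge)


def evaluate_on(net: RBFNetwork, report: FitReport,
                X_test: np.ndarray, y_test: np.ndarray) -> FitReport:
    report.r_test = _safe_pearson(net.predict(X_test), y_test)
    return report


predict_rbf = RBFNetwork.predict  # functional alias


# ---------------------------------------------------------------------------
# Baseline: ordinary least squares of normalized BMD on the same inputs.
# ---------------------------------------------------------------------------

@dataclass
class LinearBaseline:
    coef: np.ndarray
    intercept: float
    features: tuple[str, ...]
    rho_train: float
    kind: str = "linear"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept


def fit_mlr_baseline(
    X: np.ndarray, y: np.ndarray, features=(), logistic: bool = False,
    labels: np.ndarray | None = None,
) -> LinearBaseline:
    """Multiple-linear-regression comparison model.

    Reports the Spearman rho between fitted output and the target, the metric
    used to compare against the RBF model.  ``logistic=True`` fits a logistic
    model on binary risk labels instead (supplementary variant only).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need at least one input feature")
    if logistic:
        from sklearn.linear_model import LogisticRegression
        if labels is None:
            raise ValueError("logistic variant needs binary labels")
        lm = LogisticRegression(max_iter=1000).fit(X, labels)
        fitted = lm.predict_proba(X)[:, 1]
        rho, _ = stats.spearmanr(fitted, y)
        return LinearBaseline(lm.coef_[0], float(lm.intercept_[0]),
                              tuple(features), float(rho), kind="logistic")
    A = np.column_stack([X, np.ones(len(X))])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        import warnings
        warnings.warn("rank-deficient design; least-squares pseudoinverse used")
    coef, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    fitted = A @ coef
    rho, _ = stats.spearmanr(fitted, y)
    return LinearBaseline(coef[:-1], float(coef[-1]), tuple(features), float(rho))
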