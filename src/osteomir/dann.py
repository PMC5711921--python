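"""Derivative-information stacking: distance-ranked divisions and the ANN I -> ANN II cascade.

For each participant, the remaining cohort is sorted by Euclidean distance in
the normalized input space and cut into m nearly-equal contiguous divisions
(m in 2..10).  Four derivative features are read off one division:

* the participant's own first-stage (ANN I) output,
* the mean ANN I output over the division's members,
* the mean Euclidean distance to the division's members, and
* the actual proportion of osteoporosis among the division's members.

A second RBF network (ANN II) regresses normalized BMD on these four
features; the division size m and the division index are selected jointly by
the verification-set Spearman correlation.  The full cascade is the DANN.

Neighbor risk labels are used transductively (the reference cohort's labels
inform the score of a *different* participant); the focal participant's own
label is never an input to her own score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .cohort import CohortTable, NormalizationParams, fit_minmax
from .rbf import FitReport, RBFConfig, RBFNetwork, evaluate_on, fit_rbf, split_2_1_1

M_RANGE_DEFAULT = tuple(range(2, 11))
DEFAULT_RISK_THRESHOLD = 0.38


def euclidean(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def division_sizes(n_ref: int, m: int) -> list[int]:
    """Nearly-equal contiguous block sizes; the remainder goes to the nearest
    (lowest-index) divisions first."""
    if not 2 <= m <= 10:
        raise ValueError(f"division size m must be in [2, 10], got {m}")
    if m > n_ref:
        raise ValueError(f"m={m} exceeds reference size {n_ref}")
    base, rem = divmod(n_ref, m)
    return [base + 1 if i < rem else base for i in range(m)]


def make_divisions(
    distances: np.ndarray, m: int, tie_order: np.ndarray | None = None
) -> list[np.ndarray]:
    """Partition reference indices into m divisions by ascending distance.

    ``tie_order`` breaks equal distances deterministically (defaults to the
    reference index itself, i.e. id order).
    """
    distances = np.asarray(distances, dtype=float)
    n_ref = len(distances)
    sizes = division_sizes(n_ref, m)
    if tie_order is None:
        tie_order = np.arange(n_ref)
    order = np.lexsort((tie_order, distances))
    blocks, start = [], 0
    for s in sizes:
        blocks.append(order[start:start + s])
        start += s
    return blocks


@dataclass
class DerivativeFeatures:
    ann1_self: float
    div_mean_output: float
    div_mean_dist: float
    div_op_prop: float

    def as_array(self) -> np.ndarray:
        return np.array([self.ann1_self, self.div_mean_output,
                         self.div_mean_dist, self.div_op_prop])


def derivative_features(
    focal_x: np.ndarray,
    ann1_self: float,
    ref_X: np.ndarray,
    ref_ann1: np.ndarray,
    ref_risk: np.ndarray,
    m: int,
    d_index: int,
) -> DerivativeFeatures:
    """The four derivative features of one participant against a reference cohort.

    ``d_index`` counts divisions from 1 = nearest.  The caller is responsible
    for excluding the focal participant from the reference when she is a
    member of it.
    """
    if not 1 <= d_index <= m:
        raise ValueError(f"d_index must be in [1, {m}], got {d_index}")
    dists = cdist(np.atleast_2d(focal_x), ref_X)[0]
    block = make_divisions(dists, m)[d_index - 1]
    return DerivativeFeatures(
        ann1_self=float(ann1_self),
        div_mean_output=float(ref_ann1[block].mean()),
        div_mean_dist=float(dists[block].mean()),
        div_op_prop=float(ref_risk[block].mean()),
    )


def derivative_grid(
    X: np.ndarray,
    ann1_out: np.ndarray,
    risk: np.ndarray,
    m_range=M_RANGE_DEFAULT,
    ref_X: np.ndarray | None = None,
    ref_ann1: np.ndarray | None = None,
    ref_risk: np.ndarray | None = None,
) -> dict[tuple[int, int], np.ndarray]:
    """Derivative-feature tables for every (m, d_index) candidate at once.

    When no separate reference is given, each row of ``X`` is scored against
    all *other* rows (leave-self-out, the training-cohort convention);
    otherwise every row is scored against the full external reference.
    Returns {(m, d): (n, 4) array}.
    """
    internal = ref_X is None
    if internal:
        ref_X, ref_ann1, ref_risk = X, ann1_out, risk
    n = len(X)
    n_ref_eff = len(ref_X) - (1 if internal else 0)
    boundaries = {
        m: np.concatenate([[0], np.cumsum(division_sizes(n_ref_eff, m))])
        for m in m_range
    }
    tables = {
        (m, d): np.empty((n, 4))
        for m in m_range for d in range(1, m + 1)
    }
    D = cdist(X, ref_X)
    ref_idx = np.arange(len(ref_X))
    for i in range(n):
        dists = D[i]
        if internal:
            keep = ref_idx != i
            dists, out_i, risk_i, tie = (
                dists[keep], ref_ann1[keep], ref_risk[keep], ref_idx[keep])
        else:
            out_i, risk_i, tie = ref_ann1, ref_risk, ref_idx
        order = np.lexsort((tie, dists))
        d_s = np.concatenate([[0.0], np.cumsum(dists[order])])
        o_s = np.concatenate([[0.0], np.cumsum(out_i[order])])
        r_s = np.concatenate([[0.0], np.cumsum(risk_i[order])])
        for m in m_range:
            b = boundaries[m]
            for d in range(1, m + 1):
                lo, hi = b[d - 1], b[d]
                size = hi - lo
                tables[(m, d)][i] = (
                    ann1_out[i],
                    (o_s[hi] - o_s[lo]) / size,
                    (d_s[hi] - d_s[lo]) / size,
                    (r_s[hi] - r_s[lo]) / size,
                )
    return tables


def _scale_table(table: np.ndarray, dist_scale: float) -> np.ndarray:
    """ANN II inputs in [0,1]: the distance column is divided by sqrt(d)."""
    out = table.copy()
    out[:, 2] = out[:, 2] / dist_scale
    return out


ANN2_FEATURES = ("ann1_self", "div_mean_output", "div_mean_dist", "div_op_prop")


@dataclass
class DANNModel:
    """ANN I, the selected (m, d_index), ANN II, and the reference snapshot.

    The reference snapshot (normalized features, ANN I outputs, risk labels,
    ids of the training cohort) is what external participants are ranked
    against at prediction time.
    """

    ann1: RBFNetwork
    m: int
    d_index: int
    ann2: RBFNetwork
    normalization: NormalizationParams
    features: tuple[str, ...]
    ref_X: np.ndarray
    ref_ann1: np.ndarray
    ref_risk: np.ndarray
    ref_ids: np.ndarray
    threshold: float = DEFAULT_RISK_THRESHOLD
    seed: int = 0

    @property
    def dist_scale(self) -> float:
        return math.sqrt(len(self.features))

    # -- scoring ------------------------------------------------------------
    def score_internal(self) -> np.ndarray:
        """DANN scores of the stored training cohort (leave-self-out reference)."""
        tables = derivative_grid(self.ref_X, self.ref_ann1, self.ref_risk,
                                 m_range=(self.m,))
        table = _scale_table(tables[(self.m, self.d_index)], self.dist_scale)
        return self.ann2.predict(table)

    def score_external(self, cohort: CohortTable) -> np.ndarray:
        """Score an external cohort against the full training reference."""
        X = self.normalization.transform(cohort, self.features)
        ann1_out = self.ann1.predict(X)
        tables = derivative_grid(
            X, ann1_out, np.zeros(len(X)), m_range=(self.m,),
            ref_X=self.ref_X, ref_ann1=self.ref_ann1, ref_risk=self.ref_risk,
        )
        table = _scale_table(tables[(self.m, self.d_index)], self.dist_scale)
        return self.ann2.predict(table)

    def classify(self, scores: np.ndarray) -> np.ndarray:
        """Binary osteoporosis call: the score tracks BMD, so low score = at risk."""
        return (np.asarray(scores) < self.threshold).astype(int)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "ann1": self.ann1.to_dict(),
            "m": self.m,
            "d_index": self.d_index,
            "ann2": self.ann2.to_dict(),
            "normalization": {k: list(v) for k, v in self.normalization.bounds.items()},
            "features": list(self.features),
            "ref_X": self.ref_X.tolist(),
            "ref_ann1": self.ref_ann1.tolist(),
            "ref_risk": self.ref_risk.tolist(),
            "ref_ids": [str(i) for i in self.ref_ids],
            "threshold": self.threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DANNModel":
        return cls(
            ann1=RBFNetwork.from_dict(d["ann1"]),
            m=int(d["m"]),
            d_index=int(d["d_index"]),
            ann2=RBFNetwork.from_dict(d["ann2"]),
            normalization=NormalizationParams(
                {k: tuple(v) for k, v in d["normalization"].items()}
            ),
            features=tuple(d["features"]),
            ref_X=np.asarray(d["ref_X"], dtype=float),
            ref_ann1=np.asarray(d["ref_ann1"], dtype=float),
            ref_risk=np.asarray(d["ref_risk"], dtype=float),
            ref_ids=np.asarray(d["ref_ids"], dtype=object),
            threshold=float(d["threshold"]),
            seed=int(d["seed"]),
        )


@dataclass
class DANNDiagnostics:
    ann1_report: FitReport
    ann2_report: FitReport
    grid: pd.DataFrame                  # columns m, d_index, rho_verify
    rho_full: float                     # Spearman(DANN score, BMD) on the cohort
    split_sizes: tuple[int, int, int]


def optimize_division(
    X: np.ndarray,
    y: np.ndarray,
    risk: np.ndarray,
    ann1_out: np.ndarray,
    split,
    m_range=M_RANGE_DEFAULT,
    seed: int = 0,
    rbf_config: RBFConfig | None = None,
) -> tuple[int, int, RBFNetwork, FitReport, pd.DataFrame]:
    """Search (m, d_index) and fit the winning ANN II.

    Each candidate division yields a derivative-feature table; a candidate
    ANN II is fitted on the training rows and scored by the Spearman rho of
    its verification-set output against normalized BMD.  Ties break toward
    smaller (m, d_index).
    """
    dist_scale = math.sqrt(X.shape[1])
    tables = derivative_grid(X, ann1_out, risk, m_range=m_range)
    rows = []
    best = None
    for (m, d), table in sorted(tables.items()):
        T = _scale_table(table, dist_scale)
        net, report = fit_rbf(
            T[split.train], y[split.train], T[split.verify], y[split.verify],
            features=ANN2_FEATURES, config=rbf_config, seed=seed + 97 * m + d,
        )
        pred_ver = net.predict(T[split.verify])
        if np.std(pred_ver) == 0:
            rho = 0.0
        else:
            rho, _ = stats.spearmanr(pred_ver, y[split.verify])
        rows.append({"m": m, "d_index": d, "rho_verify": float(rho)})
        if best is None or rho > best[0] + 1e-12:
            best = (float(rho), m, d, net, report, T)
    rho_best, m, d, net, report, T = best
    evaluate_on(net, report, T[split.test], y[split.test])
    return m, d, net, report, pd.DataFrame(rows)


def train_dann(
    cohort: CohortTable,
    features,
    seed: int,
    m_range=M_RANGE_DEFAULT,
    rbf_config: RBFConfig | None = None,
    normalization: NormalizationParams | None = None,
) -> tuple[DANNModel, DANNDiagnostics]:
    """End-to-end DANN training on a cohort.

    Normalization is fitted on this cohort (unless supplied), ANN I on the
    2:1:1 training split, the (m, d_index) search and ANN II on the derivative
    features, and the full cohort becomes the stored reference snapshot.
    Rows with a missing value in any model feature are excluded.
    """
    features = tuple(features)
    mask = cohort.complete_cases(features)
    df = cohort.df[mask].reset_index(drop=True)
    sub = CohortTable(df, registry=cohort.registry, provenance=cohort.provenance)
    norm = normalization or fit_minmax(sub, (*features, "bmd"))
    X = norm.transform(sub, features)
    y = norm.apply(sub.bmd, "bmd")
    risk = sub.risk_labels().astype(float)

    split = split_2_1_1(len(sub), seed)
    ann1, ann1_report = fit_rbf(
        X[split.train], y[split.train], X[split.verify], y[split.verify],
        features=features, config=rbf_config, seed=seed,
    )
    evaluate_on(ann1, ann1_report, X[split.test], y[split.test])
    ann1_out = ann1.predict(X)

    m, d_index, ann2, ann2_report, grid = optimize_division(
        X, y, risk, ann1_out, split, m_range=m_range, seed=seed,
        rbf_config=rbf_config,
    )
    model = DANNModel(
        ann1=ann1, m=m, d_index=d_index, ann2=ann2, normalization=norm,
        features=features, ref_X=X, ref_ann1=ann1_out, ref_risk=risk,
        ref_ids=sub.ids, seed=seed,
    )
    scores = model.score_internal()
    rho_full, _ = stats.spearmanr(scores, y)
    diag = DANNDiagnostics(
        ann1_report=ann1_report, ann2_report=ann2_report, grid=grid,
        rho_full=float(rho_full), split_sizes=split.sizes(),
    )
    return model, diag
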