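"""Spearman screening of BMD-correlated items and collinearity flagging.

An item is retained for model integration when |rho| > 0.1 AND p < 0.01
against spine BMD (no multiple-testing correction — the fixed per-item rule
is deliberate).  Collinearity between candidate inputs is flagged at
|rho| > 0.3; when excluding collinear inputs, the lower-|rho| member of each
flagged pair is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MARKER, CohortTable

RHO_THRESHOLD = 0.1
P_THRESHOLD = 0.01
COLLINEARITY_THRESHOLD = 0.3

#: |rho| cut-points delimiting none / extremely-weak / weak / moderate / strong.
BAND_CUTS = (0.1, 0.2, 0.4, 0.7)
BAND_NAMES = ("none", "extremely-weak", "weak", "moderate", "strong")


class UndefinedCorrelationError(ValueError):
    pass


def spearman(x, y, permutation: int | None = None, seed: int = 0):
    """Spearman rho and two-sided p on pairwise-complete observations.

    Ties get average ranks; the p-value uses the t-approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.  ``permutation`` switches to a
    permutation p-value with that many shuffles (for small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise UndefinedCorrelationError("need >= 4 pairwise-complete observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("zero variance input")
    rho, p = stats.spearmanr(x, y)
    if permutation is not None:
        rng = np.random.default_rng(seed)
        ranks_x = stats.rankdata(x)
        ranks_y = stats.rankdata(y)
        obs = abs(np.corrcoef(ranks_x, ranks_y)[0, 1])
        hits = 0
        for _ in range(permutation):
            perm = rng.permutation(ranks_y)
            hits += abs(np.corrcoef(ranks_x, perm)[0, 1]) >= obs - 1e-12
        p = (hits + 1) / (permutation + 1)
    return float(rho), float(p)


def band_of(rho: float) -> str:
    """Verbal correlation band of |rho|."""
    a = abs(float(rho))
    if a > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    for cut, name in zip(BAND_CUTS, BAND_NAMES):
        if a < cut:
            return name
    return BAND_NAMES[-1]


@dataclass
class CorrelationRecord:
    item: str
    rho: float
    p: float
    band: str
    bmd_correlated: bool
    valid: bool = True


def screen_items(
    cohort: CohortTable,
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[CorrelationRecord]:
    """One correlation record per item (marker + each EI) against spine BMD."""
    bmd = cohort.bmd
    records = []
    for item in cohort.item_names:
        vals = cohort.df[item].to_numpy(dtype=float)
        try:
            rho, p = spearman(vals, bmd)
        except UndefinedCorrelationError:
            records.append(CorrelationRecord(item, float("nan"), float("nan"),
                                             "none", False, valid=False))
            continue
        flagged = abs(rho) > rho_threshold and p < p_threshold
        records.append(CorrelationRecord(item, rho, p, band_of(rho), flagged))
    return records


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class CollinearityMatrix:
    """Symmetric pairwise |rho| over candidate inputs, with flags at |rho| > 0.3."""

    items: tuple[str, ...]
    abs_rho: np.ndarray
    threshold: float = COLLINEARITY_THRESHOLD

    def value(self, a: str, b: str) -> float:
        i, j = self.items.index(a), self.items.index(b)
        return float(self.abs_rho[i, j])

    def flagged(self, a: str, b: str) -> bool:
        return a != b and self.value(a, b) > self.threshold

    def flagged_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.items)):
            for j in range(i + 1, len(self.items)):
                if self.abs_rho[i, j] > self.threshold:
                    out.append((self.items[i], self.items[j]))
        return out

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abs_rho, index=self.items, columns=self.items)


def collinearity(
    cohort: CohortTable,
    items=None,
    threshold: float = COLLINEARITY_THRESHOLD,
) -> CollinearityMatrix:
    """Pairwise |Spearman rho| matrix over marker + EIs (heatmap-ready)."""
    items = tuple(items) if items is not None else cohort.item_names
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    k = len(items)
    mat = np.eye(k)
    cols = [cohort.df[i].to_numpy(dtype=float) for i in items]
    for i in range(k):
        for j in range(i + 1, k):
            rho, _ = spearman(cols[i], cols[j])
            mat[i, j] = mat[j, i] = abs(rho)
    return CollinearityMatrix(items, mat, threshold)


def select_model_inputs(
    records: list[CorrelationRecord],
    matrix: CollinearityMatrix,
    mode: str = "noncollinear",
    max_eis: int | None = None,
    registry_order=None,
) -> list[str]:
    """Ordered model-input list: marker first, then screened EIs by |rho| descending.

    ``noncollinear`` drops the lower-|rho| member of every flagged pair;
    ``collinear`` keeps both.  Ties in |rho| break by registry order for
    determinism.
    """
    if mode not in ("noncollinear", "collinear"):
        raise ValueError(f"unknown mode {mode!r}")
    order_of = {}
    if registry_order is not None:
        order_of = {name: i for i, name in enumerate(registry_order)}
    candidates = [
        r for r in records if r.valid and r.bmd_correlated and r.item != MARKER
    ]
    candidates.sort(key=lambda r: (-abs(r.rho), order_of.get(r.item, 0), r.item))
    selected: list[str] = []
    for rec in candidates:
        if mode == "noncollinear":
            clash = any(
                rec.item in matrix.items and kept in matrix.items
                and matrix.flagged(rec.item, kept)
                for kept in selected
            )
            if clash:
                continue
        selected.append(rec.item)
        if max_eis is not None and len(selected) >= max_eis:
            break
    return [MARKER, *selected]
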