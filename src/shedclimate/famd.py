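"""Factor analysis of mixed data (FAMD), hierarchical clustering on
principal components (HCPC) and V-test cluster characterisation.

The housing table mixes quantitative variables (areas, heights, counts) and
qualitative ones (housing type, roof type, cooling equipment).  FAMD puts
both on a common footing: quantitative columns are standardised (population
variance), and each category indicator column is divided by the square root
of its category proportion and centred — the MCA weighting — so a rare
category carries the same total inertia as a common one.  A singular value
decomposition of the encoded matrix then yields components, of which the
smallest number explaining at least 70% of the variance (by default) is
retained.  Farms are clustered by Ward's method on the retained component
scores, the cut is chosen by the relative within-inertia gain between
successive cuts, and the partition is consolidated with Lloyd's k-means
iterations started from the hierarchical centroids (deterministic — no
random restarts).  Clusters are described by V-tests: standardised
deviations of the cluster mean (quantitative) or hypergeometric
over/under-representation of a category (qualitative) from the overall
value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "MixedDataMatrix",
    "FactorClusterModel",
    "famd_encode",
    "famd_decompose",
    "retain_components",
    "hcluster_ward",
    "kmeans_consolidate",
    "vtest_quantitative",
    "vtest_categorical",
    "vtest_table",
    "fit_housing_clusters",
]


@dataclass
class MixedDataMatrix:
    """FAMD-encoded design: standardised quantitative + weighted indicators."""

    X: np.ndarray                       # n × p encoded matrix
    row_ids: np.ndarray
    columns: pd.DataFrame               # variable, category, kind per column
    quantitative: list[str]
    qualitative: list[str]
    # per-column back-transform info (means/sds/proportions)
    meta: dict = field(default_factory=dict)


def famd_encode(table: pd.DataFrame,
                quantitative: list[str] | None = None,
                qualitative: list[str] | None = None,
                id_column: str | None = None) -> MixedDataMatrix:
    """Encode a mixed table for FAMD.

    Quantitative columns become ``(x − mean)/sd`` with the population
    (1/n) standard deviation; a constant column is an error naming the
    column.  Each category indicator column becomes ``(I − p)/√p`` where
    ``p`` is the category proportion, so the two blocks contribute on a
    comparable scale.  Column roles are inferred from dtypes when not given
    (object/category → qualitative).
    """
    if len(table) < 2:
        raise ValueError("need at least two rows")
    df = table.copy()
    row_ids = (df[id_column].to_numpy() if id_column and id_column in df
               else df.index.to_numpy())
    if quantitative is None or qualitative is None:
        cand = [c for c in df.columns if c != id_column]
        quantitative = quantitative or [
            c for c in cand if pd.api.types.is_numeric_dtype(df[c])]
        qualitative = qualitative or [
            c for c in cand if not pd.api.types.is_numeric_dtype(df[c])]
    if df[quantitative + qualitative].isna().any().any():
        raise ValueError("missing values are not supported")

    cols, colmeta, meta = [], [], {"means": {}, "sds": {}, "props": {}}
    for c in quantitative:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant quantitative column: {c!r} (zero sd)")
        cols.append((x - x.mean()) / sd)
        colmeta.append({"column": c, "variable": c, "category": None,
                        "kind": "quantitative"})
        meta["means"][c], meta["sds"][c] = x.mean(), sd
    for c in qualitative:
        cats = pd.unique(df[c].astype(str))
        if len(cats) < 2:
            raise ValueError(
                f"qualitative column {c!r} has fewer than 2 observed categories")
        for cat in sorted(cats):
            ind = (df[c].astype(str) == cat).to_numpy(dtype=float)
            p = ind.mean()
            w = ind / np.sqrt(p)
            cols.append(w - w.mean())
            colmeta.append({"column": f"{c}={cat}", "variable": c,
                            "category": cat, "kind": "qualitative"})
            meta["props"][(c, cat)] = p
    X = np.column_stack(cols)
    return MixedDataMatrix(X=X, row_ids=row_ids,
                           columns=pd.DataFrame(colmeta),
                           quantitative=list(quantitative),
                           qualitative=list(qualitative), meta=meta)


@dataclass
class FAMDResult:
    eigenvalues: np.ndarray          # squared singular values / n
    proportions: np.ndarray          # explained-variance shares, sum to 1
    scores: np.ndarray               # n × r row scores (U·s)
    loadings: np.ndarray             # p × r right singular vectors


def famd_decompose(matrix: MixedDataMatrix) -> FAMDResult:
    """SVD of the encoded matrix.

    Eigenvalues are squared singular values divided by n; scores are
    ``U @ diag(s)``, so ``scores @ loadings.T`` reconstructs the encoded
    matrix exactly when all components are kept.
    """
    X = matrix.X
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eig = s**2 / n
    total = eig.sum()
    proportions = eig / total if total > 0 else np.zeros_like(eig)
    return FAMDResult(eigenvalues=eig, proportions=proportions,
                      scores=U * s, loadings=Vt.T)


def retain_components(proportions, threshold: float = 0.70) -> int:
    """Smallest m whose cumulative explained-variance share ≥ ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    p = np.asarray(proportions, dtype=float)
    cum = np.cumsum(p)
    hits = np.nonzero(cum >= threshold - 1e-12)[0]
    if hits.size == 0:
        raise ValueError("proportions do not reach the threshold (do they sum to 1?)")
    return int(hits[0]) + 1


def _within_inertia(points: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        w += ((sub - sub.mean(axis=0))**2).sum()
    return w


def hcluster_ward(scores: np.ndarray, m: int,
                  k_range: tuple[int, int] = (2, 10)):
    """Ward linkage on the first ``m`` component scores + suggested cut.

    The suggested number of clusters maximises the ratio of successive
    within-inertia losses, ΔW(k)/ΔW(k+1) with ΔW(k) = W(k−1) − W(k), over
    ``k_range``: the best cut is the one after which further splitting
    stops paying.  Degenerate input (all points identical) suggests k = 1.

    Returns ``(linkage_matrix, suggested_k)``.
    """
    pts = np.asarray(scores, dtype=float)[:, :m]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    Z = linkage(pts, method="ward")
    if np.allclose(pts, pts[0]):
        return Z, 1
    kmax = min(k_range[1], n - 1)
    # within-inertia at each cut k = 1..kmax+1
    W = {1: _within_inertia(pts, np.zeros(n, dtype=int))}
    for k in range(2, kmax + 2):
        if k > n:
            W[k] = 0.0
        else:
            W[k] = _within_inertia(pts, fcluster(Z, k, criterion="maxclust"))
    best_k, best_ratio = None, -np.inf
    for k in range(max(k_range[0], 2), kmax + 1):
        d1 = W[k - 1] - W[k]
        d2 = W[k] - W[k + 1]
        ratio = np.inf if d2 <= 1e-12 else d1 / d2
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return Z, int(best_k)


def kmeans_consolidate(scores: np.ndarray, k: int,
                       init_labels: np.ndarray | None = None,
                       linkage_matrix: np.ndarray | None = None,
                       max_iter: int = 100) -> np.ndarray:
    """Lloyd iterations from the hierarchical-cut centroids.

    Starts from the centroids of ``init_labels`` (or of the ``k``-cluster
    cut of ``linkage_matrix``), reassigns points to the nearest centroid
    and recomputes until the assignment is a fixed point or ``max_iter``
    rounds.  If a cluster empties, its centroid is re-seeded at the point
    farthest from its assigned centroid.  Deterministic given the
    initialisation.  Returns labels 1..k.
    """
    pts = np.asarray(scores, dtype=float)
    n = pts.shape[0]
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if init_labels is None:
        if linkage_matrix is None:
            raise ValueError("provide init_labels or linkage_matrix")
        init_labels = fcluster(linkage_matrix, k, criterion="maxclust")
    labels = np.asarray(init_labels)
    uniq = np.unique(labels)
    centroids = np.vstack([pts[labels == u].mean(axis=0) for u in uniq])
    assign = np.searchsorted(uniq, labels)
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centroids[None, :, :])**2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        for j in range(k):
            if not np.any(new_assign == j):  # empty cluster: re-seed farthest point
                far = d2[np.arange(n), new_assign].argmax()
                centroids[j] = pts[far]
                new_assign[far] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            centroids[j] = pts[assign == j].mean(axis=0)
    return assign + 1


def vtest_quantitative(values, labels) -> pd.DataFrame:
    """V-test of each cluster's mean against the overall mean.

    v = (x̄_k − x̄) / sqrt( ((N − n_k)/(N − 1)) · s²/n_k ) with s the
    population standard deviation over all N observations; two-sided p from
    the standard normal.  Zero overall variance yields NaN (not applicable).
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    N = x.size
    xbar, s = x.mean(), x.std(ddof=0)
    rows = []
    for lab in np.unique(labels):
        sub = x[labels == lab]
        nk = sub.size
        if s == 0 or N == nk:
            v, p = np.nan, np.nan
        else:
            se = np.sqrt(((N - nk) / (N - 1)) * s**2 / nk)
            v = (sub.mean() - xbar) / se
            p = 2 * stats.norm.sf(abs(v))
        rows.append({"cluster": lab, "n": nk, "group_mean": sub.mean(),
                     "group_sd": sub.std(ddof=0), "overall_mean": xbar,
                     "overall_sd": s, "v": v, "p": p})
    return pd.DataFrame(rows)


def vtest_categorical(categories, labels, category=None) -> pd.DataFrame:
    """Hypergeometric V-test of category representation in each cluster.

    For a cluster of size n_k containing x of the K category members among
    N farms, the tail probability of drawing ≥ x (over-representation) or
    ≤ x (under-representation) without replacement gives the reported
    two-sided p (twice the smaller tail, capped at 1); v is the signed
    standard-normal quantile of the smaller tail, positive when the
    category is over-represented.
    """
    cat = pd.Series(categories).astype(str).to_numpy()
    labels = np.asarray(labels)
    N = cat.size
    which = sorted(set(cat)) if category is None else [str(category)]
    rows = []
    for c in which:
        K = int((cat == c).sum())
        for lab in np.unique(labels):
            mask = labels == lab
            nk = int(mask.sum())
            x = int((cat[mask] == c).sum())
            p_over = stats.hypergeom.sf(x - 1, N, K, nk)
            p_under = stats.hypergeom.cdf(x, N, K, nk)
            tail = min(p_over, p_under)
            sign = 1.0 if x / nk >= K / N else -1.0
            v = sign * stats.norm.isf(tail)
            rows.append({"cluster": lab, "category": c, "n": nk,
                         "group_pct": 100 * x / nk, "overall_pct": 100 * K / N,
                         "count": x, "v": v, "p": min(1.0, 2 * tail)})
    return pd.DataFrame(rows)


def vtest_table(table: pd.DataFrame, labels,
                quantitative: list[str], qualitative: list[str]) -> pd.DataFrame:
    """Combined V-test characterisation table across all variables."""
    parts = []
    for c in quantitative:
        t = vtest_quantitative(table[c].to_numpy(), labels)
        t.insert(0, "variable", c)
        t["category"] = None
        parts.append(t)
    for c in qualitative:
        t = vtest_categorical(table[c], labels)
        t.insert(0, "variable", c)
        parts.append(t)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["cluster", "variable"]).reset_index(drop=True)


@dataclass
class FactorClusterModel:
    """FAMD + HCPC outputs for one housing table."""

    encoded: MixedDataMatrix
    eigenvalues: np.ndarray
    proportions: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    retained: int
    linkage: np.ndarray
    suggested_k: int
    labels: np.ndarray
    vtests: pd.DataFrame

    @property
    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"farm_id": self.encoded.row_ids,
                             "cluster": self.labels})


def fit_housing_clusters(table: pd.DataFrame,
                         variance_threshold: float = 0.70,
                         k: int | None = None,
                         id_column: str = "farm_id",
                         quantitative: list[str] | None = None,
                         qualitative: list[str] | None = None,
                         drop_constant_qualitative: bool = False
                         ) -> FactorClusterModel:
    """Full HCPC pipeline: encode → decompose → retain → Ward → k-means → V-tests.

    ``k`` overrides the suggested number of clusters.  With
    ``drop_constant_qualitative`` a single-category qualitative variable is
    dropped with a warning instead of raising (useful on small generated
    tables where a rare category may not occur).
    """
    if quantitative is None:
        from .synthetic import QUANTITATIVE_VARS
        quantitative = [c for c in QUANTITATIVE_VARS if c in table.columns]
    if qualitative is None:
        from .synthetic import QUALITATIVE_VARS
        qualitative = [c for c in QUALITATIVE_VARS if c in table.columns]
    if drop_constant_qualitative:
        keep = []
        for c in qualitative:
            if table[c].astype(str).nunique() >= 2:
                keep.append(c)
            else:
                warnings.warn(f"dropping single-category qualitative column {c!r}")
        qualitative = keep
    enc = famd_encode(table, quantitative, qualitative,
                      id_column=id_column if id_column in table.columns else None)
    dec = famd_decompose(enc)
    m = retain_components(dec.proportions, variance_threshold)
    Z, suggested = hcluster_ward(dec.scores, m)
    k_final = k or suggested
    if k_final < 2:
        labels = np.ones(len(table), dtype=int)
    else:
        labels = kmeans_consolidate(dec.scores[:, :m], k_final, linkage_matrix=Z)
    vt = vtest_table(table, labels, quantitative, qualitative)
    return FactorClusterModel(encoded=enc, eigenvalues=dec.eigenvalues,
                              proportions=dec.proportions, scores=dec.scores,
                              loadings=dec.loadings, retained=m, linkage=Z,
                              suggested_k=suggested, labels=labels, vtests=vt)
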