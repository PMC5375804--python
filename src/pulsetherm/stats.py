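"""Multivariate statistics over feature tables.

Two procedures quantify between-class separation before any classifier is
trained:

* pairwise two-sample Hotelling T-squared tests on the class mean vectors
  (the two-group special case of one-way MANOVA, with the exact F transform
  of the statistic), and
* canonical discriminant analysis (CDA): the generalized eigenproblem of
  between-class versus pooled within-class scatter, returning scores scaled
  so the pooled within-class covariance of the canonical variates is the
  identity.

Feature tables are plain pandas DataFrames with ``sample_id`` and ``class``
columns followed by numeric feature columns.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

META_COLUMNS = ("sample_id", "class")


def feature_matrix(table: pd.DataFrame, columns: list[str] | None = None):
    """Split a feature table into (X, labels, feature_names)."""
    if columns is None:
        columns = [c for c in table.columns if c not in META_COLUMNS]
    X = table[columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains missing or non-finite values")
    labels = table["class"].to_numpy()
    return X, labels, list(columns)


@dataclass(frozen=True)
class PairwiseTestResult:
    """Hotelling T-squared test between one pair of classes."""

    class_a: str
    class_b: str
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


@dataclass
class CanonicalScores:
    """Canonical discriminant scores and the associated eigenvalues."""

    scores: np.ndarray  # (n, m), m = min(p, k-1)
    eigenvalues: np.ndarray  # non-increasing, >= 0
    labels: np.ndarray
    loadings: np.ndarray  # (p, m) raw-space coefficient vectors


def hotelling_t2(group1: np.ndarray, group2: np.ndarray,
                 class_a: str = "a", class_b: str = "b") -> PairwiseTestResult:
    """Two-sample Hotelling T-squared test with pooled covariance.

    ``T2 = (n1 n2 / (n1 + n2)) d' S_pooled^-1 d`` with ``d`` the mean
    difference; ``F = T2 (n1 + n2 - p - 1) / ((n1 + n2 - 2) p)`` follows an
    F(p, n1 + n2 - p - 1) distribution under the null of equal means. For
    p = 1 this reduces to the squared pooled-variance t statistic.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, p = g1.shape
    n2, p2 = g2.shape
    if p != p2:
        raise ValueError("groups must share the feature dimension")
    if n1 + n2 <= p + 1:
        raise ValueError(
            f"n1+n2={n1 + n2} too small for p={p} features (need n1+n2 > p+1)"
        )
    d = g1.mean(axis=0) - g2.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(g1, rowvar=False, ddof=1).reshape(p, p)
                + (n2 - 1) * np.cov(g2, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        solved = linalg.solve(s_pooled, d, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "pooled covariance is singular; reduce the feature set or apply shrinkage"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ solved)
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return PairwiseTestResult(
        class_a=class_a, class_b=class_b, t2=max(t2, 0.0),
        f_stat=f_stat, df1=df1, df2=df2, p_value=p_value,
    )


def pairwise_hotelling(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, list[PairwiseTestResult]]:
    """Hotelling tests for every unordered class pair.

    Returns a symmetric p-value matrix (diagonal 1) indexed by class name,
    plus the per-pair results. Pairs whose pooled covariance is singular are
    recorded with NaN p-values rather than aborting the sweep.
    """
    X, labels, _ = feature_matrix(table, columns)
    classes = sorted(pd.unique(labels))
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    pvals = pd.DataFrame(1.0, index=classes, columns=classes, dtype=float)
    results: list[PairwiseTestResult] = []
    for a, b in itertools.combinations(classes, 2):
        try:
            res = hotelling_t2(X[labels == a], X[labels == b], a, b)
        except (ValueError, linalg.LinAlgError) as exc:
            warnings.warn(f"Hotelling test {a} vs {b} failed: {exc}")
            res = PairwiseTestResult(a, b, np.nan, np.nan, 0, 0, np.nan)
        results.append(res)
        pvals.loc[a, b] = pvals.loc[b, a] = res.p_value
    return pvals, results


def canonical_discriminant(
    table: pd.DataFrame, columns: list[str] | None = None
) -> CanonicalScores:
    """Canonical discriminant analysis of a labelled feature table.

    Solves the generalized eigenproblem of between-class scatter against the
    pooled within-class covariance. Variates are ordered by decreasing
    eigenvalue; scores are centred on the grand mean and scaled so the pooled
    within-class covariance of the scores is the identity. The sign of each
    eigenvector is fixed so its first non-zero loading is positive.
    """
    X, labels, _ = feature_matrix(table, columns)
    n, p = X.shape
    classes = sorted(pd.unique(labels))
    k = len(classes)
    if k < 2:
        raise ValueError("canonical discriminant analysis needs >= 2 classes")
    grand = X.mean(axis=0)
    s_within = np.zeros((p, p))
    s_between = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        nc = len(Xc)
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        s_within += dev.T @ dev
        dm = (mc - grand)[:, None]
        s_between += nc * (dm @ dm.T)

    try:
        eigvals, eigvecs = linalg.eigh(s_between, s_within)
    except linalg.LinAlgError:
        # degenerate within-class scatter: fall back to a ridge-shrunk
        # scatter so the eigenproblem is well posed
        warnings.warn("within-class scatter is singular; applying shrinkage")
        shrink = 1e-6 * np.trace(s_within) / p
        eigvals, eigvecs = linalg.eigh(
            s_between, s_within + shrink * np.eye(p)
        )
    order = np.argsort(eigvals)[::-1]
    m = min(p, k - 1)
    eigvals = np.clip(eigvals[order][:m], 0.0, None)
    # scipy normalises v' S_within v = 1; rescaling by sqrt(n - k) gives the
    # canonical scaling v' W_pooled v = 1 (identity pooled within-class
    # covariance of the scores) without changing the eigenvalues
    vecs = eigvecs[:, order][:, :m] * np.sqrt(n - k)
    # fix signs so the first non-zero loading of each variate is positive
    for j in range(m):
        nz = np.flatnonzero(np.abs(vecs[:, j]) > 1e-12)
        if nz.size and vecs[nz[0], j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = (X - grand) @ vecs
    return CanonicalScores(
        scores=scores, eigenvalues=eigvals, labels=labels, loadings=vecs
    )
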