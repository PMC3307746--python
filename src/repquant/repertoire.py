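"""Repertoire-diversity inference: Ward clustering, PCA, factorial GLM.

The repertoire matrix (samples x CDR3-length bins over all TRBV groups at
once) is analysed three ways, mirroring a classic SPSS workflow:

* agglomerative hierarchical clustering under Ward's minimum-variance
  criterion on squared Euclidean distances — tissues with shared repertoire
  structure cluster together;
* principal component analysis of the correlation matrix, unrotated, with
  Kaiser (eigenvalue > 1) retention;
* a fully factorial fixed-effects GLM (two-way ANOVA, Type-III sums of
  squares) of each retained component on colonisation status and tissue,
  with Bonferroni control across components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .spectra import RepertoireMatrix

__all__ = [
    "Dendrogram",
    "ComponentScores",
    "GLMTable",
    "ward_cluster",
    "pca_retain",
    "factorial_glm",
    "bonferroni_alpha",
    "lsd_posthoc",
]


# ---------------------------------------------------------------------------
# Ward hierarchical clustering

@dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage layout.

    ``linkage`` rows are ``(id_a, id_b, height, size)`` with heights equal to
    the increase in within-cluster error sum of squares (the Ward criterion in
    squared-Euclidean units); leaves are ids ``0..n-1`` in ``labels`` order and
    merge m creates id ``n+m``.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows of (id_a, id_b, height, size)")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) at the k-cluster level."""
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights (leaves at 0)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            parts = []
            for c in (int(a), int(b)):
                parts.append(f"{node(c)}:{h - height[c]:.10g}")
            height[i] = h
            return "(" + ",".join(parts) + ")"

        for m in range(n - 1):
            a, b, h, _ = self.linkage[m]
            height[n + m] = h
        root = node(2 * n - 2)
        return root + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["cluster_a", "cluster_b", "height", "size"]
        )


def ward_cluster(matrix: RepertoireMatrix | pd.DataFrame) -> Dendrogram:
    """Ward's method on squared Euclidean distances, greedy agglomeration.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squared Euclidean distances to centroids is fused;
    the recorded height is that ESS increase,
    ``(n_a n_b)/(n_a + n_b) * ||c_a - c_b||^2``.  Ties are broken towards the
    lexicographically smallest (id_a, id_b) pair, so the result is
    deterministic for a fixed row order.
    """
    values = matrix.values if isinstance(matrix, RepertoireMatrix) else matrix
    X = np.asarray(values, dtype=float)
    labels = [str(i) for i in values.index] if hasattr(values, "index") else [
        str(i) for i in range(X.shape[0])
    ]
    n = X.shape[0]
    if n < 2:
        raise ValueError("ward_cluster needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")

    centroids: dict[int, np.ndarray] = {i: X[i].copy() for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for m in range(n - 1):
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                ni, nj = sizes[i], sizes[j]
                diff = centroids[i] - centroids[j]
                cost = (ni * nj) / (ni + nj) * float(diff @ diff)
                if best is None or cost < best[0] or (
                    cost == best[0] and (i, j) < (best[1], best[2])
                ):
                    best = (cost, i, j)
        cost, i, j = best  # type: ignore[misc]
        ni, nj = sizes[i], sizes[j]
        centroids[next_id] = (ni * centroids[i] + nj * centroids[j]) / (ni + nj)
        sizes[next_id] = ni + nj
        del centroids[i], centroids[j]
        active = [a for a in active if a not in (i, j)] + [next_id]
        Z[m] = (i, j, cost, ni + nj)
        next_id += 1
    return Dendrogram(linkage=Z, labels=labels)


# ---------------------------------------------------------------------------
# PCA with Kaiser retention

@dataclass
class ComponentScores:
    """Unrotated correlation-matrix PCA with eigenvalue-floor retention.

    ``eigenvalues`` holds the full non-increasing spectrum (summing to the
    number of analysed variables); ``scores``/``loadings`` cover only the
    retained components.  Columns with zero variance cannot be correlated and
    are dropped before the decomposition (listed in ``dropped_columns``).
    """

    eigenvalues: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    retained: int
    criterion: float
    dropped_columns: list = field(default_factory=list)


def pca_retain(
    matrix: RepertoireMatrix | pd.DataFrame, criterion: float = 1.0
) -> ComponentScores:
    """Principal components of the correlation matrix of all variables at once.

    Variables are z-scored and the exact eigendecomposition of their
    correlation matrix is taken (no iterative extraction); components with
    eigenvalue above ``criterion`` (default 1, the Kaiser rule) are retained.
    Scores are centred; eigenvector signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    values = matrix.values if isinstance(matrix, RepertoireMatrix) else matrix
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("pca_retain needs at least 2 samples")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(values.columns, keep) if not k]
    if not keep.any():
        raise ValueError("all columns have zero variance; nothing to decompose")
    if dropped:
        warnings.warn(
            f"pca_retain: dropped {len(dropped)} zero-variance column(s)", stacklevel=2
        )
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / sd[keep]
    R = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest |loading| positive
    for c in range(eigvec.shape[1]):
        col = eigvec[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, c] = -col
    retained = int((eigval > criterion).sum())
    n_show = max(retained, 1)
    comp_names = [f"PC{i + 1}" for i in range(n_show)]
    scores = pd.DataFrame(
        Z @ eigvec[:, :n_show], index=values.index, columns=comp_names
    )
    kept_cols = [c for c, k in zip(values.columns, keep) if k]
    loadings = pd.DataFrame(
        eigvec[:, :n_show] * np.sqrt(eigval[:n_show]),
        index=kept_cols,
        columns=comp_names,
    )
    return ComponentScores(
        eigenvalues=eigval,
        scores=scores,
        loadings=loadings,
        retained=retained,
        criterion=criterion,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# factorial GLM with Bonferroni control

def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not 0 < family_alpha < 1:
        raise ValueError(f"family_alpha must be in (0, 1), got {family_alpha}")
    if int(n_tests) < 1 or int(n_tests) != n_tests:
        raise ValueError(f"n_tests must be a positive integer, got {n_tests}")
    return family_alpha / int(n_tests)


@dataclass
class GLMTable:
    """Per-component ANOVA p-values with the Bonferroni per-test alpha."""

    table: pd.DataFrame
    family_alpha: float
    n_tests: int

    @property
    def per_test_alpha(self) -> float:
        return bonferroni_alpha(self.family_alpha, self.n_tests)

    def significant(self, term: str) -> pd.Series:
        return self.table[f"{term}_p"] < self.per_test_alpha


_TERMS = ("status", "tissue")


def factorial_glm(
    scores: ComponentScores | pd.DataFrame,
    meta: pd.DataFrame,
    n_components: int = 5,
    family_alpha: float = 0.05,
) -> GLMTable:
    """Fully factorial fixed-effects GLM of component scores on status x tissue.

    For each of the first ``n_components`` retained components an OLS model
    ``score ~ status * tissue`` (sum-to-zero contrasts, Type-III sums of
    squares) yields F-tests for the corrected model, each main effect and the
    interaction.  The per-test alpha is ``family_alpha / n_components``.  A
    factor observed at a single level is dropped with a warning.
    """
    sc = scores.scores if isinstance(scores, ComponentScores) else scores
    if not sc.index.equals(meta.index):
        meta = meta.loc[sc.index]
    n_comp = min(n_components, sc.shape[1])
    terms = []
    for t in _TERMS:
        if meta[t].nunique() >= 2:
            terms.append(t)
        else:
            warnings.warn(
                f"factorial_glm: factor {t!r} has a single level and was dropped",
                stacklevel=2,
            )
    if not terms:
        raise ValueError("no factor with >=2 levels; nothing to test")
    rhs = " * ".join(f"C({t}, Sum)" for t in terms)
    with_interaction = len(terms) == 2

    rows = []
    for comp in sc.columns[:n_comp]:
        df = meta.copy()
        df["score"] = sc[comp].to_numpy()
        res = smf.ols(f"score ~ {rhs}", data=df).fit()
        aov = sm.stats.anova_lm(res, typ=3)
        row = {"component": comp, "model_F": res.fvalue, "model_p": res.f_pvalue}
        for t in _TERMS:
            key = f"C({t}, Sum)"
            if t in terms:
                row[f"{t}_F"] = aov.loc[key, "F"]
                row[f"{t}_p"] = aov.loc[key, "PR(>F)"]
            else:
                row[f"{t}_F"] = np.nan
                row[f"{t}_p"] = np.nan
        if with_interaction:
            key = "C(status, Sum):C(tissue, Sum)"
            row["interaction_F"] = aov.loc[key, "F"]
            row["interaction_p"] = aov.loc[key, "PR(>F)"]
        else:
            row["interaction_F"] = np.nan
            row["interaction_p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("component")
    return GLMTable(table=table, family_alpha=family_alpha, n_tests=n_comp)


def lsd_posthoc(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Fisher's least-significant-difference pairwise comparisons.

    Unadjusted pairwise t-tests on group means using the pooled one-way ANOVA
    mean-square error; reported for inspection, never used for the headline
    Bonferroni-controlled significance calls.
    """
    from scipy import stats

    y = np.asarray(values, dtype=float)
    g = pd.Series(list(groups))
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("lsd_posthoc needs >=2 groups")
    means = {lv: y[(g == lv).to_numpy()].mean() for lv in levels}
    ns = {lv: int((g == lv).sum()) for lv in levels}
    sse = sum(
        float(((y[(g == lv).to_numpy()] - means[lv]) ** 2).sum()) for lv in levels
    )
    df_err = len(y) - len(levels)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom for LSD")
    mse = sse / df_err
    rows = []
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            a, b = levels[a_i], levels[b_i]
            se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
            t = (means[a] - means[b]) / se if se > 0 else np.inf
            p = 2 * stats.t.sf(abs(t), df_err)
            rows.append(
                {"group_a": a, "group_b": b, "diff": means[a] - means[b],
                 "t": t, "df": df_err, "p": p}
            )
    return pd.DataFrame(rows)
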