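"""Descriptive and exploratory analyses of feature tables.

PCA of the standardized descriptor matrix, coefficient-of-variation
summaries per cultivar × year (trait stability across seasons),
Ward-linkage hierarchical clustering of cultivar mean phenotypes with
Newick export, and violin-plot summaries (kernel density + quartiles)
for year-to-year comparisons.

Features are z-standardized (sample sd, n−1) before PCA and clustering:
the descriptor catalogs mix mm², mm and unitless quantities, so
raw-covariance analyses would be dominated by the largest unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .features import FeatureTable

#: groups with |mean| below this have an undefined CV
CV_MEAN_FLOOR = 1e-12


@dataclass
class PcaResult:
    scores: pd.DataFrame  # instances × components, with cultivar/year columns
    loadings: pd.DataFrame  # features × components, unit-norm columns
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score with sample (n−1) sd; returns (Z, keep_mask)."""
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def pca(table: FeatureTable, n_components: int | None = None) -> PcaResult:
    """PCA of the z-standardized descriptor matrix.

    Constant features are dropped with a warning before standardization.
    Scores carry the cultivar and year columns for score-plot export.
    """
    X = table.matrix()
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 instances")
    Z, keep = _standardize(X)
    names = [n for n, k in zip(table.feature_names, keep) if k]
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant features before PCA: {dropped}", stacklevel=2)
    n_components = n_components or min(Z.shape)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Z)
    comp_names = [f"PC{i+1}" for i in range(model.n_components_)]
    score_df = pd.DataFrame(scores, columns=comp_names)
    score_df.insert(0, "cultivar", table.df["cultivar"].to_numpy())
    score_df.insert(1, "year", table.df["year"].to_numpy())
    loadings = pd.DataFrame(model.components_.T, index=names, columns=comp_names)
    return PcaResult(
        scores=score_df,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_features=dropped,
    )


def cv_by_year(table: FeatureTable, min_group_size: int = 3) -> pd.DataFrame:
    """Coefficient of variation (sample sd / |mean|) per cultivar × year × feature.

    Long format with an extra ``stable_mean_cv`` summary attribute: the
    mean CV per feature across cultivars and years — low values flag
    environmentally stable traits.  Groups smaller than
    ``min_group_size`` or with near-zero mean yield NA with a warning.
    """
    rows = []
    small = []
    for (cultivar, year), grp in table.df.groupby(["cultivar", "year"]):
        n = len(grp)
        for feat in table.feature_names:
            x = grp[feat].to_numpy(float)
            if n < min_group_size:
                cv = np.nan
            else:
                mean = x.mean()
                cv = np.nan if abs(mean) < CV_MEAN_FLOOR else x.std(ddof=1) / abs(mean)
            rows.append(
                {"cultivar": cultivar, "year": year, "feature": feat, "cv": cv, "n": n}
            )
        if n < min_group_size:
            small.append((cultivar, year))
    if small:
        warnings.warn(f"groups below {min_group_size} samples, CV set to NA: {small}",
                      stacklevel=2)
    out = pd.DataFrame(rows)
    out.attrs["stability"] = out.groupby("feature")["cv"].mean().sort_values()
    return out


@dataclass
class DendrogramResult:
    linkage_matrix: np.ndarray
    cultivars: list[str]
    newick: str
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    bl_l = node.dist - node.left.dist
    bl_r = node.dist - node.right.dist
    return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"


def cultivar_dendrogram(
    fruit: FeatureTable, leaf: FeatureTable, endocarp: FeatureTable
) -> DendrogramResult:
    """Ward/Euclidean clustering of per-cultivar mean phenotype vectors.

    Each cultivar is represented by the mean of its standardized
    descriptors concatenated across the three organs; cultivars missing
    an organ are excluded with a warning.
    """
    tables = {"fruit": fruit, "leaf": leaf, "endocarp": endocarp}
    common = sorted(set.intersection(*(set(t.df["cultivar"]) for t in tables.values())))
    dropped = sorted(set.union(*(set(t.df["cultivar"]) for t in tables.values())) - set(common))
    if dropped:
        warnings.warn(f"cultivars missing an organ, excluded: {dropped}", stacklevel=2)
    if len(common) < 3:
        raise ValueError("need at least 3 cultivars for a dendrogram")
    blocks = []
    for t in tables.values():
        Z, keep = _standardize(t.matrix())
        df = pd.DataFrame(Z, index=t.df["cultivar"].to_numpy())
        blocks.append(df.groupby(level=0).mean().loc[common])
    means = pd.concat(blocks, axis=1).to_numpy()
    lm = linkage(means, method="ward", metric="euclidean")
    assert np.all(np.diff(lm[:, 2]) >= -1e-9), "Ward heights must be non-decreasing"
    tree = to_tree(lm)
    newick = _to_newick(tree, common) + ";"
    leaf_order = [common[i] for i in tree.pre_order(lambda n: n.id) if i < len(common)]
    return DendrogramResult(
        linkage_matrix=lm, cultivars=common, newick=newick, leaf_order=leaf_order
    )


@dataclass
class ViolinSummary:
    group: dict
    median: float
    q1: float
    q3: float
    grid: np.ndarray | None  # density support (None below 5 points)
    density: np.ndarray | None
    n: int
    n_outliers_removed: int


def violin_summary(
    table: FeatureTable,
    feature: str,
    by_year: bool = True,
    grid_size: int = 128,
) -> list[ViolinSummary]:
    """Kernel-density + quartile summaries per cultivar (and year).

    Outliers beyond 1.5×IQR of their group are excluded from the density
    (quartiles are computed on the full group).  Groups below 5 points
    get quartiles only.  Gaussian kernel, Silverman bandwidth, 128-point
    support grid.
    """
    if feature not in table.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    keys = ["cultivar", "year"] if by_year else ["cultivar"]
    out = []
    for key, grp in table.df.groupby(keys):
        x = grp[feature].to_numpy(float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        kept = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
        if len(x) >= 5 and np.ptp(kept) > 0:
            kde = gaussian_kde(kept, bw_method="silverman")
            lo, hi = kept.min() - kde.factor * kept.std(ddof=1) * 3, kept.max() + kde.factor * kept.std(ddof=1) * 3
            grid = np.linspace(lo, hi, grid_size)
            density = kde(grid)
        else:
            grid = density = None
        out.append(
            ViolinSummary(
                group=dict(zip(keys, key if isinstance(key, tuple) else (key,))),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                grid=grid,
                density=density,
                n=len(x),
                n_outliers_removed=int(len(x) - len(kept)),
            )
        )
    return out


def violin_summary_frame(summaries: list[ViolinSummary]) -> pd.DataFrame:
    """Flatten violin summaries to a long CSV-ready frame."""
    rows = []
    for s in summaries:
        base = {**s.group, "median": s.median, "q1": s.q1, "q3": s.q3,
                "n": s.n, "n_outliers_removed": s.n_outliers_removed}
        if s.grid is None:
            rows.append({**base, "grid": np.nan, "density": np.nan})
        else:
            for g, d in zip(s.grid, s.density):
                rows.append({**base, "grid": g, "density": d})
    return pd.DataFrame(rows)
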