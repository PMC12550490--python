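"""Phylogenetic generalized least squares under Brownian motion.

Residual covariance is proportional to the Brownian matrix C whose entries
are shared root-to-MRCA path lengths on the species tree; estimation is
exact GLS, beta = (X' C^-1 X)^-1 X' C^-1 y, delegated to statsmodels with
sigma = C.  Tukey honestly-significant-difference contrasts on a fitted
factor use the studentized-range distribution with the GLS covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range


def brownian_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance matrix C_ij = shared root-to-MRCA path length.

    Returns (C, taxon labels in matrix order).  Rejects negative branch
    lengths; a star tree of depth 1 yields the identity.
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label.replace(" ", "_") if lf.taxon else str(id(lf)) for lf in leaves]
    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)
    n = len(leaves)
    C = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i in range(n):
        C[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = depth[mrca]
    return C, labels


@dataclass
class ComparativeDataset:
    """Ultrametric tree plus per-species traits/labels, rows matched to taxa."""

    tree: dendropy.Tree
    table: pd.DataFrame  # indexed by species

    C: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if "species" in self.table.columns:
            self.table = self.table.set_index("species")
        C, labels = brownian_covariance(self.tree)
        missing = set(labels) - set(self.table.index)
        if missing:
            raise ValueError(f"species missing from table: {sorted(missing)}")
        self.table = self.table.loc[labels]
        self.C = C


@dataclass
class PGLSFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    df_resid: int
    nobs: int
    cov_params: pd.DataFrame
    formula: str


def pgls_fit(
    dataset: ComparativeDataset,
    response: str,
    predictors: list[str],
    subset: pd.Series | None = None,
) -> PGLSFit:
    """GLS regression of ``response`` on ``predictors`` with Brownian C.

    Categorical predictors (e.g. status) are dummy-coded with the first
    level as baseline.  ``subset`` is a boolean mask over species (e.g. the
    at-risk-only model); C is subset accordingly.
    """
    tab = dataset.table
    C = dataset.C
    if subset is not None:
        mask = subset.loc[tab.index].to_numpy(dtype=bool) if isinstance(subset, pd.Series) else np.asarray(subset)
        tab = tab[mask]
        C = C[np.ix_(mask, mask)]
    y = tab[response].to_numpy(dtype=float)
    cols = {}
    for p in predictors:
        col = tab[p]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols[f"{p}[{lev}]"] = (col == lev).astype(float).to_numpy()
        else:
            cols[p] = col.to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(tab)), **cols})
    if len(tab) <= X.shape[1]:
        raise ValueError("not enough species for the number of predictors")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    model = sm.GLS(y, X.to_numpy(), sigma=C)
    res = model.fit()
    names = list(X.columns)
    return PGLSFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        sigma2=float(res.mse_resid),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
        formula=f"{response} ~ {' + '.join(predictors)}",
    )


def tukey_hsd(
    y: np.ndarray,
    groups: np.ndarray,
    C: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise Tukey HSD contrasts of (GLS-)adjusted group means.

    Fits means by GLS with covariance C (identity when None), then compares
    all level pairs with studentized-range adjusted p-values.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two factor levels")
    X = np.column_stack([(groups == lev).astype(float) for lev in levels])
    n = len(y)
    if C is None:
        C = np.eye(n)
    res = sm.GLS(y, X, sigma=C).fit()
    means = res.params
    V = res.cov_params()
    df = n - k
    rows = []
    scale = max(1.0, float(np.max(np.abs(means))))
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        se = float(np.sqrt(max(V[i, i] + V[j, j] - 2 * V[i, j], 0.0)))
        if se <= 1e-12 * scale:  # zero residual variance: only sign matters
            q = 0.0 if abs(diff) <= 1e-12 * scale else np.inf
        else:
            q = abs(diff) / (se / np.sqrt(2.0))
        p = float(np.clip(studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append({"group1": levels[i], "group2": levels[j], "diff": float(diff), "se": se, "q": float(q), "p_adj": p})
    return pd.DataFrame(rows)


def tukey_from_fit(dataset: ComparativeDataset, response: str, factor: str = "status") -> pd.DataFrame:
    """HSD contrasts of a response across a factor, under the Brownian C."""
    tab = dataset.table
    return tukey_hsd(tab[response].to_numpy(dtype=float), tab[factor].to_numpy(), C=dataset.C)
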