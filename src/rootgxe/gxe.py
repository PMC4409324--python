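"""AMMI and GGE decompositions of genotype x environment tables.

AMMI ("mean polish") removes the grand mean and both main effects, then takes
the SVD of the doubly-centered interaction residual:

    Y_ge = mu + G_g + E_e + sum_k lambda_k alpha_gk gamma_ek + eps_ge

GGE instead standardizes each environment column (center, scale by its SD)
and takes the SVD of the standardized matrix, so the multiplicative scores
carry the genotype main effect together with the interaction — the
"location standardized" model of which-won-where biplots.

Both are exposed as scikit-learn style estimators with fitted attributes
(`singular_values_`, `genotype_scores_`, ...) plus thin functional wrappers,
alongside an EM-style low-rank imputer for missing cells and hierarchical
clustering of the standardized genotype / environment profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# decomposition containers


@dataclass
class GxEDecomposition:
    """Full multiplicative decomposition of a genotype x environment table."""

    kind: str                       # "AMMI" | "GGE"
    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame   # genotypes x PCs (orthonormal columns)
    environment_scores: pd.DataFrame
    ss: dict[str, float]            # ss_G, ss_E, ss_GxE, ss_total
    df: dict[str, int]
    pc_percent: np.ndarray          # per-PC % of interaction (AMMI) / G+GxE (GGE)

    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        """Additive fit plus the first ``n_components`` multiplicative terms.

        Only meaningful for AMMI (the GGE scores live on the standardized
        scale).
        """
        if self.kind != "AMMI":
            raise ValueError("reconstruction is defined for the AMMI model")
        k = len(self.singular_values) if n_components is None else n_components
        A = self.genotype_scores.to_numpy()[:, :k]
        C = self.environment_scores.to_numpy()[:, :k]
        lam = self.singular_values[:k]
        Y = (
            self.grand_mean
            + self.genotype_effects.to_numpy()[:, None]
            + self.environment_effects.to_numpy()[None, :]
            + (A * lam) @ C.T
        )
        return pd.DataFrame(Y, index=self.genotype_scores.index,
                            columns=self.environment_scores.index)

    def biplot_coordinates(self, n_components: int = 2) -> pd.DataFrame:
        """Symmetrically scaled biplot coordinates (scores x sqrt(lambda))."""
        k = n_components
        lam = np.sqrt(self.singular_values[:k])
        rows = []
        for label, scores in self.genotype_scores.iterrows():
            rows.append((label, "genotype", *(scores.to_numpy()[:k] * lam)))
        for label, scores in self.environment_scores.iterrows():
            rows.append((label, "environment", *(scores.to_numpy()[:k] * lam)))
        cols = ["label", "kind"] + [f"PC{i + 1}" for i in range(k)]
        return pd.DataFrame(rows, columns=cols)


def _two_way_ss(Y: np.ndarray) -> tuple[dict, dict, np.ndarray, np.ndarray, float]:
    """Grand mean, main effects and the classical two-way SS partition."""
    ng, ne = Y.shape
    mu = Y.mean()
    g = Y.mean(axis=1) - mu
    e = Y.mean(axis=0) - mu
    R = Y - mu - g[:, None] - e[None, :]
    ss = {
        "ss_G": ne * float((g ** 2).sum()),
        "ss_E": ng * float((e ** 2).sum()),
        "ss_GxE": float((R ** 2).sum()),
        "ss_total": float(((Y - mu) ** 2).sum()),
    }
    return ss, {"df_G": ng - 1, "df_E": ne - 1, "df_GxE": (ng - 1) * (ne - 1)}, g, e, mu


def _signed_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD with the sign of each PC fixed so the largest-|.| left score is +."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return U, s, Vt


def _check_matrix(X) -> pd.DataFrame:
    M = pd.DataFrame(X).astype(float)
    if M.isna().any().any():
        raise ValueError("matrix has missing cells; impute first")
    if M.shape[0] < 3 or M.shape[1] < 3:
        raise ValueError("need at least 3 genotypes and 3 environments")
    return M


class AMMI(BaseEstimator):
    """Additive Main effects and Multiplicative Interaction model.

    ``fit`` performs the mean polish and the SVD of the interaction residual.

    Attributes
    ----------
    grand_mean_, genotype_effects_, environment_effects_ : additive fit
    singular_values_ : non-increasing interaction singular values
    genotype_scores_, environment_scores_ : orthonormal score vectors
    ss_, df_ : two-way sum-of-squares partition with degrees of freedom
    pc_percent_ : per-PC percentage of the interaction SS
    decomposition_ : the assembled :class:`GxEDecomposition`
    """

    def fit(self, X, y=None):
        M = _check_matrix(X)
        Y = M.to_numpy()
        ss, df, g, e, mu = _two_way_ss(Y)
        R = Y - mu - g[:, None] - e[None, :]
        U, s, Vt = _signed_svd(R)
        k = min(M.shape) - 1  # double-centering kills one dimension
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        tot = float((s ** 2).sum())
        if tot > 0:
            pc = 100.0 * s ** 2 / tot
        else:
            pc = np.zeros_like(s)
        nondeg = int((s > 1e-12 * max(s[0], 1.0)).sum()) if len(s) else 0
        if nondeg < 2:
            warnings.warn("fewer than 2 non-degenerate interaction PCs; "
                          "PC2 share reported as 0", stacklevel=2)
        self.grand_mean_ = float(mu)
        self.genotype_effects_ = pd.Series(g, index=M.index)
        self.environment_effects_ = pd.Series(e, index=M.columns)
        self.singular_values_ = s
        pcs = [f"PC{i + 1}" for i in range(k)]
        self.genotype_scores_ = pd.DataFrame(U, index=M.index, columns=pcs)
        self.environment_scores_ = pd.DataFrame(Vt.T, index=M.columns, columns=pcs)
        self.ss_ = ss
        self.df_ = df
        self.pc_percent_ = pc
        self.decomposition_ = GxEDecomposition(
            kind="AMMI", grand_mean=self.grand_mean_,
            genotype_effects=self.genotype_effects_,
            environment_effects=self.environment_effects_,
            singular_values=s, genotype_scores=self.genotype_scores_,
            environment_scores=self.environment_scores_,
            ss=ss, df=df, pc_percent=pc,
        )
        return self


class GGE(BaseEstimator):
    """Environment-standardized (G + G×E) decomposition.

    Each environment column is centered by its mean and scaled by its sample
    standard deviation before the SVD, so the model is invariant to
    per-environment affine rescaling of the input.  Zero-variance columns are
    dropped with a warning.
    """

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, X, y=None):
        M = _check_matrix(X)
        sd = M.std(axis=0, ddof=1)
        dead = sd[sd == 0].index
        if len(dead):
            warnings.warn(f"zero-variance environment(s) dropped: {list(dead)}",
                          stacklevel=2)
            M = M.drop(columns=dead)
            sd = sd.drop(dead)
        Z = M - M.mean(axis=0)
        if self.scale:
            Z = Z / sd
        ss, df, g, e, mu = _two_way_ss(M.to_numpy())
        U, s, Vt = _signed_svd(Z.to_numpy())
        k = min(Z.shape) - 1
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        tot = float((s ** 2).sum())
        pc = 100.0 * s ** 2 / tot if tot > 0 else np.zeros_like(s)
        pcs = [f"PC{i + 1}" for i in range(k)]
        self.grand_mean_ = float(mu)
        self.genotype_effects_ = pd.Series(g, index=M.index)
        self.environment_effects_ = pd.Series(e, index=M.columns)
        self.singular_values_ = s
        self.genotype_scores_ = pd.DataFrame(U, index=M.index, columns=pcs)
        self.environment_scores_ = pd.DataFrame(Vt.T, index=M.columns, columns=pcs)
        self.ss_ = ss
        self.df_ = df
        self.pc_percent_ = pc
        self.decomposition_ = GxEDecomposition(
            kind="GGE", grand_mean=self.grand_mean_,
            genotype_effects=self.genotype_effects_,
            environment_effects=self.environment_effects_,
            singular_values=s, genotype_scores=self.genotype_scores_,
            environment_scores=self.environment_scores_,
            ss=ss, df=df, pc_percent=pc,
        )
        return self


class LowRankImputer(TransformerMixin, BaseEstimator):
    """EM-style additive + rank-k SVD imputation of missing cells.

    Missing cells are initialized from the additive row/column fit, then the
    matrix is iterated through (additive fit + rank-``rank`` SVD of the
    residual) reconstructions, refreshing only the missing cells, until the
    largest absolute change drops below ``tol``.  Observed cells are never
    altered.
    """

    def __init__(self, rank: int = 2, tol: float = 1e-8, max_iter: int = 500):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def fit_transform(self, X, y=None):
        M = pd.DataFrame(X).astype(float)
        mask = M.isna().to_numpy()
        if not mask.any():
            self.converged_, self.n_iter_ = True, 0
            return M
        obs_per_row = (~mask).sum(axis=1)
        obs_per_col = (~mask).sum(axis=0)
        if obs_per_row.min() < 2 or obs_per_col.min() < 2:
            raise ValueError("every row and column needs >= 2 observed cells")
        Y = M.to_numpy().copy()
        # initialize from the least-squares additive fit on the observed
        # cells (exact for additive data, so a purely additive matrix is
        # imputed in zero SVD iterations)
        rows, cols = np.nonzero(~mask)
        ng, ne = Y.shape
        X = np.zeros((len(rows), 1 + ng + ne))
        X[:, 0] = 1.0
        X[np.arange(len(rows)), 1 + rows] = 1.0
        X[np.arange(len(rows)), 1 + ng + cols] = 1.0
        beta, *_ = np.linalg.lstsq(X, Y[~mask], rcond=None)
        fill = beta[0] + beta[1:1 + ng][:, None] + beta[1 + ng:][None, :]
        Y[mask] = fill[mask]

        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            mu = Y.mean()
            r = Y.mean(axis=1) - mu
            c = Y.mean(axis=0) - mu
            R = Y - mu - r[:, None] - c[None, :]
            U, s, Vt = np.linalg.svd(R, full_matrices=False)
            k = min(self.rank, len(s))
            Rk = (U[:, :k] * s[:k]) @ Vt[:k]
            new = mu + r[:, None] + c[None, :] + Rk
            delta = np.abs(new[mask] - Y[mask]).max()
            Y[mask] = new[mask]
            if delta < self.tol:
                self.converged_ = True
                self.n_iter_ = it
                break
        else:
            self.n_iter_ = self.max_iter
            warnings.warn("imputation did not converge; returning last iterate",
                          stacklevel=2)
        return pd.DataFrame(Y, index=M.index, columns=M.columns)

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def impute_missing(matrix: pd.DataFrame, rank: int = 2, tol: float = 1e-8,
                   max_iter: int = 500) -> pd.DataFrame:
    return LowRankImputer(rank=rank, tol=tol, max_iter=max_iter).fit_transform(matrix)


def ammi_decompose(matrix: pd.DataFrame) -> GxEDecomposition:
    return AMMI().fit(matrix).decomposition_


def gge_decompose(matrix: pd.DataFrame) -> GxEDecomposition:
    return GGE().fit(matrix).decomposition_


def ss_partition_percent(d: GxEDecomposition, n_pcs: int = 4) -> dict[str, float]:
    """Percent-of-total-SS partition plus per-PC shares, on the printed scale.

    ``pct_G + pct_E + pct_GxE == 100`` for complete data; ``pct_PCk`` is the
    percentage of the multiplicative variation (interaction for AMMI,
    G + G×E for GGE) carried by the k-th principal component.
    """
    tot = d.ss["ss_total"]
    out = {
        "pct_G": 100.0 * d.ss["ss_G"] / tot,
        "pct_E": 100.0 * d.ss["ss_E"] / tot,
        "pct_GxE": 100.0 * d.ss["ss_GxE"] / tot,
    }
    for k in range(n_pcs):
        out[f"pct_PC{k + 1}"] = (
            float(d.pc_percent[k]) if k < len(d.pc_percent) else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# cluster dendrograms


@dataclass
class DendrogramTree:
    """Agglomerative tree over genotype or environment labels."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    axis: str = "genotypes"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def cluster_dendrogram(matrix: pd.DataFrame, axis: str = "genotypes",
                       linkage_method: str = "average") -> DendrogramTree:
    """Average-linkage clustering of standardized profiles.

    Profiles are the rows (``axis="genotypes"``) or columns
    (``axis="environments"``) of the matrix after standardizing each feature;
    distances are Euclidean, computed pairwise-complete over shared observed
    cells and rescaled to the full feature count.  Any pair sharing fewer
    than two observed cells raises an error naming the pair.
    """
    if axis == "environments":
        M = matrix.T
    elif axis == "genotypes":
        M = matrix
    else:
        raise ValueError("axis must be 'genotypes' or 'environments'")
    M = pd.DataFrame(M).astype(float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 labels to cluster")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1).replace(0.0, 1.0)
    Z = ((M - mean) / sd).to_numpy()
    labels = list(M.index)
    n, m = Z.shape
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(Z[i]) & ~np.isnan(Z[j])
            if shared.sum() < 2:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) shares fewer than 2 "
                    "observed cells"
                )
            diff = Z[i, shared] - Z[j, shared]
            cond.append(np.sqrt((diff ** 2).sum() * m / shared.sum()))
    link = hierarchy.linkage(np.asarray(cond), method=linkage_method)
    return DendrogramTree(labels=labels, linkage=link, axis=axis)
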