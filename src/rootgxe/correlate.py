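"""Cross-experiment Pearson correlation structure.

Experiments share only subsets of genotypes, so all correlations are
pairwise-complete; two-sided p-values come from the t transform with n - 2
degrees of freedom.  No multiple-testing correction is applied — the
significant-partner counts deliberately replicate raw p < 0.05 counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete correlation structure among experiments."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r.index)

    def stars(self) -> pd.DataFrame:
        """Formatted r with significance stars at 0.05 / 0.01 / 0.001."""
        def fmt(r, p):
            if np.isnan(r):
                return "NA"
            s = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            return f"{r:.2f}{s}"
        out = self.r.copy().astype(object)
        for a in out.index:
            for b in out.columns:
                out.loc[a, b] = fmt(self.r.loc[a, b], self.p.loc[a, b])
        return out


def _pair_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    shared = ~np.isnan(x) & ~np.isnan(y)
    n = int(shared.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[shared], y[shared]
    if xs.std() == 0 or ys.std() == 0:
        logger.info("zero-variance column in a pairwise set; r reported missing")
        return np.nan, np.nan, n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def pairwise_correlations(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson r / two-sided p among experiment columns."""
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 experiment columns")
    X = matrix.to_numpy(dtype=float)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i] = 1.0
        n[i, i] = int((~np.isnan(X[:, i])).sum())
        for j in range(i + 1, k):
            rij, pij, nij = _pair_corr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def count_significant(cm: CorrelationMatrix, alpha: float = 0.05,
                      sign_split: bool = False) -> pd.DataFrame:
    """Per experiment, how many other experiments correlate at p < alpha."""
    counts = []
    for a in cm.labels:
        p_row = cm.p.loc[a].drop(a)
        r_row = cm.r.loc[a].drop(a)
        sig = p_row < alpha
        row = {"experiment": a, "n_significant": int(sig.sum())}
        if sign_split:
            row["n_positive"] = int((sig & (r_row > 0)).sum())
            row["n_negative"] = int((sig & (r_row < 0)).sum())
        counts.append(row)
    return pd.DataFrame(counts).set_index("experiment")


def pc_env_correlations(scores: pd.DataFrame,
                        covariates: pd.DataFrame) -> pd.DataFrame:
    """Correlate environment PC scores with environment covariates.

    ``scores``: environments x PCs (e.g. biplot environment coordinates);
    ``covariates``: environments x characteristics, aligned on the index.
    Covariates with fewer than 3 paired values or zero variance are skipped
    with a log entry.  Returns a tidy (covariate, pc, r, p, n) table.
    """
    shared = scores.index.intersection(covariates.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 environments shared between scores and covariates")
    rows = []
    for cov in covariates.columns:
        for pc in scores.columns:
            x = covariates.loc[shared, cov].to_numpy(dtype=float)
            y = scores.loc[shared, pc].to_numpy(dtype=float)
            r, p, n = _pair_corr(x, y)
            if np.isnan(r):
                logger.info("covariate %s x %s skipped (n=%d or zero variance)",
                            cov, pc, n)
                continue
            rows.append({"covariate": cov, "pc": pc, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["covariate", "pc", "r", "p", "n"])
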