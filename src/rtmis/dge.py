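"""Exploratory statistics: volcano analysis, PCA maps, rank-sum tests.

Two-group differential expression uses Welch's unequal-variance t-test on
log-scale expression with Benjamini-Hochberg control of the false
discovery rate; fold changes are computed on de-logged values with a
pseudo-count of 0.5 molecules-per-10k so genes absent from one group stay
finite.  A gene is flagged significant when |log2 fold change| > 1 and
FDR < 0.05.

PCA maps standardise each gene to zero mean and unit variance before the
decomposition; the "most discriminatory" markers of a map are the 40 genes
with the largest Euclidean loading norm over the first two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .quantify import delog

LOG2_FC_CUTOFF = 1.0
FDR_CUTOFF = 0.05
PSEUDOCOUNT = 0.5
N_TOP_MARKERS = 40


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _two_groups(groups: pd.Series) -> tuple:
    values = pd.unique(groups.dropna())
    if len(values) != 2:
        raise ValueError(f"need exactly two groups, got {list(values)}")
    return values[0], values[1]


def volcano(expr: pd.DataFrame, groups: pd.Series,
            log2_fc_cutoff: float = LOG2_FC_CUTOFF,
            fdr_cutoff: float = FDR_CUTOFF) -> pd.DataFrame:
    """Per-gene Welch test and log2 fold change between two groups.

    ``groups`` assigns each sample to one of two labels; the fold change is
    group A minus group B in log2, where A is the first label encountered.
    Returns a DataFrame indexed by gene with columns log2_fc, p_value, fdr,
    significant and tested (False where the test is undefined).
    """
    a_label, b_label = _two_groups(groups)
    A = expr.loc[groups == a_label]
    B = expr.loc[groups == b_label]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("both groups need >= 2 samples for a Welch test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A.to_numpy(), B.to_numpy(), axis=0,
                               equal_var=False)
    mean_a = delog(A).mean(axis=0)
    mean_b = delog(B).mean(axis=0)
    log2_fc = np.log2(mean_a + PSEUDOCOUNT) - np.log2(mean_b + PSEUDOCOUNT)
    tested = ~np.isnan(p)
    fdr = np.full_like(p, np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    out = pd.DataFrame({
        "log2_fc": log2_fc, "p_value": p, "fdr": fdr,
        "tested": tested}, index=expr.columns)
    out["significant"] = (tested & (np.abs(out["log2_fc"]) > log2_fc_cutoff)
                          & (out["fdr"] < fdr_cutoff))
    out.index.name = "gene"
    return out


@dataclass
class PcaMap:
    """Two-component PCA of a (standardised) expression matrix."""

    coordinates: pd.DataFrame        # samples x 2
    loadings: pd.DataFrame           # genes x 2
    explained_variance: np.ndarray   # ratio, length 2
    top_markers: list[str]           # largest loading norm over PC1-2


def pca_map(expr: pd.DataFrame, subset: pd.Series | list | None = None,
            n_top: int = N_TOP_MARKERS) -> PcaMap:
    """PCA on gene-standardised expression; deterministic component signs.

    Genes are centred and scaled to unit variance (constant genes are left
    centred only).  Each component's sign is fixed so the gene with the
    largest absolute loading has a positive loading.
    """
    if subset is not None:
        expr = expr.loc[subset]
    if expr.shape[0] < 3 or expr.shape[1] < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 genes")
    X = expr.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Z)
    # variable loadings scaled by singular value, FactoMineR-style
    load = pca.components_.T * np.sqrt(
        np.maximum(pca.explained_variance_, 0.0))
    for k in range(2):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1
            coords[:, k] *= -1
    norms = np.linalg.norm(load, axis=1)
    top_idx = np.argsort(-norms, kind="stable")[:n_top]
    return PcaMap(
        coordinates=pd.DataFrame(coords, index=expr.index,
                                 columns=["PC1", "PC2"]),
        loadings=pd.DataFrame(load, index=expr.columns,
                              columns=["PC1", "PC2"]),
        explained_variance=np.nan_to_num(
            pca.explained_variance_ratio_[:2]),
        top_markers=[expr.columns[i] for i in top_idx])


def compare_groups(expr: pd.DataFrame, gene: str,
                   groups: pd.Series) -> tuple[float, dict[str, float]]:
    """Two-sided Wilcoxon rank-sum comparison of one gene between groups.

    Uses the exact null distribution for small tie-free samples (both
    groups <= 25), otherwise the tie-corrected normal approximation.
    Returns (p_value, per-group medians).
    """
    a_label, b_label = _two_groups(groups)
    a = expr.loc[groups == a_label, gene].to_numpy(dtype=float)
    b = expr.loc[groups == b_label, gene].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not ties) \
        else "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0, {str(a_label): float(np.median(a)),
                     str(b_label): float(np.median(b))}
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    p = float(min(res.pvalue, 1.0))
    return p, {str(a_label): float(np.median(a)),
               str(b_label): float(np.median(b))}
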