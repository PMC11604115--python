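"""Population-structure summary and downstream association statistics.

PCA on standardized doses summarises between-subpopulation structure (with
per-subpopulation mean eigenvectors); contribution signs are cross-classified
against sample-size classes and contrasted with a generalized
Cochran-Mantel-Haenszel test; rank and product-moment correlations compare
estimate pairs (infinite effective sizes excluded pairwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, SubpopulationMap

__all__ = [
    "PcaResult",
    "pca_genotypes",
    "classify_signs",
    "cmh_test",
    "moment_fst",
    "paired_correlations",
    "SIZE_SCHEMES",
]


def moment_fst(counts) -> float:
    """Frequency-variance (Weir-Cockerham-style) moment estimator of F.

    Per locus, with per-subpopulation sample frequencies p_s from c_s observed
    gene copies: the across-subpopulation sample variance s^2 estimates
    F p0 q0 plus the binomial sampling term, which is removed via its unbiased
    estimate mean_s[p_s q_s / (c_s - 1)]; the ancestral heterozygosity p0 q0
    is estimated by pbar qbar + s^2 / k (undoing the shrinkage of the pooled
    mean).  Loci are combined as a ratio of sums.
    """
    p = counts.freq
    c = counts.tot
    if np.isnan(p).any() or (c < 2).any():
        raise ValueError("moment_fst needs >= 2 observed copies everywhere")
    k = p.shape[0]
    if k < 2:
        raise ValueError("moment_fst needs >= 2 subpopulations")
    pbar = p.mean(axis=0)
    s2 = p.var(axis=0, ddof=1)
    within = (p * (1 - p) / (c - 1)).mean(axis=0)
    num = s2 - within
    den = pbar * (1 - pbar) + s2 / k
    keep = den > 0
    if not keep.any():
        raise ValueError("no polymorphic locus for moment_fst")
    return float(num[keep].sum() / den[keep].sum())

# Sample-size class schemes: label -> bin edges (right-open) and class names
SIZE_SCHEMES = {
    "lt10": ([10], ["<10", ">=10"]),
    "lt20": ([20], ["<20", ">=20"]),
    "three": ([10, 20], ["<10", "10-19", ">=20"]),
}


@dataclass
class PcaResult:
    eigenvectors: pd.DataFrame       # individuals x components
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    subpop_means: pd.DataFrame | None = None


def pca_genotypes(
    gm: GenotypeMatrix, m: int = 10, subs: SubpopulationMap | None = None
) -> PcaResult:
    """PCA of standardized genotype doses.

    Missing doses are mean-imputed per locus (for this operation only); each
    locus is centered by 2p and scaled by sqrt(2p(1-p)).  Deterministic up to
    component sign, which is fixed by making each component's
    largest-magnitude locus loading positive.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X = gm.dose.astype(float)
    obs = X >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, X, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    keep = (p > 0) & (p < 1) & obs.any(axis=0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic loci (zero-variance data)")
    Xk, pk = X[:, keep], p[keep]
    Xk = np.where(Xk >= 0, Xk, 2 * pk)
    Z = (Xk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    m = min(m, len(s))
    lam = s**2 / Z.shape[1]
    prop = lam / lam.sum() if lam.sum() > 0 else lam
    # sign convention: largest-|loading| entry positive per component
    for c in range(m):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    ev = pd.DataFrame(
        U[:, :m], index=gm.individual_ids, columns=[f"PC{k + 1}" for k in range(m)]
    )
    means = None
    if subs is not None:
        subs.validate_against(gm)
        lab = pd.Series({i: subs.assignment[i] for i in gm.individual_ids})
        means = ev.groupby(lab).mean()
        means.index.name = "subpopulation"
    return PcaResult(ev, lam[:m], prop[:m], means)


# ---------------------------------------------------------------------------
# Sign classification
# ---------------------------------------------------------------------------


def classify_signs(
    contrib: pd.DataFrame,
    size_scheme: str = "lt10",
    tie_rule: str = "positive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-classify subpopulations by HT/AT contribution sign and size class.

    Sign classes: '++' (favorable to both), '+-', '-+', '--'; first symbol is
    the gene-diversity (cHT) sign, second the allelic-richness (cAT) sign.
    Exact zeros follow ``tie_rule`` ('positive' or 'negative').  Returns the
    per-subpopulation labels and the size-class x sign-class crosstab.
    """
    if size_scheme not in SIZE_SCHEMES:
        raise ValueError(f"unknown size scheme {size_scheme!r}")
    edges, names = SIZE_SCHEMES[size_scheme]

    def _sign(v: float) -> str:
        if v > 0:
            return "+"
        if v < 0:
            return "-"
        return "+" if tie_rule == "positive" else "-"

    sign_class = [
        _sign(r.cHT) + _sign(r.cAT) for r in contrib.itertuples()
    ]
    size_class = [
        names[int(np.searchsorted(edges, n, side="right"))] for n in contrib["n"]
    ]
    labels = pd.DataFrame(
        {"n": contrib["n"], "size_class": size_class, "sign_class": sign_class},
        index=contrib.index,
    )
    tab = pd.crosstab(labels["size_class"], labels["sign_class"])
    return labels, tab


# ---------------------------------------------------------------------------
# Generalized Cochran-Mantel-Haenszel test
# ---------------------------------------------------------------------------


def cmh_test(tables: list[np.ndarray]) -> tuple[float, int, float]:
    """Generalized CMH statistic for general association across strata.

    Each stratum is an R x C count table.  df = (R-1)(C-1).  With a single
    stratum the statistic equals (N-1)/N times the Pearson chi-square.  Strata
    whose margin structure carries no information (an all-zero row and column,
    or total < 2) are dropped with a warning.
    """
    import warnings

    tabs = []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.ndim != 2:
            raise ValueError("each stratum must be a 2-D count table")
        if t.sum() < 2 or (t.sum(axis=1) == 0).any() and (t.sum(axis=0) == 0).any():
            warnings.warn("dropping uninformative stratum", stacklevel=2)
            continue
        tabs.append(t)
    if not tabs:
        raise ValueError("no informative strata")
    R, C = tabs[0].shape
    for t in tabs:
        if t.shape != (R, C):
            raise ValueError("strata must share dimensions")
    df = (R - 1) * (C - 1)
    G = np.zeros(df)
    V = np.zeros((df, df))
    for t in tabs:
        n = t.sum()
        r = t.sum(axis=1)
        c = t.sum(axis=0)
        m = np.outer(r, c) / n
        u = (t - m)[: R - 1, : C - 1].ravel()
        G += u
        # hypergeometric covariance of the reduced cell-count vector
        vr = (np.diag(r * n) - np.outer(r, r))[: R - 1, : R - 1]
        vc = (np.diag(c * n) - np.outer(c, c))[: C - 1, : C - 1]
        V += np.kron(vr, vc) / (n**2 * (n - 1))
    Q = float(G @ np.linalg.pinv(V) @ G)
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n_used: int
    n_excluded: int = 0


def paired_correlations(x, y) -> CorrelationResult:
    """Pearson and Spearman (mid-rank) correlations with pairwise exclusion.

    Non-finite entries (e.g. infinite Ne estimates) are excluded pairwise and
    counted.  P-values use the t-distribution approximation with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue),
        len(x), n_excluded,
    )
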