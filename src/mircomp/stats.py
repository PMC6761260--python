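"""Shared statistical kernel.

Rank tests, chi-square variants, Welch's t, hypergeometric enrichment with
Benjamini-Hochberg correction, and PCA.  Distribution machinery comes from
scipy/statsmodels; the wrappers fix the exact variants used throughout the
pipeline (Yates correction with clamping, exact-vs-asymptotic switch for
Mann-Whitney, upper-tail hypergeometric) and return a uniform record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str
    n: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U with midranks for ties.

    Exact p by enumeration when the combined sample size is at most 10 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size <= 10) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method=f"mann_whitney_u_{method}",
        n=(x.size, y.size),
    )


def chi2_2x2(table, yates: bool = True) -> TestResult:
    """Chi-square test of independence on a 2x2 table.

    With ``yates`` the absolute deviations are reduced by 0.5 but clamped
    at zero, so near-null tables cannot have their statistic inflated.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi2_2x2 expects a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi2_2x2 requires all margins > 0")
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return TestResult(
        statistic=stat,
        df=1,
        p_value=float(sps.chi2.sf(stat, 1)),
        method="chi2_yates" if yates else "chi2_pearson",
        n=tuple(int(v) for v in rows),
    )


def chi2_gof(observed, expected_probs) -> TestResult:
    """Chi-square goodness of fit of counts against given probabilities."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected_probs must align")
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("expected_probs must sum to 1")
    expected = probs * obs.sum()
    if (expected == 0).any():
        raise ValueError("expected count of zero")
    stat, p = sps.chisquare(obs, f_exp=expected)
    return TestResult(
        statistic=float(stat),
        df=obs.size - 1,
        p_value=float(p),
        method="chi2_gof",
        n=(int(obs.sum()),),
    )


def welch_t(x, y) -> TestResult:
    """Two-sided Welch t test (Satterthwaite df).

    If both samples are constant with equal means the statistic is 0 and
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires >= 2 values per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, float(x.size + y.size - 2), 1.0,
                              "welch_t", (x.size, y.size))
    res = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2x, se2y = vx / x.size, vy / y.size
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method="welch_t",
        n=(x.size, y.size),
    )


def fisher_enrichment(k: int, n: int, K: int, N: int) -> TestResult:
    """One-sided over-representation p-value, P(X >= k).

    X is hypergeometric: draw ``n`` genes (the test set) from ``N`` baseline
    genes of which ``K`` carry the annotation; ``k`` is the observed overlap.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return TestResult(
        statistic=float(k), df=None, p_value=min(p, 1.0),
        method="hypergeom_upper_tail", n=(n, N),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def go_enrichment(test_genes, baseline_genes, annotation: dict[str, set[str]]):
    """Per-term over-representation of the test set against the baseline.

    Returns a list of dicts (term, k, n, K, N, p_value, q_value) for every
    term with at least one test-set hit, sorted by p then term id.
    """
    test = set(test_genes)
    baseline = set(baseline_genes)
    if not test:
        raise ValueError("empty test gene set")
    if not test <= baseline:
        raise ValueError("test set must be a subset of the baseline")
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene in baseline:
            for t in terms:
                term_to_genes.setdefault(t, set()).add(gene)
    if not term_to_genes:
        raise ValueError("annotation covers no baseline gene")
    N, n = len(baseline), len(test)
    rows = []
    for term in sorted(term_to_genes):
        genes = term_to_genes[term]
        k = len(genes & test)
        if k == 0:
            continue
        K = len(genes)
        res = fisher_enrichment(k, n, K, N)
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "p_value": res.p_value})
    rows.sort(key=lambda r: (r["p_value"], r["term"]))
    qs = bh_fdr([r["p_value"] for r in rows])
    for row, q in zip(rows, qs):
        row["q_value"] = float(q)
    return rows


def pca(matrix):
    """PCA of a features x samples matrix.

    Features are centered across samples; components come from the SVD of
    the centered sample-by-feature matrix.  Returns
    ``(variance_explained, scores)`` with scores of shape
    (n_samples, n_components).  Sign convention: the largest-magnitude
    loading of each component is positive.  A matrix with zero total
    variance yields all-zero shares and scores.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("pca expects a 2-D matrix with >= 2 samples")
    D = X.T - X.mean(axis=1)  # samples x features, feature-centered
    if np.allclose(D, 0):
        k = min(D.shape)
        return np.zeros(k), np.zeros((D.shape[0], k))
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    var = S**2
    shares = var / var.sum()
    # fix component signs via the dominant loading
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * S
    return shares, scores
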