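"""Per-gene association screening between environments.

Welch's t with Satterthwaite degrees of freedom, biweight midcorrelation
with Student-t p-values, Bonferroni and Benjamini-Hochberg control, and the
drifted-gene screen (cord versus culture) that defines the denominator for
every downstream rescue fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix, validate_samples

# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p).

    Both groups constant and equal gives t = 0, p = 1; both constant and
    unequal gives an infinite-t sentinel with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_matrix(A: np.ndarray, B: np.ndarray):
    """Row-wise Welch test: A (genes x n1) vs B (genes x n2).

    Returns (delta, t, df, p) arrays; constant-equal rows get t=0, p=1.
    """
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1, v2 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    delta = m1 - m2
    both_const = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t[both_const & (delta == 0)] = 0.0
    t[both_const & (delta != 0)] = np.sign(delta[both_const & (delta != 0)]) * np.inf
    df[both_const] = n1 + n2 - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    p[(t == 0) & both_const] = 1.0
    return delta, t, df, p


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------


def _bicor_prepare(X: np.ndarray, max_p_outliers: float = 1.0) -> np.ndarray:
    """Normalized biweight deviations per row; Pearson fallback when MAD=0.

    Each row is mapped to a vector d / ||d|| with d_i = (x_i - med) * w_i,
    w_i = (1 - u_i^2)^2 * 1[|u_i| < 1], u_i = (x_i - med) / (9 * MAD), where
    MAD carries the usual normal-consistency constant 1.4826 (the R ``mad``
    convention of the reference implementation). Rows with zero MAD (or all
    weights zero) fall back to mean-centred deviations, which makes the
    resulting correlation Pearson's r.

    ``max_p_outliers`` caps the proportion of samples on each side of the
    median that can receive zero weight: when the relevant side quantile of
    |u| exceeds 1, that side is rescaled so only the capped fraction is
    excluded. The cap protects strongly bimodal vectors (a group contrast)
    from having one whole group discarded as outliers.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = 1.4826 * np.median(np.abs(dev), axis=1, keepdims=True)
    safe_mad = np.where(mad == 0, 1.0, mad)  # MAD=0 rows are replaced by the fallback below
    u = dev / (9.0 * safe_mad)
    if max_p_outliers < 1.0:
        lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        hi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
        lo_scale = np.where(lo < -1.0, -lo, 1.0)
        hi_scale = np.where(hi > 1.0, hi, 1.0)
        u = np.where(u < 0, u / lo_scale, u / hi_scale)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    d = dev * w
    fallback = (mad[:, 0] == 0) | (np.abs(d).sum(axis=1) == 0)
    if fallback.any():
        xf = X[fallback]
        d[fallback] = xf - xf.mean(axis=1, keepdims=True)
    norm = np.sqrt((d**2).sum(axis=1, keepdims=True))
    const = norm[:, 0] == 0
    norm[const] = 1.0
    out = d / norm
    out[const] = np.nan  # constant rows: correlation undefined
    return out


def bicor_matrix(
    X: np.ndarray, Y: np.ndarray | None = None, max_p_outliers: float = 1.0
) -> np.ndarray:
    """Biweight midcorrelation between rows of X and rows of Y (or X)."""
    Xn = _bicor_prepare(np.atleast_2d(X), max_p_outliers)
    Yn = Xn if Y is None else _bicor_prepare(np.atleast_2d(Y), max_p_outliers)
    if Xn.shape[1] != Yn.shape[1]:
        raise ValueError("row length mismatch")
    R = Xn @ Yn.T
    return np.clip(R, -1.0, 1.0)


def bicor(x, y, max_p_outliers: float = 1.0) -> float:
    """Biweight midcorrelation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("bicor requires n >= 3")
    return float(bicor_matrix(x[None, :], y[None, :], max_p_outliers)[0, 0])


def bicor_with_p(x, y, max_p_outliers: float = 1.0) -> tuple[float, float]:
    """bicor plus a two-sided p-value from the Student-t approximation
    t = r * sqrt((n-2) / (1-r^2))."""
    r = bicor(x, y, max_p_outliers)
    n = len(np.asarray(x))
    if np.isnan(r):
        return np.nan, np.nan
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _bicor_p_matrix(R: np.ndarray, n: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1 - R**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(R) >= 1.0] = 0.0
    return p


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# drift screen
# ---------------------------------------------------------------------------


@dataclass
class DriftTable:
    """Per-gene cord-versus-culture statistics plus the drifted/expressed calls."""

    table: pd.DataFrame
    contrast: tuple
    rule: str
    alpha: float
    m_tests: int

    @property
    def n_expressed(self) -> int:
        return int(self.table["expressed"].sum())

    @property
    def n_drifted(self) -> int:
        return int(self.table["drifted"].sum())

    @property
    def fraction_drifted(self) -> float:
        n = self.n_expressed
        return self.n_drifted / n if n else np.nan

    @property
    def drifted_genes(self) -> pd.Index:
        return self.table.index[self.table["drifted"]]


def de_contrast(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    group1,
    group2,
    compute_bicor: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch DE between two environment groups (group1 - group2).

    ``group1``/``group2`` are environment names or tuples of them. Returns a
    DataFrame indexed by gene with delta, t, df, p, q (BH over all genes)
    and optionally the robust correlation with the group-1 indicator.
    """
    samples = validate_samples(samples, m)
    g1 = (group1,) if isinstance(group1, str) else tuple(group1)
    g2 = (group2,) if isinstance(group2, str) else tuple(group2)
    env = samples["environment"]
    mask1 = env.isin(g1).to_numpy()
    mask2 = env.isin(g2).to_numpy()
    if mask1.sum() < 2 or mask2.sum() < 2:
        missing = g1 if mask1.sum() < 2 else g2
        raise ValueError(f"contrast group {missing} has fewer than 2 samples")
    X = m.values.to_numpy(dtype=float)
    delta, t, df, p = welch_t_matrix(X[:, mask1], X[:, mask2])
    out = pd.DataFrame(
        {"delta": delta, "t": t, "df": df, "p": p, "q": bh_fdr(p)}, index=m.gene_ids
    )
    if compute_bicor:
        both = mask1 | mask2
        indicator = mask1[both].astype(float)
        R = bicor_matrix(X[:, both], indicator[None, :])[:, 0]
        out["bicor_r"] = R
        out["bicor_p"] = _bicor_p_matrix(R, int(both.sum()))
    return out


def drift_screen(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    contrast: tuple = ("cord", ("early_culture", "late_culture")),
    rule: str = "bonferroni",
    alpha: float = 0.05,
    m_tests: int | None = None,
    expressed_threshold: float = 1.0,
) -> DriftTable:
    """Screen genes for cord-versus-culture drift.

    A gene is *expressed* when its mean linear-scale expression reaches
    ``expressed_threshold`` in at least one contrast group (the matrix must
    be on the log10 scale so linear values can be recovered). The drifted
    rule is Bonferroni ``p < alpha / m`` (m defaulting to the number of
    expressed genes) or BH ``q < alpha``.
    """
    if rule not in ("bonferroni", "fdr"):
        raise ValueError(f"unknown drifted rule {rule!r}")
    if m.scale != "log10":
        raise ValueError("drift_screen expects the log10 working scale")
    samples = validate_samples(samples, m)
    g1 = (contrast[0],) if isinstance(contrast[0], str) else tuple(contrast[0])
    g2 = (contrast[1],) if isinstance(contrast[1], str) else tuple(contrast[1])
    env = samples["environment"]
    mask1 = env.isin(g1).to_numpy()
    mask2 = env.isin(g2).to_numpy()
    if not mask1.any() or not mask2.any():
        raise ValueError(f"missing contrast group in sample table: {contrast}")

    X = m.values.to_numpy(dtype=float)
    linear = np.power(10.0, X)
    expressed = (linear[:, mask1].mean(axis=1) >= expressed_threshold) | (
        linear[:, mask2].mean(axis=1) >= expressed_threshold
    )

    de = de_contrast(m, samples, g1, g2, compute_bicor=True)
    # multiple-testing corrections use only the expressed (tested) genes
    q = np.full(len(de), np.nan)
    q[expressed] = bh_fdr(de["p"].to_numpy()[expressed])
    de["q"] = q
    m_eff = int(m_tests) if m_tests is not None else int(expressed.sum())
    if m_eff < 1:
        raise ValueError("no expressed genes to test")
    if rule == "bonferroni":
        thr = bonferroni_threshold(alpha, m_eff)
        drifted = expressed & (de["p"].to_numpy() < thr)
    else:
        drifted = expressed & (de["q"].to_numpy() < alpha)

    table = de.copy()
    table["expressed"] = expressed
    table["drifted"] = drifted
    table["direction"] = np.where(
        ~drifted, "ns", np.where(table["delta"] > 0, "up", "down")
    )
    table = table.rename(columns={"t": "t_stat"})
    return DriftTable(table=table, contrast=(g1, g2), rule=rule, alpha=alpha, m_tests=m_eff)


# ---------------------------------------------------------------------------
# set overlap
# ---------------------------------------------------------------------------


def overlap_report(setA, setB, universe) -> dict:
    """Disjoint counts (A_only, B_only, both, neither) over a gene universe."""
    A, B, U = set(setA), set(setB), set(universe)
    stray = (A | B) - U
    if stray:
        raise ValueError(f"elements outside the universe: {sorted(stray)[:5]}")
    both = A & B
    return {
        "A_only": len(A - B),
        "B_only": len(B - A),
        "both": len(both),
        "neither": len(U - A - B),
    }
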