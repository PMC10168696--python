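"""Expression containers and pre-statistics transforms.

Everything downstream of raw matrices and upstream of inference lives here:
the validated gene x sample container, log10 transform, gene-wise scaling,
empirical-Bayes batch adjustment (location/scale model, parametric or
nonparametric priors), and PCA on the scaled matrix.

The working scale of the whole pipeline is log10 expression; matrices carry
an explicit ``scale`` tag (``linear`` -> ``log10`` -> ``scaled``) so that
each stage can enforce its preconditions instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCALES = ("linear", "log10", "scaled")

#: recognised sample environments; "flow" samples additionally carry timepoint_h
ENVIRONMENTS = (
    "cord",
    "early_culture",
    "late_culture",
    "static",
    "flow",
    "mono_culture",
    "co_culture",
)

#: environments representing the in-vitro (culture) state, i.e. carrying drift
CULTURE_ENVIRONMENTS = (
    "early_culture",
    "late_culture",
    "static",
    "flow",
    "mono_culture",
    "co_culture",
)

SAMPLE_COLUMNS = ("sample_id", "donor", "environment", "timepoint_h", "batch", "layer")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a declared scale.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns. Entries
        must be finite; gene and sample identifiers must be unique.
    scale
        One of ``linear``, ``log10`` or ``scaled``.
    constant_genes
        Optional boolean Series flagging genes that had zero variance when
        the matrix was gene-scaled (they are centred, not divided).
    """

    values: pd.DataFrame
    scale: str = "linear"
    constant_genes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index.name = "gene_id"
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            g, s = bad[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r} ({len(bad)} such entries)"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], scale=self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, samples], scale=self.scale)


def validate_samples(samples: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a sample table and (optionally) its alignment with a matrix.

    The table must contain the canonical columns, one row per sample, and —
    when a matrix is given — one row for every matrix column, in column order.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sample table: {dup[:5]}")
    bad_env = set(samples["environment"]) - set(ENVIRONMENTS)
    if bad_env:
        raise ValueError(f"unknown environments: {sorted(bad_env)}")
    if matrix is not None:
        tab = samples.set_index("sample_id")
        missing_rows = [s for s in matrix.sample_ids if s not in tab.index]
        if missing_rows:
            raise ValueError(f"matrix samples missing from sample table: {missing_rows[:5]}")
        samples = tab.loc[matrix.sample_ids]
        samples.index.name = "sample_id"
        samples = samples.reset_index()
    return samples


# ---------------------------------------------------------------------------
# log transform and gene-wise scaling
# ---------------------------------------------------------------------------


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log10(value + pseudocount) on a linear-scale matrix."""
    if m.scale != "linear":
        raise ValueError(f"log_transform expects a linear-scale matrix, got {m.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    arr = m.values.to_numpy()
    neg = (arr < 0).any(axis=1)
    if neg.any():
        genes = m.gene_ids[neg].tolist()
        raise ValueError(f"negative expression values for genes {genes[:10]}")
    out = np.log10(arr + pseudocount)
    return ExpressionMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), scale="log10")


def scale_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene to zero mean and unit (n-1) standard deviation.

    Constant genes are centred to zero and flagged in ``constant_genes``
    rather than divided by zero.
    """
    if m.n_samples < 2:
        raise ValueError("gene scaling needs at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    out = (arr - mean) / sd
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
        scale="scaled",
        constant_genes=pd.Series(const, index=m.gene_ids),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-8  # variance floor for zero-variance genes inside standardization


def _eb_parametric(z: np.ndarray, n_i: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form iterative posterior means under normal / inverse-gamma priors.

    ``z`` is the standardized data for one batch (genes x batch samples).
    Returns shrunken per-gene location (gamma*) and scale (delta^2*).
    """
    gamma_hat = z.mean(axis=1)
    if n_i > 1:
        delta_hat = z.var(axis=1, ddof=1)
    else:  # pragma: no cover - guarded by caller
        delta_hat = np.ones(z.shape[0])
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    # method-of-moments inverse-gamma hyperparameters for the scale prior
    m_d = delta_hat.mean()
    s2_d = delta_hat.var(ddof=1)
    if s2_d == 0:
        s2_d = _VAR_FLOOR
    a_prior = (2 * s2_d + m_d**2) / s2_d
    b_prior = (m_d * s2_d + m_d**3) / s2_d

    g_star = gamma_hat.copy()
    d_star = delta_hat.copy()
    ssq = ((z - g_star[:, None]) ** 2).sum(axis=1)
    for _ in range(200):
        g_new = (n_i * tau2 * gamma_hat + d_star * gamma_bar) / (n_i * tau2 + d_star)
        ssq = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b_prior + 0.5 * ssq) / (n_i / 2 + a_prior - 1)
        change = max(
            np.abs(g_new - g_star).max(initial=0), np.abs(d_new - d_star).max(initial=0)
        )
        g_star, d_star = g_new, d_new
        if change < 1e-10:
            break
    return g_star, d_star


def _eb_nonparametric(
    z: np.ndarray, n_i: int, n_mc: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo posterior integration with likelihood weights.

    The empirical prior on (gamma, delta^2) is the set of per-gene batch
    estimates; for each gene the posterior mean is the likelihood-weighted
    average over a seeded Monte-Carlo sample of the other genes' estimates.
    """
    G = z.shape[0]
    gamma_hat = z.mean(axis=1)
    delta_hat = z.var(axis=1, ddof=1) if n_i > 1 else np.ones(G)
    delta_hat = np.maximum(delta_hat, _VAR_FLOOR)

    if G - 1 <= n_mc:
        support = np.arange(G)
    else:
        support = rng.choice(G, size=n_mc, replace=False)
    g_sup = gamma_hat[support]
    d_sup = delta_hat[support]

    g_star = np.empty(G)
    d_star = np.empty(G)
    chunk = max(1, int(2e7 // max(len(support), 1)))
    for lo in range(0, G, chunk):
        hi = min(lo + chunk, G)
        zc = z[lo:hi]  # (c, n_i)
        # log-likelihood of each gene's batch data under each support point
        ssq = ((zc[:, None, :] - g_sup[None, :, None]) ** 2).sum(axis=2)  # (c, S)
        ll = -0.5 * ssq / d_sup[None, :] - 0.5 * n_i * np.log(d_sup)[None, :]
        # leave-one-out: a gene never informs its own prior
        own = np.nonzero((support[None, :] >= lo) & (support[None, :] < hi))[1]
        for j in own:
            ll[support[j] - lo, j] = -np.inf
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)
        wsum = w.sum(axis=1)
        g_star[lo:hi] = (w * g_sup[None, :]).sum(axis=1) / wsum
        d_star[lo:hi] = (w * d_sup[None, :]).sum(axis=1) / wsum
    return g_star, d_star


def eb_batch_adjust(
    m: ExpressionMatrix,
    batches,
    mode: str = "nonparametric",
    n_mc: int = 10_000,
    seed: int = 0,
) -> ExpressionMatrix:
    """Empirical-Bayes location/scale batch adjustment (intercept-only model).

    Standardizes each gene, estimates per-batch additive and multiplicative
    effects, shrinks them toward common priors (parametric closed-form or
    nonparametric Monte-Carlo integration), removes them, and restores the
    original location and scale.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown mode {mode!r}")
    batches = np.asarray(batches)
    if len(batches) != m.n_samples:
        raise ValueError("batch labels must align with matrix samples")
    labels, inv = np.unique(batches, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("batch adjustment needs at least 2 batches")
    counts = np.bincount(inv)
    small = labels[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {small.tolist()}")

    X = m.values.to_numpy(dtype=float)
    G, n = X.shape
    # batch means and pooled residual variance (the "standardization" model)
    batch_means = np.stack([X[:, inv == b].mean(axis=1) for b in range(len(labels))], axis=1)
    grand = batch_means @ (counts / n)
    resid = X - batch_means[:, inv]
    var_pooled = np.maximum((resid**2).mean(axis=1), _VAR_FLOOR)
    sd_pooled = np.sqrt(var_pooled)
    Z = (X - grand[:, None]) / sd_pooled[:, None]

    rng = np.random.default_rng(seed)
    Zadj = np.empty_like(Z)
    for b in range(len(labels)):
        cols = inv == b
        zb = Z[:, cols]
        if mode == "parametric":
            g_star, d_star = _eb_parametric(zb, counts[b])
        else:
            g_star, d_star = _eb_nonparametric(zb, counts[b], n_mc, rng)
        d_star = np.maximum(d_star, _VAR_FLOOR)
        Zadj[:, cols] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    # re-centre residuals so the per-gene grand mean is preserved exactly
    Zadj -= (Zadj @ (np.ones(n) / n))[:, None]
    out = Zadj * sd_pooled[:, None] + grand[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), scale=m.scale
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Sample-space principal components of a gene-scaled matrix."""

    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components

    def __post_init__(self) -> None:
        vr = np.asarray(self.variance_ratio, dtype=float)
        if (vr < -1e-12).any() or (np.diff(vr) > 1e-12).any() or vr.sum() > 1 + 1e-9:
            raise ValueError("variance ratios must be non-negative, non-increasing, sum <= 1")
        self.variance_ratio = vr


def pca(m: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA with samples as observations.

    Requires a gene-scaled matrix. Sign convention: each component is
    oriented so its largest-magnitude gene loading is positive.
    """
    if m.scale != "scaled":
        raise ValueError("pca expects a gene-scaled matrix (run scale_genes first)")
    max_c = min(m.n_genes, m.n_samples)
    if n_components is None:
        n_components = max_c
    if n_components > max_c:
        raise ValueError(f"n_components={n_components} exceeds min(genes, samples)={max_c}")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation: largest-|loading| gene positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = (S**2).sum()
    ratio = (S**2) / total if total > 0 else np.zeros_like(S)
    comps = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame((U * S)[:, :n_components], index=m.sample_ids, columns=comps),
        variance_ratio=ratio[:n_components],
        loadings=pd.DataFrame(Vt[:n_components].T, index=m.gene_ids, columns=comps),
    )
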