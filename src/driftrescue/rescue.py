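"""Sign-concordance rescue classification and the transcriptome partition.

A drifted gene is *rescued* by a perturbation (laminar flow, smooth-muscle
co-culture) when the perturbation contrast is significant and moves culture
expression in the cord direction: sign(t_perturb) == sign(t_cord), where
the cord contrast is cord - culture and the perturbation contrast is
perturbed - unperturbed. The four sign categories are the concordant /
discordant table; the fractions partition the expressed transcriptome into
drifted = flow-only + co-culture-only + both + unrescued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drift import DriftTable, bonferroni_threshold
from .preprocess import ExpressionMatrix

CATEGORIES = (
    "concordant_up",
    "concordant_down",
    "discordant_up_down",
    "discordant_down_up",
    "drift_only",
    "not_drifted",
)

CONCORDANT = ("concordant_up", "concordant_down")


@dataclass
class RescueClassification:
    """Per-gene category plus the fraction summary for one perturbation."""

    table: pd.DataFrame  # index gene_id: cord_t, cord_q, perturb_t, perturb_q, category
    sig_rule: tuple
    n_expressed: int
    drifted_genes: frozenset

    @property
    def rescued_genes(self) -> pd.Index:
        return self.table.index[self.table["category"].isin(CONCORDANT)]

    @property
    def fraction_rescued(self) -> float:
        """Fraction of the expressed transcriptome rescued by this perturbation."""
        return len(self.rescued_genes) / self.n_expressed if self.n_expressed else np.nan

    @property
    def fraction_rescued_of_drifted(self) -> float:
        n = len(self.drifted_genes)
        return len(self.rescued_genes) / n if n else np.nan


def _perturb_significant(perturb: pd.DataFrame, sig_rule: tuple) -> np.ndarray:
    kind, level = sig_rule
    if kind == "fdr":
        return perturb["q"].to_numpy() < level
    if kind == "bonferroni":
        thr = bonferroni_threshold(level, len(perturb))
        return perturb["p"].to_numpy() < thr
    raise ValueError(f"unknown significance rule {kind!r}")


def concordance_classify(
    drift: DriftTable,
    de_perturb: pd.DataFrame,
    sig_rule: tuple = ("fdr", 0.05),
) -> RescueClassification:
    """Classify every gene by drift status and perturbation sign-concordance.

    ``de_perturb`` must index the same gene universe as the drift table and
    carry t, p and q columns for the perturbation contrast (perturbed minus
    unperturbed, so that a concordant perturbation has the same t sign as
    the cord-minus-culture contrast).
    """
    cord = drift.table
    if not cord.index.equals(de_perturb.index):
        if set(cord.index) != set(de_perturb.index):
            raise ValueError("gene universes of the drift table and perturbation DE differ")
        de_perturb = de_perturb.loc[cord.index]
    cord_t = cord["t_stat"].to_numpy()
    drifted = cord["drifted"].to_numpy()
    pt = de_perturb["t"].to_numpy()
    sig = _perturb_significant(de_perturb, sig_rule)

    category = np.full(len(cord), "not_drifted", dtype=object)
    d = drifted
    category[d] = "drift_only"
    conc = d & sig & (np.sign(pt) == np.sign(cord_t)) & (pt != 0)
    disc = d & sig & (np.sign(pt) == -np.sign(cord_t)) & (pt != 0)
    category[conc & (cord_t > 0)] = "concordant_up"
    category[conc & (cord_t < 0)] = "concordant_down"
    category[disc & (cord_t > 0)] = "discordant_up_down"
    category[disc & (cord_t < 0)] = "discordant_down_up"

    table = pd.DataFrame(
        {
            "cord_t": cord_t,
            "cord_q": cord["q"].to_numpy(),
            "perturb_t": pt,
            "perturb_q": de_perturb["q"].to_numpy(),
            "category": category,
        },
        index=cord.index,
    )
    return RescueClassification(
        table=table,
        sig_rule=tuple(sig_rule),
        n_expressed=drift.n_expressed,
        drifted_genes=frozenset(drift.drifted_genes),
    )


@dataclass
class RescuePartition:
    """Partition of the expressed transcriptome by drift and rescue status.

    All ``fraction_*`` fields are fractions of expressed genes; the
    ``of_drifted`` dict re-expresses the rescue terms relative to drifted
    genes. The identity drifted = flow_only + cc_only + both + unrescued
    holds exactly by construction.
    """

    n_expressed: int
    n_drifted: int
    n_flow_only: int
    n_cc_only: int
    n_both: int
    n_unrescued: int
    fractions: dict = field(default_factory=dict)
    of_drifted: dict = field(default_factory=dict)


def rescue_fractions(
    c_flow: RescueClassification,
    c_cc: RescueClassification | None,
    drift: DriftTable,
) -> RescuePartition:
    """Combine one or two perturbation classifications into the partition."""
    drifted = frozenset(drift.drifted_genes)
    for name, c in (("flow", c_flow), ("co-culture", c_cc)):
        if c is not None and c.drifted_genes != drifted:
            raise ValueError(f"{name} classification was built from a different drift table")
    flow = set(c_flow.rescued_genes)
    cc = set(c_cc.rescued_genes) if c_cc is not None else set()
    both = flow & cc
    n_exp = drift.n_expressed
    n_drift = len(drifted)
    part = RescuePartition(
        n_expressed=n_exp,
        n_drifted=n_drift,
        n_flow_only=len(flow - cc),
        n_cc_only=len(cc - flow),
        n_both=len(both),
        n_unrescued=n_drift - len(flow | cc),
    )
    f = lambda k: k / n_exp if n_exp else np.nan
    part.fractions = {
        "drifted": f(n_drift),
        "rescued_by_flow": f(len(flow)),
        "rescued_by_cc": f(len(cc)),
        "rescued_by_flow_only": f(part.n_flow_only),
        "rescued_by_cc_only": f(part.n_cc_only),
        "rescued_by_both": f(part.n_both),
        "rescued_by_either": f(len(flow | cc)),
        "unrescued": f(part.n_unrescued),
    }
    g = lambda k: k / n_drift if n_drift else np.nan
    part.of_drifted = {
        "rescued_by_flow": g(len(flow)),
        "rescued_by_cc": g(len(cc)),
        "rescued_by_either": g(len(flow | cc)),
        "unrescued": g(part.n_unrescued),
    }
    return part


# ---------------------------------------------------------------------------
# time-course correlation to cord
# ---------------------------------------------------------------------------


def timecourse_correlation(
    de_cord: pd.DataFrame,
    de_flow: dict,
    stat: str = "t",
) -> pd.DataFrame:
    """Correlation to the cord signature as a function of time under flow.

    For each timepoint, the Pearson correlation across genes between the
    cord-versus-culture statistic and the flow(t)-versus-static statistic.
    ``stat`` selects the t-statistic (default) or the mean difference
    ``delta``.
    """
    if stat not in ("t", "delta"):
        raise ValueError("stat must be 't' or 'delta'")
    if len(de_flow) < 2:
        raise ValueError("timecourse_correlation needs >= 2 timepoints")
    rows = []
    for t_h in sorted(de_flow):
        de_t = de_flow[t_h]
        shared = de_cord.index.intersection(de_t.index)
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared genes at timepoint {t_h}")
        x = de_cord.loc[shared, stat if stat in de_cord else "t"].to_numpy()
        y = de_t.loc[shared, stat].to_numpy()
        r, p = stats.pearsonr(x, y)
        rows.append({"timepoint_h": float(t_h), "r": float(r), "p": float(p),
                     "n_genes": len(shared)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-protein concordance
# ---------------------------------------------------------------------------


@dataclass
class CrossOmicResult:
    r: float
    p: float
    n_matched: int
    n_unmatched_rna: int
    n_unmatched_protein: int


def crossomic_concordance(
    de_rna: pd.DataFrame,
    de_protein: pd.DataFrame,
    id_map: pd.DataFrame,
) -> CrossOmicResult:
    """Pearson correlation of matched RNA and protein t-statistics.

    ``id_map`` must have ``gene_id`` and ``protein_id`` columns; unmatched
    identifiers are counted and reported, never silently dropped.
    """
    for col in ("gene_id", "protein_id"):
        if col not in id_map.columns:
            raise ValueError(f"id_map is missing the {col!r} column")
    pairs = id_map[
        id_map["gene_id"].isin(de_rna.index) & id_map["protein_id"].isin(de_protein.index)
    ]
    if len(pairs) == 0:
        raise ValueError("id_map yields zero matched gene/protein pairs")
    if len(pairs) < 3:
        raise ValueError(f"id_map yields only {len(pairs)} matched pairs; need >= 3")
    x = de_rna.loc[pairs["gene_id"], "t"].to_numpy()
    y = de_protein.loc[pairs["protein_id"], "t"].to_numpy()
    r, p = stats.pearsonr(x, y)
    return CrossOmicResult(
        r=float(r),
        p=float(p),
        n_matched=len(pairs),
        n_unmatched_rna=int((~de_rna.index.isin(pairs["gene_id"])).sum()),
        n_unmatched_protein=int((~de_protein.index.isin(pairs["protein_id"])).sum()),
    )


# ---------------------------------------------------------------------------
# gene-set module score
# ---------------------------------------------------------------------------


def geneset_module_score(
    m: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched gene-set score per sample.

    Genes are binned into ``n_bins`` quantile bins by average expression;
    for each set gene, ``n_ctrl`` control genes are drawn (seeded) from the
    non-set genes of its bin; the score is mean(set expression) minus
    mean(control expression) per sample. A bin with fewer candidates than
    ``n_ctrl`` is sampled with replacement (with a warning).
    """
    gene_set = pd.Index(gene_set).unique()
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    missing = gene_set.difference(m.gene_ids)
    if len(missing):
        raise ValueError(f"gene_set members absent from the matrix: {missing[:5].tolist()}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    avg = m.values.mean(axis=1)
    # deterministic quantile bins; ties broken by stable rank
    ranks = avg.rank(method="first").to_numpy()
    bins = np.minimum((ranks - 1) * n_bins // len(avg), n_bins - 1).astype(int)
    bin_of = pd.Series(bins, index=m.gene_ids)
    in_set = m.gene_ids.isin(gene_set)

    ctrl_rows: list[np.ndarray] = []
    X = m.values.to_numpy(dtype=float)
    warned = False
    for g in gene_set:
        b = bin_of[g]
        candidates = np.flatnonzero((bins == b) & ~in_set)
        if len(candidates) == 0:
            # set covers the whole bin: fall back to the full bin
            candidates = np.flatnonzero(bins == b)
        if len(candidates) < n_ctrl:
            if not warned:
                warnings.warn(
                    f"bin with only {len(candidates)} control candidates; "
                    f"sampling with replacement", stacklevel=2
                )
                warned = True
            chosen = rng.choice(candidates, size=n_ctrl, replace=True)
        else:
            chosen = rng.choice(candidates, size=n_ctrl, replace=False)
        ctrl_rows.append(chosen)
    ctrl_idx = np.concatenate(ctrl_rows)
    set_mean = X[m.gene_ids.isin(gene_set)].mean(axis=0)
    ctrl_mean = X[ctrl_idx].mean(axis=0)
    return pd.Series(set_mean - ctrl_mean, index=m.sample_ids, name="module_score")


def top_table(classification: RescueClassification, n: int = 30) -> pd.DataFrame:
    """Most-drifted genes (sorted by cord FDR) with their rescue categories."""
    tab = classification.table
    drifted = tab[tab.index.isin(classification.drifted_genes)]
    return drifted.sort_values("cord_q").head(n)
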