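"""Synthetic multi-environment expression data with known planted truth.

Emulates the study design the pipeline targets: paired donors sampled at
the vessel (cord), at early and at late culture passage; a second donor arm
cultured static versus under laminar flow across a time course; a
mono-culture versus smooth-muscle co-culture arm; and a protein layer whose
per-gene effects correlate imperfectly with the RNA effects.

Expression is generated directly on the log10 scale as

    x_gs = b_g + lambda * f_{m(g),s} + delta_g * culture(s) * (1 - rho(s,g))
           + beta_{batch(s),g} + eps_gs

where ``delta_g`` is the planted culture drift (zero for non-drifted genes),
``rho`` is the rescue factor (t/t_max for flow-rescued genes under flow,
1 for co-culture-rescued genes in co-culture, 0 otherwise), module factors
``f`` are standard normal per sample, batch effects are additive and
mean-zero across batches, and ``eps`` is Gaussian noise. Cord samples never
carry drift or rescue terms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CULTURE_ENVIRONMENTS, ExpressionMatrix

UNASSIGNED = ""  # module label for genes outside any planted module


def _check_fraction(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class GeneratorParams:
    """Design parameters of the synthetic study.

    Fractions ``pi_drift``, ``pi_flow_rescue`` and ``pi_cc_rescue`` are all
    expressed relative to the whole transcriptome (the convention in which
    the planted 0.43 / 0.17 / 0.09 partition is stated); the two rescue
    fractions are converted internally to fractions of drifted genes and are
    disjoint unless ``rescue_overlap`` > 0. Effect sizes and noise are in
    log10 units.
    """

    n_genes: int = 10_000
    donors_paired: int = 7
    donors_flow: int = 4
    timepoints_h: tuple[float, ...] = (0.0, 0.5, 8.0, 24.0, 48.0)
    pi_drift: float = 0.43
    pi_flow_rescue: float = 0.17
    pi_cc_rescue: float = 0.09
    drift_effect_mean: float = 2.5
    drift_effect_sd: float = 0.5
    n_modules: int = 5
    module_size: int = 200
    module_loading: float = 0.25
    noise_sd: float = 0.25
    batch_shift_sd: float = 0.2
    n_batches: int = 2
    protein_rho: float = 0.4
    protein_fraction: float = 0.3
    seed: int = 0
    baseline_mean: float = 1.5
    baseline_sd: float = 0.5
    rescue_overlap: float = 0.0  # fraction of drifted genes rescued by both

    def validate(self) -> None:
        for name in ("pi_drift", "pi_flow_rescue", "pi_cc_rescue", "protein_fraction",
                     "rescue_overlap"):
            _check_fraction(name, getattr(self, name))
        for name in ("n_genes", "donors_paired", "donors_flow", "n_modules",
                     "module_size", "n_batches"):
            if getattr(self, name) < 0 or int(getattr(self, name)) != getattr(self, name):
                raise ValueError(f"{name} must be a non-negative integer")
        for name in ("drift_effect_sd", "noise_sd", "batch_shift_sd", "drift_effect_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1 <= self.protein_rho <= 1:
            raise ValueError("protein_rho must be in [-1, 1]")
        tp = tuple(self.timepoints_h)
        if len(tp) == 0:
            raise ValueError("timepoints_h must be non-empty")
        if any(t < 0 for t in tp):
            raise ValueError("timepoints_h must be non-negative hours")
        if list(tp) != sorted(tp) or tp[0] != 0:
            raise ValueError("timepoints_h must be sorted ascending with first entry 0")
        if self.pi_drift > 0:
            if self.pi_flow_rescue + self.pi_cc_rescue > self.pi_drift + 1e-12:
                raise ValueError(
                    "pi_flow_rescue + pi_cc_rescue must not exceed pi_drift "
                    "(rescued genes are drifted genes)"
                )
        elif self.pi_flow_rescue > 0 or self.pi_cc_rescue > 0:
            raise ValueError("rescue fractions require pi_drift > 0")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"n_modules*module_size = {self.n_modules * self.module_size} "
                f"exceeds n_genes = {self.n_genes}"
            )


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth plus realized dataset-level fractions."""

    table: pd.DataFrame  # index gene_id: drift_direction, delta, flow_rescued,
    #                       cc_rescued, module_id, protein_mapped, baseline
    realized_fractions: dict
    seed: int
    params: GeneratorParams

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")


def _draw_truth(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    G = params.n_genes
    drifted = rng.random(G) < params.pi_drift
    direction = np.where(drifted, rng.choice([-1, 1], size=G), 0)
    delta = np.where(
        drifted, direction * np.abs(rng.normal(params.drift_effect_mean,
                                               params.drift_effect_sd, G)), 0.0
    )

    flow_rescued = np.zeros(G, bool)
    cc_rescued = np.zeros(G, bool)
    if params.pi_drift > 0:
        p_flow = params.pi_flow_rescue / params.pi_drift
        p_cc = params.pi_cc_rescue / params.pi_drift
        p_both = min(params.rescue_overlap, p_flow, p_cc)
        u = rng.random(G)
        idx = np.flatnonzero(drifted)
        uu = u[idx]
        flow_rescued[idx[uu < p_flow]] = True
        cc_rescued[idx[(uu >= p_flow - p_both) & (uu < p_flow - p_both + p_cc)]] = True

    module_id = np.full(G, UNASSIGNED, dtype=object)
    if params.n_modules > 0 and params.module_size > 0:
        # the first module is the planted cord-associated one: preferentially
        # built from drifted, cord-up (direction -1) genes so its condition
        # association is fully accounted in the drift truth
        cord_up = np.flatnonzero((direction == -1))
        cord_up = rng.permutation(cord_up)
        m0 = cord_up[: params.module_size]
        if len(m0) < params.module_size:
            rest_pool = np.setdiff1d(np.arange(G), m0)
            extra = rng.choice(rest_pool, params.module_size - len(m0), replace=False)
            m0 = np.concatenate([m0, extra])
        module_id[m0] = "module_1"
        pool = rng.permutation(np.setdiff1d(np.arange(G), m0))
        for k in range(1, params.n_modules):
            members = pool[(k - 1) * params.module_size: k * params.module_size]
            module_id[members] = f"module_{k + 1}"

    protein_mapped = rng.random(G) < params.protein_fraction
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, G)
    return pd.DataFrame(
        {
            "drift_direction": direction,
            "delta": delta,
            "flow_rescued": flow_rescued,
            "cc_rescued": cc_rescued,
            "module_id": module_id,
            "protein_mapped": protein_mapped,
            "baseline": baseline,
        },
        index=_gene_ids(G),
    )


def _batch_effects(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Per-(batch, gene) additive shifts, mean-zero across batches per gene."""
    beta = rng.normal(0.0, params.batch_shift_sd, size=(params.n_batches, params.n_genes))
    if params.n_batches > 1:
        beta -= beta.mean(axis=0, keepdims=True)
    else:
        beta[:] = 0.0
    return beta


def _module_matrix(truth_table: pd.DataFrame, params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    """(gene -> module index or -1, loading vector)."""
    mod = truth_table["module_id"].to_numpy()
    names = [f"module_{k + 1}" for k in range(params.n_modules)]
    lookup = {name: k for k, name in enumerate(names)}
    midx = np.array([lookup.get(x, -1) for x in mod])
    return midx, np.array(names, dtype=object)


def _assemble(
    params: GeneratorParams,
    truth_table: pd.DataFrame,
    samples: pd.DataFrame,
    rescue_rho: np.ndarray,  # genes x samples
    rng: np.random.Generator,
) -> ExpressionMatrix:
    G = params.n_genes
    n = len(samples)
    midx, _ = _module_matrix(truth_table, params)
    factors = rng.normal(size=(max(params.n_modules, 1), n))
    module_term = np.zeros((G, n))
    in_mod = midx >= 0
    if in_mod.any():
        module_term[in_mod] = params.module_loading * factors[midx[in_mod]]

    culture = samples["environment"].isin(CULTURE_ENVIRONMENTS).to_numpy().astype(float)
    delta = truth_table["delta"].to_numpy()[:, None]
    drift_term = delta * culture[None, :] * (1.0 - rescue_rho)

    beta = _batch_effects(params, rng)
    batch_idx = samples["batch"].map(
        {b: i for i, b in enumerate(sorted(samples["batch"].unique()))}
    ).to_numpy()
    # reuse the same per-gene batch effect vector for matching batch labels
    batch_term = beta[batch_idx % params.n_batches].T if params.n_batches else 0.0

    noise = rng.normal(0.0, params.noise_sd, size=(G, n))
    X = truth_table["baseline"].to_numpy()[:, None] + module_term + drift_term + batch_term + noise
    values = pd.DataFrame(X, index=truth_table.index, columns=samples["sample_id"].to_numpy())
    return ExpressionMatrix(values, scale="log10")


def _study_samples(params: GeneratorParams) -> pd.DataFrame:
    rows = []
    t_max = max(params.timepoints_h)
    for d in range(params.donors_paired):
        donor = f"P{d + 1}"
        for env in ("cord", "early_culture", "late_culture"):
            rows.append((f"{donor}_{env}", donor, env, np.nan, "rna"))
    for d in range(params.donors_flow):
        donor = f"F{d + 1}"
        rows.append((f"{donor}_static", donor, "static", 0.0, "rna"))
        rows.append((f"{donor}_flow", donor, "flow", t_max, "rna"))
    for d in range(params.donors_flow):
        donor = f"C{d + 1}"
        rows.append((f"{donor}_mono", donor, "mono_culture", np.nan, "rna"))
        rows.append((f"{donor}_co", donor, "co_culture", np.nan, "rna"))
    df = pd.DataFrame(rows, columns=["sample_id", "donor", "environment", "timepoint_h", "layer"])
    # batches alternate within arms so condition and batch are not confounded
    df["batch"] = [f"B{i % max(params.n_batches, 1) + 1}" for i in range(len(df))]
    return df[["sample_id", "donor", "environment", "timepoint_h", "batch", "layer"]]


def _rescue_rho(truth_table: pd.DataFrame, samples: pd.DataFrame, t_max: float) -> np.ndarray:
    G = len(truth_table)
    rho = np.zeros((G, len(samples)))
    flow_g = truth_table["flow_rescued"].to_numpy()[:, None]
    cc_g = truth_table["cc_rescued"].to_numpy()[:, None]
    env = samples["environment"].to_numpy()
    tp = samples["timepoint_h"].to_numpy(dtype=float)
    is_flow = (env == "flow")[None, :]
    frac = np.where(np.isnan(tp) | (t_max == 0), 0.0, tp / t_max)[None, :]
    rho += flow_g * is_flow * frac
    rho += cc_g * (env == "co_culture")[None, :]
    return np.clip(rho, 0.0, 1.0)


def generate_study(params: GeneratorParams):
    """Generate the full multi-arm study.

    Returns ``(matrix, samples, truth)``; the matrix is on the log10 scale
    with one column per (donor, condition) sample.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    truth_table = _draw_truth(params, rng)
    samples = _study_samples(params)
    rho = _rescue_rho(truth_table, samples, max(params.timepoints_h))
    matrix = _assemble(params, truth_table, samples, rho, rng)

    G = params.n_genes
    realized = {
        "drifted": float((truth_table["drift_direction"] != 0).mean()),
        "flow_rescued": float(truth_table["flow_rescued"].mean()),
        "cc_rescued": float(truth_table["cc_rescued"].mean()),
        "protein_mapped": float(truth_table["protein_mapped"].mean()),
    }
    truth = SyntheticTruth(truth_table, realized, params.seed, dataclasses.replace(params))
    return matrix, samples, truth


def generate_timecourse(params: GeneratorParams, truth: SyntheticTruth):
    """One sample per (flow donor, timepoint); flow-rescued drift decays
    linearly to zero at the last timepoint, other drifted genes keep full
    delta throughout. The t = 0 samples are the static controls."""
    params.validate()
    if len(params.timepoints_h) == 0:
        raise ValueError("timepoints_h must be non-empty")
    if truth.seed != params.seed:
        raise ValueError("truth was generated under a different seed")
    rng = np.random.default_rng([params.seed, 1])
    rows = []
    for d in range(params.donors_flow):
        donor = f"F{d + 1}"
        for t in params.timepoints_h:
            env = "static" if t == 0 else "flow"
            rows.append((f"{donor}_t{t:g}h", donor, env, float(t),
                         f"B{d % max(params.n_batches, 1) + 1}", "rna"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "donor", "environment", "timepoint_h", "batch", "layer"]
    )
    rho = _rescue_rho(truth.table, samples, max(params.timepoints_h))
    matrix = _assemble(params, truth.table, samples, rho, rng)
    return matrix, samples


class EmptyProteinLayerError(ValueError):
    """Raised when no genes are mapped to the protein layer."""


def generate_protein_layer(params: GeneratorParams, truth: SyntheticTruth):
    """Protein abundance matrix for mapped genes plus the gene<->protein map.

    Planted protein effects follow delta'_g = rho*delta_g + sd(delta)*
    sqrt(1-rho^2)*eta_g, so corr(delta, delta') targets ``protein_rho``.
    """
    params.validate()
    if params.protein_fraction == 0:
        raise EmptyProteinLayerError("protein_fraction is 0: no protein layer to generate")
    mapped = truth.table["protein_mapped"].to_numpy()
    if not mapped.any():
        raise EmptyProteinLayerError("no genes were mapped to proteins under this seed")
    rng = np.random.default_rng([params.seed, 2])

    delta = truth.table["delta"].to_numpy()[mapped]
    sd_delta = delta.std(ddof=1)
    if sd_delta == 0:
        sd_delta = 1.0
    eta = rng.normal(size=mapped.sum())
    rho = params.protein_rho
    delta_p = rho * delta + sd_delta * np.sqrt(1 - rho**2) * eta

    genes = truth.table.index[mapped]
    protein_ids = pd.Index([f"PR_{g}" for g in genes], name="protein_id")
    id_map = pd.DataFrame({"gene_id": genes.to_numpy(), "protein_id": protein_ids.to_numpy()})

    rows = []
    for d in range(params.donors_paired):
        donor = f"P{d + 1}"
        rows.append((f"{donor}_cord_prot", donor, "cord", np.nan, "B1", "protein"))
        rows.append((f"{donor}_culture_prot", donor, "late_culture", np.nan, "B1", "protein"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "donor", "environment", "timepoint_h", "batch", "layer"]
    )
    culture = samples["environment"].isin(CULTURE_ENVIRONMENTS).to_numpy().astype(float)
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, mapped.sum())
    noise = rng.normal(0.0, params.noise_sd, size=(mapped.sum(), len(samples)))
    X = baseline[:, None] + delta_p[:, None] * culture[None, :] + noise
    values = pd.DataFrame(X, index=protein_ids, columns=samples["sample_id"].to_numpy())
    matrix = ExpressionMatrix(values, scale="log10")
    matrix._planted_protein_delta = pd.Series(delta_p, index=protein_ids)  # for truth checks
    return matrix, id_map, samples


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Export a log10-scale matrix as TPM-like linear values (10^x - 1)."""
    if m.scale != "log10":
        raise ValueError("to_linear expects a log10-scale matrix")
    vals = np.power(10.0, m.values.to_numpy()) - 1.0
    vals = np.maximum(vals, 0.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids), scale="linear"
    )
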