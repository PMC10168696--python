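"""End-to-end pipeline driver: generate (optional) -> preprocess -> drift
screen -> rescue classification -> co-expression modules -> time profiles,
with every per-gene artifact written as TSV and a JSON run report whose
numbers are recomputable from those artifacts."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as drio
from .drift import de_contrast, drift_screen
from .network import NetworkParams, build_network_modules, module_trait_correlation
from .preprocess import eb_batch_adjust, log_transform, pca, scale_genes
from .profiles import build_profiles, write_profile_table
from .rescue import concordance_classify, crossomic_concordance, rescue_fractions, top_table
from .synthetic import (
    GeneratorParams,
    generate_protein_layer,
    generate_study,
    generate_timecourse,
)

log = logging.getLogger("driftrescue")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "driftrescue_out"
    seed: int = 0
    # either generate synthetic data ...
    generate: bool = True
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    # ... or read matrices from disk
    expression_path: str | None = None
    samples_path: str | None = None
    protein_path: str | None = None
    protein_samples_path: str | None = None
    id_map_path: str | None = None
    input_scale: str = "linear"
    # stage toggles
    run_drift: bool = True
    run_rescue: bool = True
    run_network: bool = True
    run_profiles: bool = True
    # thresholds
    alpha: float = 0.05
    drift_rule: str = "bonferroni"
    perturb_rule: tuple = ("fdr", 0.05)
    bonferroni_m: int | None = None
    batch_mode: str = "parametric"
    n_network_genes: int = 2000
    network: NetworkParams = field(default_factory=NetworkParams)

    def validate(self) -> None:
        if self.generate:
            self.generator.validate()
        else:
            for name in ("expression_path", "samples_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when generate is off")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")
        if self.drift_rule not in ("bonferroni", "fdr"):
            raise ValueError(f"unknown drift rule {self.drift_rule!r}")
        self.network.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorParams(**raw.pop("generator", {}))
        net = NetworkParams(**raw.pop("network", {}))
        if "perturb_rule" in raw:
            raw["perturb_rule"] = tuple(raw["perturb_rule"])
        cfg = cls(generator=gen, network=net, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Per-stage summaries; every number is recomputable from the TSVs."""

    version: str
    seed: int
    config: dict
    drift: dict = field(default_factory=dict)
    rescue: dict = field(default_factory=dict)
    timecourse: list = field(default_factory=list)
    crossomic: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def run_pipeline(config: PipelineConfig) -> RunReport:
    t0 = time.time()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = drio.config_hash(config.to_dict())
    _setup_logging(outdir / "run.log")
    log.info("driftrescue v%s starting (seed=%s, config %s)", __version__, config.seed, cfg_hash)

    report = RunReport(version=__version__, seed=config.seed, config=config.to_dict())
    stage = "generate"
    try:
        if config.generate:
            params = dataclasses.replace(config.generator, seed=config.seed)
            study, samples, truth = generate_study(params)
            tc_matrix, tc_samples = generate_timecourse(params, truth)
            protein = id_map = protein_samples = None
            if params.protein_fraction > 0:
                protein, id_map, protein_samples = generate_protein_layer(params, truth)
            drio.write_expression(study, outdir / "expression.tsv", config.seed, cfg_hash)
            drio.write_samples(samples, outdir / "samples.tsv", config.seed, cfg_hash)
            drio.write_expression(tc_matrix, outdir / "timecourse.tsv", config.seed, cfg_hash)
            drio.write_samples(tc_samples, outdir / "timecourse_samples.tsv", config.seed, cfg_hash)
            drio.write_truth(truth, outdir / "truth.tsv")
            if protein is not None:
                drio.write_expression(protein, outdir / "protein.tsv", config.seed, cfg_hash)
                drio.write_id_map(id_map, outdir / "id_map.tsv", config.seed)
            log.info("generated %d genes x %d samples", study.n_genes, study.n_samples)
        else:
            study = drio.read_expression(config.expression_path, scale=config.input_scale)
            samples = drio.read_samples(config.samples_path)
            tc_matrix = tc_samples = None
            protein = protein_samples = id_map = None
            if config.protein_path:
                protein = drio.read_expression(config.protein_path, scale=config.input_scale)
                protein_samples = drio.read_samples(config.protein_samples_path)
                id_map = drio.read_id_map(config.id_map_path)

        stage = "preprocess"
        if study.scale == "linear":
            study = log_transform(study)
        n_batches = samples["batch"].nunique()
        if n_batches >= 2:
            study = eb_batch_adjust(
                study, samples["batch"].to_numpy(), mode=config.batch_mode, seed=config.seed
            )
            log.info("batch-adjusted %d batches (%s)", n_batches, config.batch_mode)
        scaled = scale_genes(study)
        pca_res = pca(scaled, n_components=min(5, scaled.n_samples - 1))
        report.pca = {
            "variance_ratio": pca_res.variance_ratio.tolist(),
        }

        drift_tab = None
        if config.run_drift:
            stage = "drift"
            drift_tab = drift_screen(
                study,
                samples,
                rule=config.drift_rule,
                alpha=config.alpha,
                m_tests=config.bonferroni_m,
            )
            drio.write_tsv(drift_tab.table, outdir / "drift.tsv", config.seed, cfg_hash)
            report.drift = {
                "n_expressed": drift_tab.n_expressed,
                "n_drifted": drift_tab.n_drifted,
                "fraction_drifted": drift_tab.fraction_drifted,
                "rule": drift_tab.rule,
            }
            log.info("drift screen: %.1f%% of %d expressed genes drifted",
                     100 * drift_tab.fraction_drifted, drift_tab.n_expressed)

        if config.run_rescue and drift_tab is not None:
            stage = "rescue"
            envs = set(samples["environment"])
            c_flow = c_cc = None
            if {"flow", "static"} <= envs:
                de_flow = de_contrast(study, samples, "flow", "static")
                c_flow = concordance_classify(drift_tab, de_flow, config.perturb_rule)
                drio.write_tsv(c_flow.table, outdir / "rescue_flow.tsv", config.seed, cfg_hash)
                drio.write_tsv(top_table(c_flow), outdir / "rescue_flow_top30.tsv",
                               config.seed, cfg_hash)
            if {"co_culture", "mono_culture"} <= envs:
                de_cc = de_contrast(study, samples, "co_culture", "mono_culture")
                c_cc = concordance_classify(drift_tab, de_cc, config.perturb_rule)
                drio.write_tsv(c_cc.table, outdir / "rescue_cc.tsv", config.seed, cfg_hash)
            if c_flow is not None:
                part = rescue_fractions(c_flow, c_cc, drift_tab)
                report.rescue = {"fractions": part.fractions, "of_drifted": part.of_drifted}
                with open(outdir / "rescue_partition.json", "w") as fh:
                    json.dump(report.rescue, fh, indent=1)
                log.info("rescue partition: %s", {k: round(v, 3) for k, v in part.fractions.items()})

            if tc_matrix is not None:
                de_by_t = {}
                tc_log = tc_matrix if tc_matrix.scale != "linear" else log_transform(tc_matrix)
                for t_h in sorted(set(tc_samples["timepoint_h"].dropna()) - {0.0}):
                    sel = tc_samples[
                        (tc_samples["timepoint_h"] == t_h) | (tc_samples["timepoint_h"] == 0.0)
                    ]
                    sub = tc_log.subset_samples(sel["sample_id"].to_numpy())
                    de_by_t[t_h] = de_contrast(sub, sel, "flow", "static")
                if len(de_by_t) >= 2:
                    from .rescue import timecourse_correlation

                    tc_corr = timecourse_correlation(drift_tab.table.rename(
                        columns={"t_stat": "t"}), de_by_t)
                    drio.write_tsv(tc_corr, outdir / "timecourse_correlation.tsv",
                                   config.seed, cfg_hash, index=False)
                    report.timecourse = tc_corr.to_dict("records")

            if protein is not None and id_map is not None:
                if protein.scale == "linear":
                    protein = log_transform(protein)
                de_prot = de_contrast(protein, protein_samples, "cord",
                                      ("early_culture", "late_culture"))
                xo = crossomic_concordance(
                    drift_tab.table.rename(columns={"t_stat": "t"}), de_prot, id_map
                )
                report.crossomic = dataclasses.asdict(xo)
                log.info("RNA-protein concordance r=%.3f (n=%d)", xo.r, xo.n_matched)

        if config.run_network:
            stage = "coexpression"
            var_rank = study.values.var(axis=1).sort_values(ascending=False)
            top = var_rank.index[: min(config.n_network_genes, study.n_genes)]
            net_matrix = scale_genes(study.subset_genes(top))
            labels, eig, var_exp = build_network_modules(net_matrix, config.network)
            traits = pd.DataFrame(
                {
                    "cord": (samples["environment"] == "cord").astype(float).to_numpy(),
                    "flow": (samples["environment"] == "flow").astype(float).to_numpy(),
                },
                index=samples["sample_id"].to_numpy(),
            )
            drio.write_tsv(labels.to_frame(), outdir / "module_labels.tsv", config.seed, cfg_hash)
            drio.write_tsv(eig, outdir / "module_eigengenes.tsv", config.seed, cfg_hash)
            sizes = labels.value_counts().to_dict()
            report.modules = {"n_modules": len(eig.index), "sizes": sizes}
            if len(eig.index):
                mt = module_trait_correlation(eig, traits)
                drio.write_tsv(mt, outdir / "module_trait.tsv", config.seed, cfg_hash, index=False)
            log.info("modules: %s", sizes)

        if config.run_profiles and tc_matrix is not None:
            stage = "profiles"
            tc_log = tc_matrix if tc_matrix.scale != "linear" else log_transform(tc_matrix)
            prof = build_profiles(tc_log, tc_samples)
            write_profile_table(prof, outdir / "profiles.tsv", outdir / "profiles.json")

        with open(outdir / "report.json", "w") as fh:
            fh.write(report.to_json())
        log.info("finished in %.1f s", time.time() - t0)
        return report
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _setup_logging(logfile) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_dr_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler()
        h._dr_tag = "stderr"
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    fh = logging.FileHandler(logfile)
    fh._dr_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    for h in list(log.handlers):
        if getattr(h, "_dr_tag", None) == "file":
            log.removeHandler(h)
    log.addHandler(fh)
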