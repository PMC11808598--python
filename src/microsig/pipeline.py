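"""End-to-end orchestration: load or simulate profiles, build per-tissue
cores and their union, run the iterated signature models, test the
positive tissues for contamination resilience, and optionally transfer the
resilient models onto an external cohort against a shuffled-label null.

Every stage logs its parameters and seeds, writes its artifacts into the
output directory, and contributes to a consolidated ``report.json`` that
records everything needed to reproduce each number it contains.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import community, io
from .containers import ConfigurationError, CountMatrix
from .contamination import ContaminationStudy, build_default_scenario
from .models import ModelSpec, TissueSignatureModel
from .normalize import DEFAULT_QUANTILE, DEFAULT_SCALE
from .simulate import CohortConfig, generate_cohort, generate_external_cohort
from .validation import TransferStudy, random_label_null

logger = logging.getLogger("microsig.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either the three input paths or a synthetic ``cohort`` config must be
    given. Thresholds default to the signature-detection settings
    (prevalence 0.10, AUROC 0.70, relative AUPR 1.4, alpha 0.05).
    """

    output_dir: str = "microsig_run"
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    cohort: CohortConfig | None = None
    genus_level: bool = False
    prevalence_threshold: float = 0.10
    auroc_min: float = 0.70
    rel_aupr_min: float = 1.4
    alpha: float = 0.05
    css_quantile: float = DEFAULT_QUANTILE
    css_scale: float = DEFAULT_SCALE
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    run_contamination: bool = True
    run_transfer: bool = False
    external_samples_per_tissue: int = 6
    external_library_shift: float = 1.0
    master_seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cohort is None and (self.counts_path is None or self.metadata_path is None):
            raise ConfigurationError(
                "counts_path", "either input paths or a synthetic cohort config is required"
            )
        for name, lo, hi in (
            ("prevalence_threshold", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("auroc_min", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(name, f"must lie in [{lo}, {hi}]")
        if self.rel_aupr_min < 0:
            raise ConfigurationError("rel_aupr_min", "must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        spec = raw.pop("model_spec", None)
        config = cls(**raw)
        if cohort is not None:
            if "signature_tissues" in cohort:
                cohort["signature_tissues"] = tuple(cohort["signature_tissues"])
            if "baseline_prevalence_range" in cohort:
                cohort["baseline_prevalence_range"] = tuple(cohort["baseline_prevalence_range"])
            config.cohort = CohortConfig(**cohort)
        if spec is not None:
            for key in ("interaction_depth_grid", "n_trees_grid"):
                if key in spec:
                    spec[key] = tuple(spec[key])
            config.model_spec = ModelSpec(**spec)
        return config


def _configure_logging(outdir: Path, level: str) -> None:
    handlers = [logging.StreamHandler(), logging.FileHandler(outdir / "run.log")]
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    root = logging.getLogger("microsig")
    root.setLevel(level.upper())
    for h in list(root.handlers):
        root.removeHandler(h)
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("load_or_simulate")
def _load_or_simulate(config: RunConfig, outdir: Path):
    if config.cohort is not None:
        counts, meta = generate_cohort(config.cohort)
        logger.info("simulated cohort: seed=%d", config.cohort.seed)
    else:
        counts = io.read_count_table(config.counts_path)
        meta = io.read_metadata(config.metadata_path)
        if config.taxonomy_path:
            counts.taxonomy = io.read_taxonomy(config.taxonomy_path)
    io.write_count_table(counts, outdir / "counts.tsv")
    io.write_metadata(meta, outdir / "metadata.tsv")
    return counts, meta


@_stage("aggregate")
def _aggregate(counts: CountMatrix, outdir: Path) -> CountMatrix:
    if counts.taxonomy is None:
        raise ValueError("genus-level run requested but no taxonomy map available")
    genus = io.aggregate_taxa(counts, counts.taxonomy)
    io.write_count_table(genus, outdir / "counts_genus.tsv")
    return genus


@_stage("core_microbiome")
def _cores(counts, meta, config: RunConfig, outdir: Path):
    cores_dir = outdir / "cores"
    cores_dir.mkdir(exist_ok=True)
    cores = []
    for tissue in meta.tissues:
        core = community.core_microbiome(counts, meta, tissue, config.prevalence_threshold)
        core.write_json(cores_dir / f"{tissue}.json")
        logger.info("core %s: %d species at threshold %.2f", tissue, len(core), core.threshold)
        cores.append(core)
    union, table = community.core_union_and_intersections(cores)
    community.write_intersections(table, outdir / "core_intersections.tsv")
    logger.info("core union: %d species", len(union))
    return cores, union


@_stage("signature_models")
def _signatures(counts, meta, union, config: RunConfig, outdir: Path):
    results = {}
    for tissue in meta.tissues:
        model = TissueSignatureModel(
            counts,
            meta,
            tissue,
            union,
            config.model_spec,
            quantile=config.css_quantile,
            scale_constant=config.css_scale,
            store_models=config.run_transfer,
        )
        res = model.fit()
        results[tissue] = res
        logger.info(
            "signature %s: mean AUROC %.3f, mean rel. AUPR %.3f, verdict %s",
            tissue,
            res.mean_auroc,
            res.mean_relative_aupr,
            res.verdict(config.auroc_min, config.rel_aupr_min),
        )
    sig_dir = outdir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for tissue, res in results.items():
        (sig_dir / f"{tissue}.json").write_text(json.dumps(res.to_dict(), indent=1, sort_keys=True))
    return results


@_stage("contamination")
def _contamination(counts, meta, union, positives, config: RunConfig, outdir: Path):
    scenario = build_default_scenario(meta, seed=config.master_seed)
    scenario.write_json(outdir / "contamination_scenario.json")
    study = ContaminationStudy(
        counts,
        meta,
        positives,
        union,
        scenario,
        config.model_spec,
        quantile=config.css_quantile,
        scale_constant=config.css_scale,
        alpha=config.alpha,
    )
    results = study.fit()
    results.to_frame().to_csv(outdir / "resilience_summary.tsv", sep="\t", index=False)
    for tissue, verdict in results.verdicts().items():
        logger.info("resilience %s: %s", tissue, verdict)
    return results


@_stage("transfer")
def _transfer(counts, meta, sig_results, resilient, union, config: RunConfig, outdir: Path):
    counts_ext, meta_ext = generate_external_cohort(
        config.cohort,
        n_samples_per_tissue=config.external_samples_per_tissue,
        shift_library_size=config.external_library_shift,
    )
    io.write_count_table(counts_ext, outdir / "external_counts.tsv")
    io.write_metadata(meta_ext, outdir / "external_metadata.tsv")
    reports = {}
    for tissue in resilient:
        trained = sig_results[tissue]
        null = random_label_null(counts, meta, tissue, union, config.model_spec)
        study = TransferStudy(
            trained,
            null,
            counts_ext,
            meta_ext,
            feature_universe=union,
            alpha=config.alpha,
            auroc_min=config.auroc_min,
            rel_aupr_min=config.rel_aupr_min,
        )
        reports[tissue] = study.fit()
        logger.info("transfer %s: preserved=%s", tissue, reports[tissue].preserved)
    return reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the consolidated run report.

    The report is also written to ``<output_dir>/report.json``; it contains
    no timestamps, so identical configs and seeds reproduce it byte for
    byte.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _configure_logging(outdir, config.log_level)

    counts, meta = _load_or_simulate(config, outdir)
    if config.genus_level:
        counts = _aggregate(counts, outdir)
    cores, union = _cores(counts, meta, config, outdir)
    sig_results = _signatures(counts, meta, union, config, outdir)
    verdicts = {
        t: r.verdict(config.auroc_min, config.rel_aupr_min) for t, r in sig_results.items()
    }
    positives = [t for t, v in verdicts.items() if v]

    report = {
        "config": {
            "prevalence_threshold": config.prevalence_threshold,
            "auroc_min": config.auroc_min,
            "rel_aupr_min": config.rel_aupr_min,
            "alpha": config.alpha,
            "css_quantile": config.css_quantile,
            "css_scale": config.css_scale,
            "master_seed": config.master_seed,
            "model_spec": dataclasses.asdict(config.model_spec),
            "cohort": dataclasses.asdict(config.cohort) if config.cohort else None,
            "genus_level": config.genus_level,
        },
        "core_sizes": {c.tissue: len(c) for c in cores},
        "core_union_size": len(union),
        "signatures": {
            t: {
                "mean_auroc": r.mean_auroc,
                "mean_aupr": r.mean_aupr,
                "mean_relative_aupr": r.mean_relative_aupr,
                "ci_margin": r.ci_margins(),
                "iteration_seeds": r.iteration_seeds,
                "selected_hyperparameters": [
                    {"interaction_depth": d, "n_trees": n}
                    for d, n in r.selected_hyperparameters
                ],
                "verdict": verdicts[t],
            }
            for t, r in sig_results.items()
        },
        "signature_positive_tissues": positives,
    }

    if config.run_contamination and len(positives) >= 1 and len(meta.tissues) >= 2:
        res = _contamination(counts, meta, union, positives, config, outdir)
        report["resilience"] = {
            t: r.report.to_dict() for t, r in res.per_tissue.items()
        }
        resilient = [t for t, v in res.verdicts().items() if v == "resilient"]
        report["resilient_tissues"] = resilient
    else:
        resilient = positives

    if config.run_transfer:
        if config.cohort is None:
            raise StageError("transfer", ValueError("transfer requires a synthetic cohort config"))
        reports = _transfer(counts, meta, sig_results, resilient, union, config, outdir)
        report["transfer"] = {t: {
            "mean_auroc": rep.mean_auroc,
            "mean_relative_aupr": rep.mean_relative_aupr,
            "null_mean_auroc": rep.null_mean_auroc,
            "p_auroc": rep.p_auroc,
            "p_aupr": rep.p_aupr,
            "preserved": rep.preserved,
        } for t, rep in reports.items()}

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("report written to %s", outdir / "report.json")
    return report
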