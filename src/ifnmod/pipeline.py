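"""End-to-end orchestration: per-subset network analysis, IFN module
identification and scoring, cross-subset comparison, threshold
calibration and classification, under a single resolved configuration
and one root seed.

A run either reads expression/annotation/signature files (``paths``
mode) or generates a synthetic cohort (``simulate`` mode); the two are
mutually exclusive.  Per-subset analyses are independent; cross-subset
steps run after every subset completes.  Re-running an identical
configuration reproduces the report bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__
from .io import (ExpressionMatrix, GeneSignature, SampleAnnotation,
                 read_expression_matrix, read_gene_signatures,
                 read_sample_annotation, write_expression_matrix,
                 write_sample_annotation, write_gene_signatures)
from .simulate import CohortConfig, SyntheticTruth, default_paperlike_config, \
    draw_signature, generate_cohort
from .network import WGCNA
from .identify import (IfnModuleReport, build_score_table, curated_ifn_score,
                       identify_ifn_module)
from .compare import (cluster_core_heatmap, group_expression_summary,
                      kme_distributions, venn_partition_from_sets)
from .classify import (ClassificationResult, GroupTestReport, ThresholdReport,
                       calibrate_subset_threshold, classify, group_tests)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subset."""


class ConfigurationError(ValueError):
    """The pipeline configuration violates the schema."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    # one fixed conventional power for every subset keeps TOM and kME
    # scales comparable across subsets; "auto" enables the per-subset
    # scale-free sweep instead
    power: int | str = 6
    candidates: tuple[int, ...] = tuple(range(1, 21))
    fit_target: float = 0.8
    fallback_power: int = 6
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_threshold: float = 0.25
    signed: bool = False

    def validate(self) -> None:
        if self.min_module_size < 2:
            raise ConfigurationError("network.min_module_size must be >= 2")
        if not 0 < self.fit_target <= 1:
            raise ConfigurationError("network.fit_target must be in (0, 1]")
        if not 0 < self.cut_height <= 1:
            raise ConfigurationError("network.cut_height must be in (0, 1]")
        if not 0 <= self.merge_threshold < 1:
            raise ConfigurationError("network.merge_threshold must be in [0, 1)")
        if isinstance(self.power, str) and self.power != "auto":
            raise ConfigurationError("network.power must be an integer or 'auto'")


@dataclass
class IdentificationParams:
    target_diagnosis: str = "SLE"
    min_overlap_fraction: float = 0.5
    min_curated_correlation: float = 0.6
    curated_scaled: bool = True
    signature_size: int = 21  # used only when simulating

    def validate(self) -> None:
        if not 0 <= self.min_overlap_fraction <= 1:
            raise ConfigurationError(
                "identification.min_overlap_fraction must be in [0, 1]")
        if not -1 <= self.min_curated_correlation <= 1:
            raise ConfigurationError(
                "identification.min_curated_correlation must be in [-1, 1]")


@dataclass
class ClassificationParams:
    percentile: float = 99.0
    outlier_alpha: float = 0.001
    adjust: str = "holm"
    healthy_label: str = "HV"

    def validate(self) -> None:
        if not 0 < self.percentile < 100:
            raise ConfigurationError("classification.percentile must be in (0, 100)")
        if not 0 <= self.outlier_alpha <= 1:
            raise ConfigurationError("classification.outlier_alpha must be in [0, 1]")
        if self.adjust not in ("holm", "bonferroni"):
            raise ConfigurationError("classification.adjust must be holm|bonferroni")


@dataclass
class InputPaths:
    expression: dict[str, str]  # subset -> TSV path
    annotation: str
    signature: str

    def validate(self) -> None:
        if not self.expression:
            raise ConfigurationError("paths.expression must name at least one subset")
        for subset, p in self.expression.items():
            if not Path(p).exists():
                raise ConfigurationError(f"paths.expression[{subset}]: {p} does not exist")
        for name in ("annotation", "signature"):
            if not Path(getattr(self, name)).exists():
                raise ConfigurationError(f"paths.{name}: {getattr(self, name)} does not exist")


@dataclass
class PipelineConfig:
    simulate: CohortConfig | None = None
    paths: InputPaths | None = None
    network: NetworkParams = field(default_factory=NetworkParams)
    identification: IdentificationParams = field(default_factory=IdentificationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    lineages: dict[str, str] = field(default_factory=dict)  # subset -> myeloid|lymphoid
    out_dir: str | None = None
    seed: int = 0
    plots: bool = False

    def validate(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ConfigurationError(
                "exactly one of 'simulate' and 'paths' must be present")
        if self.simulate is not None:
            self.simulate.validate()
        else:
            self.paths.validate()
        self.network.validate()
        self.identification.validate()
        self.classification.validate()

    def to_dict(self) -> dict:
        d: dict = {
            "network": dataclasses.asdict(self.network),
            "identification": dataclasses.asdict(self.identification),
            "classification": dataclasses.asdict(self.classification),
            "lineages": dict(self.lineages),
            "out_dir": self.out_dir, "seed": self.seed, "plots": self.plots,
        }
        d["network"]["candidates"] = list(self.network.candidates)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        if self.paths is not None:
            d["paths"] = dataclasses.asdict(self.paths)
        return d


def validate_config(source) -> PipelineConfig:
    """Resolve a YAML/JSON path or a mapping into a validated config.

    Defaults are filled; the resolved config re-validates to itself.
    """
    if isinstance(source, PipelineConfig):
        cfg_dict = source.to_dict()
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        cfg_dict = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(cfg_dict, dict):
            raise ConfigurationError(f"{source}: expected a mapping at top level")
    elif isinstance(source, Mapping):
        cfg_dict = dict(source)
    else:
        raise ConfigurationError(f"unsupported config source: {type(source)!r}")

    def build(section, cls):
        raw = cfg_dict.get(section)
        if raw is None:
            return cls()
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"{section}: expected a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigurationError(f"{section}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    network = build("network", NetworkParams)
    network.candidates = tuple(network.candidates)
    identification = build("identification", IdentificationParams)
    classification = build("classification", ClassificationParams)
    simulate_cfg = cfg_dict.get("simulate")
    simulate = CohortConfig.from_dict(simulate_cfg) if simulate_cfg is not None else None
    paths_cfg = cfg_dict.get("paths")
    paths = None
    if paths_cfg is not None:
        paths = InputPaths(expression=dict(paths_cfg.get("expression", {})),
                           annotation=paths_cfg.get("annotation", ""),
                           signature=paths_cfg.get("signature", ""))
    cfg = PipelineConfig(simulate=simulate, paths=paths, network=network,
                         identification=identification, classification=classification,
                         lineages=dict(cfg_dict.get("lineages", {})),
                         out_dir=cfg_dict.get("out_dir"),
                         seed=int(cfg_dict.get("seed", 0)),
                         plots=bool(cfg_dict.get("plots", False)))
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------


@dataclass
class SubsetResult:
    subset: str
    soft_threshold_power: int
    reached_fit_target: bool
    module_sizes: dict[int, int]
    ifn_report: IfnModuleReport
    scores: pd.DataFrame | None
    threshold: ThresholdReport | None
    classification: ClassificationResult | None
    tests: GroupTestReport | None

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "soft_threshold_power": self.soft_threshold_power,
            "reached_fit_target": self.reached_fit_target,
            "module_sizes": {str(k): v for k, v in sorted(self.module_sizes.items())},
            "ifn_report": self.ifn_report.to_dict(),
            "threshold": self.threshold.to_dict() if self.threshold else None,
            "classification": (self.classification.to_dict()
                               if self.classification else None),
            "tests": self.tests.to_dict() if self.tests else None,
        }


@dataclass
class RunReport:
    version: str
    config: dict
    input_checksums: dict[str, str]
    subsets: dict[str, SubsetResult]
    venn_counts: dict[str, int]
    core_genes: tuple[str, ...]
    kme_summary: pd.DataFrame | None
    core_expression_summary: pd.DataFrame | None
    truth_metrics: dict | None
    complete: bool

    def to_dict(self) -> dict:
        return _jsonable({
            "version": self.version,
            "config": self.config,
            "input_checksums": self.input_checksums,
            "subsets": {s: r.to_dict() for s, r in self.subsets.items()},
            "venn_counts": self.venn_counts,
            "core_genes": sorted(self.core_genes),
            "kme_summary": (self.kme_summary.reset_index().to_dict(orient="records")
                            if self.kme_summary is not None else None),
            "core_expression_summary": (
                self.core_expression_summary.to_dict(orient="records")
                if self.core_expression_summary is not None else None),
            "truth_metrics": self.truth_metrics,
            "complete": self.complete,
        })

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


# ---------------------------------------------------------------------------
# metrics against planted truth
# ---------------------------------------------------------------------------


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _truth_metrics(cfg: PipelineConfig, truth: SyntheticTruth,
                   subsets: dict[str, SubsetResult],
                   assignments, core_recovered: set[str]) -> dict:
    metrics: dict = {"per_subset": {}, "core_jaccard": jaccard(core_recovered, truth.core)}
    healthy = cfg.classification.healthy_label
    for s, res in subsets.items():
        entry: dict = {}
        if res.ifn_report.selected is not None:
            genes = assignments[s].genes_in(res.ifn_report.selected)
            entry["module_jaccard"] = jaccard(genes, truth.responsive[s])
        if res.scores is not None:
            sc = res.scores.set_index("sample_id")
            activity = np.array([truth.activity[x] for x in sc.index])
            entry["score_activity_spearman"] = float(
                spearmanr(sc["module_score"].to_numpy(), activity).statistic)
            entry["curated_activity_spearman"] = float(
                spearmanr(sc["curated_score"].to_numpy(), activity).statistic)
            entry["module_curated_spearman"] = float(
                spearmanr(sc["module_score"].to_numpy(),
                          sc["curated_score"].to_numpy()).statistic)
        if res.classification is not None:
            flags = res.classification.flags
            planted = np.array([truth.ifn_high[x] for x in flags.index])
            pred = flags.to_numpy()
            tp = int((pred & planted).sum())
            fn = int((~pred & planted).sum())
            fp = int((pred & ~planted).sum())
            tn = int((~pred & ~planted).sum())
            entry.update(tp=tp, fn=fn, fp=fp, tn=tn)
            entry["sensitivity"] = tp / (tp + fn) if (tp + fn) else None
            entry["specificity"] = tn / (tn + fp) if (tn + fp) else None
            props = res.classification.proportions
            if healthy in props.index:
                entry["hv_high_fraction"] = float(props.loc[healthy, "proportion"])
        metrics["per_subset"][s] = entry
    return metrics


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def _load_inputs(cfg: PipelineConfig):
    """Returns (matrices, annotation, signature, truth-or-None, checksums)."""
    checksums: dict[str, str] = {}
    if cfg.simulate is not None:
        root = np.random.SeedSequence(cfg.seed)
        cohort_seed, signature_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                                       for c in root.spawn(2))
        sim = dataclasses.replace(cfg.simulate, seed=cohort_seed)
        matrices, annot, truth = generate_cohort(sim)
        signature = draw_signature(truth, size=cfg.identification.signature_size,
                                   seed=signature_seed)
        canon = json.dumps(sim.to_dict(), sort_keys=True).encode()
        checksums["simulate_config"] = hashlib.sha256(canon).hexdigest()
        return matrices, annot, signature, truth, checksums
    matrices = {}
    for subset, path in cfg.paths.expression.items():
        matrices[subset] = read_expression_matrix(path, subset_label=subset)
        checksums[f"expression/{subset}"] = _sha256(path)
    annot = read_sample_annotation(cfg.paths.annotation)
    checksums["annotation"] = _sha256(cfg.paths.annotation)
    signatures = read_gene_signatures(cfg.paths.signature)
    checksums["signature"] = _sha256(cfg.paths.signature)
    return matrices, annot, signatures[0], None, checksums


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis and return (and optionally write) the report.

    Per subset: soft threshold -> adjacency -> TOM -> modules -> eigengenes
    and kME -> IFN module identification -> interferon scores -> healthy
    threshold -> IFN-high classification -> group tests.  Cross-subset:
    Venn partition, core genes, kME and core-expression summaries, and
    the core-gene Ward clustering.
    """
    cfg.validate()
    stage = "load-inputs"
    subset = ""
    try:
        matrices, annot, signature, truth, checksums = _load_inputs(cfg)

        subset_results: dict[str, SubsetResult] = {}
        assignments = {}
        eigengene_maps = {}
        module_sets: dict[str, frozenset[str]] = {}
        net = cfg.network
        for subset, m in matrices.items():
            stage = "network"
            model = WGCNA(power=net.power, power_candidates=tuple(net.candidates),
                          fit_target=net.fit_target, fallback_power=net.fallback_power,
                          min_module_size=net.min_module_size,
                          cut_height=net.cut_height,
                          merge_threshold=net.merge_threshold, signed=net.signed)
            model.fit(m.df.T)
            assignments[subset] = model.assignment_
            eigengene_maps[subset] = model.eigengenes_

            stage = "identification"
            ident = cfg.identification
            report = identify_ifn_module(
                model.assignment_, model.eigengenes_, m, annot, signature,
                target_diagnosis=ident.target_diagnosis,
                min_overlap_fraction=ident.min_overlap_fraction,
                min_curated_correlation=ident.min_curated_correlation,
                curated_scaled=ident.curated_scaled)

            scores = threshold = classification = tests = None
            if report.selected is not None:
                stage = "scoring"
                module_sets[subset] = frozenset(
                    model.assignment_.genes_in(report.selected))
                eig = model.eigengenes_[report.selected]
                curated = curated_ifn_score(m, signature,
                                            scaled=ident.curated_scaled)
                scores = build_score_table(m, eig, curated, report.selected)

                stage = "classification"
                cls = cfg.classification
                series = scores.set_index("sample_id")["module_score"]
                healthy_ids = [x for x in series.index
                               if annot.column("diagnosis", [x]).iloc[0]
                               == cls.healthy_label]
                if len(healthy_ids) >= 5:
                    threshold = calibrate_subset_threshold(
                        series.loc[healthy_ids], subset=subset,
                        percentile=cls.percentile, alpha=cls.outlier_alpha,
                        method=cls.adjust)
                    classification = classify(series, annot, threshold.threshold)
                else:
                    logger.warning("subset %s: %d healthy samples; threshold skipped",
                                   subset, len(healthy_ids))
                stage = "group-tests"
                tests = group_tests(series, annot)

            subset_results[subset] = SubsetResult(
                subset=subset,
                soft_threshold_power=model.soft_threshold_.power,
                reached_fit_target=model.soft_threshold_.reached_target,
                module_sizes=model.assignment_.sizes(),
                ifn_report=report, scores=scores, threshold=threshold,
                classification=classification, tests=tests)

        # ----- cross-subset ------------------------------------------------
        subset = ""
        stage = "cross-subset"
        venn_counts: dict[str, int] = {}
        core: frozenset[str] = frozenset()
        kme_summary = core_summary = None
        if len(module_sets) >= 2:
            vp = venn_partition_from_sets(module_sets)
            venn_counts = {"+".join(c): n for c, n in sorted(vp.counts().items())}
            core = vp.core
            ifn_labels = {s: subset_results[s].ifn_report.selected
                          for s in module_sets}
            _, kme_summary = kme_distributions(
                {s: assignments[s] for s in module_sets}, ifn_labels)
        if core:
            frames = []
            for s in module_sets:
                gs = group_expression_summary(matrices[s], sorted(core), annot,
                                              group_by="diagnosis")
                med = gs.groupby("diagnosis", sort=True)["median"].median()
                for diag, v in med.items():
                    frames.append({"subset": s, "diagnosis": diag,
                                   "median_core_expression": float(v)})
            core_summary = pd.DataFrame(frames)
            stage = "core-heatmap"
            heatmap = cluster_core_heatmap(
                {s: matrices[s] for s in module_sets}, sorted(core), annot,
                diagnoses=(cfg.classification.healthy_label,))
        else:
            heatmap = None

        truth_metrics = None
        if truth is not None:
            stage = "truth-metrics"
            truth_metrics = _truth_metrics(cfg, truth, subset_results, assignments,
                                           set(core))

        report = RunReport(version=__version__, config=cfg.to_dict(),
                           input_checksums=checksums, subsets=subset_results,
                           venn_counts=venn_counts, core_genes=tuple(sorted(core)),
                           kme_summary=kme_summary,
                           core_expression_summary=core_summary,
                           truth_metrics=truth_metrics,
                           complete=all(r.ifn_report.selected is not None
                                        for r in subset_results.values()))
        if cfg.out_dir:
            stage = "write-artifacts"
            _write_artifacts(cfg, report, matrices, annot, signature, truth,
                             assignments, heatmap)
        return report
    except (PipelineError, ):
        raise
    except Exception as exc:
        where = f"stage {stage!r}" + (f", subset {subset!r}" if subset else "")
        raise PipelineError(f"pipeline failed at {where}: {exc}") from exc


def _write_artifacts(cfg, report, matrices, annot, signature, truth,
                     assignments, heatmap) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(_jsonable(cfg.to_dict()), sort_keys=True), encoding="utf-8")
    write_sample_annotation(annot, out / "annotation.csv")
    write_gene_signatures([signature], out / "signature.gmt")
    for s, assign in assignments.items():
        assign.to_frame().to_csv(out / f"modules_{s}.tsv", sep="\t", index=False)
    score_frames = [r.scores for r in report.subsets.values() if r.scores is not None]
    if score_frames:
        pd.concat(score_frames, ignore_index=True).to_csv(
            out / "scores.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(out / "truth.json")
        for s, m in matrices.items():
            write_expression_matrix(m, out / f"expression_{s}.tsv")
    if heatmap is not None:
        heatmap.matrix.to_csv(out / "core_heatmap.tsv", sep="\t",
                              index_label="gene_id")
        if cfg.plots:
            from .compare import plot_heatmap
            plot_heatmap(heatmap, str(out / "core_heatmap.png"))


def default_simulation_pipeline(seed: int = 0, **overrides) -> PipelineConfig:
    """Convenience: a simulate-mode config on the default cohort."""
    cfg = PipelineConfig(simulate=default_paperlike_config(), seed=seed,
                         lineages={"CD4": "lymphoid", "CD8": "lymphoid",
                                   "monocyte": "myeloid", "neutrophil": "myeloid"},
                         **overrides)
    cfg.validate()
    return cfg
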