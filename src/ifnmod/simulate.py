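"""Synthetic multi-subset expression cohorts with planted ground truth.

The generator emulates a cross-sectional immune-disease cohort in which
each subject contributes one purified-cell expression array per
leucocyte subset (CD4+ T, CD8+ T, monocyte, neutrophil).  Every sample
carries a latent type-1-interferon (IFN-1) activity drawn from a
per-diagnosis two-component Gaussian mixture (baseline ``N(0,1)``,
elevated ``N(shift,1)``); a planted set of IFN-responsive genes loads
positively on that activity, with a shared core responsive in every
subset and broader programs in the myeloid subsets.  Diagnosis-independent
background factors plant non-IFN coexpression modules, and per-batch
gene offsets add technical structure.

The additive model for gene g in sample s of subset c is::

    x[g, s] = baseline[g, c] + activity[s] * loading[g, c]   (responsive g)
            + factor[b(g), s] * bg_loading[g, c]             (background g)
            + batch_offset[g, batch(s)] + noise[g, s]

Everything stochastic flows from a single seed, so a configuration
reproduces bit-identical matrices, and the emitted truth object records
the planted memberships, latent activities and IFN-high flags that the
recovery tests score against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleAnnotation, GeneSignature

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A cohort configuration violates an invariant."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityModel:
    """Per-diagnosis latent IFN activity: baseline N(0,1) with an
    elevated N(shift,1) component of weight ``prop_elevated``."""

    prop_elevated: float
    shift: float

    def validate(self, name: str) -> None:
        if not 0.0 <= self.prop_elevated <= 1.0:
            raise ConfigError(f"activity[{name}].prop_elevated must be in [0,1]")


@dataclass(frozen=True)
class SporadicActivation:
    """Subset-restricted extra activation (e.g. rare acute ISG spikes in
    healthy-volunteer neutrophils).  Applied on top of the subject's
    activity for samples of ``subset`` with ``diagnosis``; affected
    samples are flagged IFN-high in the truth."""

    subset: str
    diagnosis: str
    prop: float
    shift: float

    def validate(self) -> None:
        if not 0.0 <= self.prop <= 1.0:
            raise ConfigError("sporadic.prop must be in [0,1]")


@dataclass(frozen=True)
class LoadingModel:
    """Uniform[low, high] positive gene loadings (config units)."""

    low: float
    high: float

    def validate(self, name: str) -> None:
        if self.low <= 0 or self.high < self.low:
            raise ConfigError(f"loading model {name!r} requires 0 < low <= high")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class BackgroundModules:
    """Count and size of planted non-IFN coexpression modules."""

    count: int
    size: int
    loading: LoadingModel = LoadingModel(0.5, 2.0)

    def validate(self) -> None:
        if self.count < 0 or (self.count > 0 and self.size < 1):
            raise ConfigError("background module count/size must be non-negative/positive")
        self.loading.validate("background")


@dataclass(frozen=True)
class IfnProgram:
    """Planted IFN-responsive gene program.

    ``blocks`` maps an exclusive subset combination (tuple of subset
    names, not the all-subsets core) to the number of genes responsive
    in exactly those subsets; the ``core`` genes are responsive in every
    subset.  The per-subset responsive count is therefore
    ``core + sum of blocks containing the subset``.
    """

    core: int
    blocks: Mapping[tuple[str, ...], int]
    core_loading: LoadingModel = LoadingModel(0.8, 2.0)
    subset_loading: Mapping[str, LoadingModel] = field(default_factory=dict)
    baseline_boost: Mapping[str, float] = field(default_factory=dict)

    def validate(self, subsets: tuple[str, ...]) -> None:
        if self.core < 0:
            raise ConfigError("ifn_program.core must be non-negative")
        for combo, n in self.blocks.items():
            if n <= 0:
                raise ConfigError(f"ifn_program block {combo} must have positive count")
            unknown = set(combo) - set(subsets)
            if unknown:
                raise ConfigError(f"ifn_program block {combo} names unknown subsets {unknown}")
            if set(combo) == set(subsets):
                raise ConfigError(f"block {combo} covers all subsets; use 'core' instead")
        self.core_loading.validate("core")
        for name, lm in self.subset_loading.items():
            lm.validate(name)

    def responsive_counts(self, subsets: tuple[str, ...]) -> dict[str, int]:
        counts = {s: self.core for s in subsets}
        for combo, n in self.blocks.items():
            for s in combo:
                counts[s] += n
        return counts

    @property
    def total_genes(self) -> int:
        return self.core + sum(self.blocks.values())


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort (see module docstring)."""

    subsets: tuple[str, ...]
    diagnoses: Mapping[str, int]                 # subject counts per diagnosis
    genes_total: int
    ifn_program: IfnProgram
    activity: Mapping[str, ActivityModel]
    background: BackgroundModules = BackgroundModules(0, 0)
    sporadic: SporadicActivation | None = None
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    batch_effect_sd: float = 0.2
    n_batches: int = 3
    centres: tuple[str, ...] = ("Cambridge", "Singapore")
    healthy_label: str = "HV"
    seed: int = 0

    def validate(self) -> None:
        if len(self.subsets) < 1 or len(set(self.subsets)) != len(self.subsets):
            raise ConfigError("subsets must be non-empty and unique")
        if not self.diagnoses:
            raise ConfigError("at least one diagnosis is required")
        for d, n in self.diagnoses.items():
            if n <= 0:
                raise ConfigError(f"diagnoses[{d}] must be positive")
        if self.genes_total < 1:
            raise ConfigError("genes_total must be positive")
        self.ifn_program.validate(self.subsets)
        planted = self.ifn_program.total_genes + self.background.count * self.background.size
        if planted > self.genes_total:
            raise ConfigError(
                f"planted genes ({planted}) exceed genes_total ({self.genes_total})")
        missing = set(self.diagnoses) - set(self.activity)
        if missing:
            raise ConfigError(f"no activity model for diagnoses {sorted(missing)}")
        for name, am in self.activity.items():
            am.validate(name)
        if self.sporadic is not None:
            self.sporadic.validate()
            if self.sporadic.subset not in self.subsets:
                raise ConfigError(f"sporadic.subset {self.sporadic.subset!r} unknown")
            if self.sporadic.diagnosis not in self.diagnoses:
                raise ConfigError(f"sporadic.diagnosis {self.sporadic.diagnosis!r} unknown")
        self.background.validate()
        if self.noise_sd < 0 or self.batch_effect_sd < 0:
            raise ConfigError("noise_sd and batch_effect_sd must be non-negative")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be positive")
        cnt = self.responsive_counts()
        for s in self.subsets:
            if self.ifn_program.core > cnt[s]:  # cannot happen by construction
                raise ConfigError("core larger than a subset's responsive count")

    def responsive_counts(self) -> dict[str, int]:
        return self.ifn_program.responsive_counts(self.subsets)

    @property
    def n_subjects(self) -> int:
        return sum(self.diagnoses.values())

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["ifn_program"]["blocks"] = {
            "+".join(k): v for k, v in self.ifn_program.blocks.items()}
        d["subsets"] = list(self.subsets)
        d["centres"] = list(self.centres)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        prog = dict(d.pop("ifn_program"))
        blocks = {tuple(k.split("+")) if isinstance(k, str) else tuple(k): v
                  for k, v in dict(prog.pop("blocks")).items()}
        prog["core_loading"] = _loading(prog.get("core_loading", {"low": 0.8, "high": 2.0}))
        prog["subset_loading"] = {k: _loading(v)
                                  for k, v in dict(prog.get("subset_loading", {})).items()}
        prog["baseline_boost"] = dict(prog.get("baseline_boost", {}))
        ifn = IfnProgram(blocks=blocks, **prog)
        activity = {k: ActivityModel(**v) for k, v in dict(d.pop("activity")).items()}
        background = d.pop("background", None)
        if background is not None:
            background = dict(background)
            background["loading"] = _loading(background.get("loading",
                                                            {"low": 0.5, "high": 2.0}))
            background = BackgroundModules(**background)
        else:
            background = BackgroundModules(0, 0)
        sporadic = d.pop("sporadic", None)
        if sporadic is not None:
            sporadic = SporadicActivation(**sporadic)
        return cls(subsets=tuple(d.pop("subsets")),
                   diagnoses=dict(d.pop("diagnoses")),
                   genes_total=int(d.pop("genes_total")),
                   ifn_program=ifn, activity=activity, background=background,
                   sporadic=sporadic,
                   centres=tuple(d.pop("centres", ("Cambridge", "Singapore"))),
                   **d)


def _loading(v) -> LoadingModel:
    if isinstance(v, LoadingModel):
        return v
    return LoadingModel(**v)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic cohort.

    ``responsive`` maps each subset to its planted IFN-responsive gene
    set; ``core`` is their intersection.  ``activity`` and ``ifn_high``
    are keyed by sample id; the flag marks membership of the elevated
    mixture component (including sporadic activation).
    """

    responsive: dict[str, frozenset[str]]
    core: frozenset[str]
    activity: dict[str, float]
    ifn_high: dict[str, bool]
    background: dict[str, int]

    def __post_init__(self) -> None:
        inter = None
        for genes in self.responsive.values():
            inter = genes if inter is None else inter & genes
        if inter is not None and inter != self.core:
            raise ValueError("core set is not the intersection of responsive sets")

    def to_dict(self) -> dict:
        return {
            "responsive": {k: sorted(v) for k, v in self.responsive.items()},
            "core": sorted(self.core),
            "activity": dict(self.activity),
            "ifn_high": dict(self.ifn_high),
            "background": dict(self.background),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(responsive={k: frozenset(v) for k, v in d["responsive"].items()},
                   core=frozenset(d["core"]),
                   activity=dict(d["activity"]),
                   ifn_high=dict(d["ifn_high"]),
                   background=dict(d["background"]))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(cfg: CohortConfig
                    ) -> tuple[dict[str, ExpressionMatrix], SampleAnnotation, SyntheticTruth]:
    """Generate per-subset expression matrices, annotation and truth.

    Subjects are simulated once and reused across subsets, so a subject
    keeps the same latent activity in every subset (plus any sporadic
    subset-restricted activation).  Identical config (including seed)
    gives bitwise-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # -- deterministic gene layout ----------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.genes_total)]
    cursor = 0
    core_genes = gene_ids[cursor:cursor + cfg.ifn_program.core]
    cursor += cfg.ifn_program.core
    block_genes: dict[tuple[str, ...], list[str]] = {}
    for combo in sorted(cfg.ifn_program.blocks, key=lambda c: (-len(c), c)):
        n = cfg.ifn_program.blocks[combo]
        block_genes[combo] = gene_ids[cursor:cursor + n]
        cursor += n
    background_membership: dict[str, int] = {}
    bg_gene_lists: list[list[str]] = []
    for b in range(cfg.background.count):
        genes_b = gene_ids[cursor:cursor + cfg.background.size]
        cursor += cfg.background.size
        bg_gene_lists.append(genes_b)
        for g in genes_b:
            background_membership[g] = b + 1

    responsive: dict[str, frozenset[str]] = {}
    for s in cfg.subsets:
        members = list(core_genes)
        for combo, genes_c in block_genes.items():
            if s in combo:
                members.extend(genes_c)
        responsive[s] = frozenset(members)

    # -- subjects ----------------------------------------------------------
    subjects: list[str] = []
    subj_diagnosis: dict[str, str] = {}
    for diag in cfg.diagnoses:
        for _ in range(cfg.diagnoses[diag]):
            sid = f"P{len(subjects) + 1:04d}"
            subjects.append(sid)
            subj_diagnosis[sid] = diag
    n_subj = len(subjects)
    subj_centre = {s: cfg.centres[int(i)] for s, i in
                   zip(subjects, rng.integers(0, len(cfg.centres), n_subj))}
    elevated = np.zeros(n_subj, dtype=bool)
    base_activity = rng.standard_normal(n_subj)
    for i, sid in enumerate(subjects):
        am = cfg.activity[subj_diagnosis[sid]]
        elevated[i] = rng.random() < am.prop_elevated
        if elevated[i]:
            base_activity[i] += am.shift

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    matrices: dict[str, ExpressionMatrix] = {}
    annot_rows: list[dict[str, str]] = []
    activity_out: dict[str, float] = {}
    high_out: dict[str, bool] = {}

    for subset in cfg.subsets:
        sample_ids = [f"{sid}_{subset}" for sid in subjects]
        activity = base_activity.copy()
        high = elevated.copy()
        if cfg.sporadic is not None and cfg.sporadic.subset == subset:
            eligible = np.array([subj_diagnosis[s] == cfg.sporadic.diagnosis
                                 for s in subjects])
            hit = eligible & (rng.random(n_subj) < cfg.sporadic.prop)
            activity = activity + cfg.sporadic.shift * hit
            high = high | hit

        # loadings for responsive genes in this subset
        loading = np.zeros(cfg.genes_total)
        subset_lm = cfg.ifn_program.subset_loading.get(subset, LoadingModel(0.5, 2.0))
        core_idx = [gene_index[g] for g in core_genes]
        loading[core_idx] = cfg.ifn_program.core_loading.draw(rng, len(core_idx))
        for combo, genes_c in block_genes.items():
            if subset in combo:
                idx = [gene_index[g] for g in genes_c]
                loading[idx] = subset_lm.draw(rng, len(idx))

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.genes_total)
        boost = cfg.ifn_program.baseline_boost.get(subset, 0.0)
        if boost:
            resp_idx = [gene_index[g] for g in sorted(responsive[subset])]
            baseline[resp_idx] += boost

        x = baseline[:, None] + np.outer(loading, activity)

        for genes_b in bg_gene_lists:
            idx = [gene_index[g] for g in genes_b]
            factor = rng.standard_normal(n_subj)
            bg_load = cfg.background.loading.draw(rng, len(idx))
            x[idx, :] += np.outer(bg_load, factor)

        batch = rng.integers(1, cfg.n_batches + 1, n_subj)
        if cfg.batch_effect_sd > 0:
            offsets = rng.normal(0.0, cfg.batch_effect_sd,
                                 (cfg.genes_total, cfg.n_batches))
            x += offsets[:, batch - 1]
        if cfg.noise_sd > 0:
            x += rng.normal(0.0, cfg.noise_sd, x.shape)

        matrices[subset] = ExpressionMatrix(
            pd.DataFrame(x, index=gene_ids, columns=sample_ids), subset=subset)
        for j, (sid, samp) in enumerate(zip(subjects, sample_ids)):
            annot_rows.append({
                "sample_id": samp, "subject_id": sid, "subset": subset,
                "diagnosis": subj_diagnosis[sid], "centre": subj_centre[sid],
                "batch": f"b{batch[j]}"})
            activity_out[samp] = float(activity[j])
            high_out[samp] = bool(high[j])

    annot = SampleAnnotation(pd.DataFrame(annot_rows))
    truth = SyntheticTruth(responsive=responsive, core=frozenset(core_genes),
                           activity=activity_out, ifn_high=high_out,
                           background=background_membership)
    return matrices, annot, truth


def draw_signature(truth: SyntheticTruth, size: int = 21, seed: int = 0,
                   name: str = "ISG21_synthetic") -> GeneSignature:
    """A synthetic stand-in for a published curated ISG signature: ``size``
    genes sampled (seeded) from the planted core responsive set."""
    core = sorted(truth.core)
    if not core:
        raise ValueError("truth has no core genes to draw a signature from")
    rng = np.random.default_rng(seed)
    size = min(size, len(core))
    picked = sorted(rng.choice(len(core), size=size, replace=False))
    return GeneSignature(name=name, genes=tuple(core[i] for i in picked),
                         description="synthetic curated ISG signature drawn from planted core")


def default_paperlike_config(seed: int = 0) -> CohortConfig:
    """The study-condition cohort: four leucocyte subsets, five diagnosis
    groups, myeloid IFN programs much broader than T-cell programs, SLE
    activity elevated in most subjects, and rare extreme sporadic
    activation confined to healthy-volunteer neutrophils.

    150 samples per subset (24 SLE, 10 AAV, 10 IBD, 6 Behçet's, 100 HV
    subjects, each contributing one array per subset).  Responsive
    counts: neutrophil 300, monocyte 250, CD4 80, CD8 70, sharing a
    60-gene core; 8 background modules of 60 genes; 1500 genes total.
    """
    subsets = ("CD4", "CD8", "monocyte", "neutrophil")
    program = IfnProgram(
        core=60,
        blocks={
            ("monocyte", "neutrophil"): 120,
            ("neutrophil",): 120,
            ("monocyte",): 70,
            ("CD4", "CD8"): 4,
            ("CD4",): 16,
            ("CD8",): 6,
        },
        core_loading=LoadingModel(0.8, 2.0),
        subset_loading={
            "CD4": LoadingModel(0.7, 2.0),
            "CD8": LoadingModel(0.7, 2.0),
            "monocyte": LoadingModel(0.4, 2.0),
            "neutrophil": LoadingModel(0.4, 2.0),
        },
        baseline_boost={"monocyte": 2.0, "neutrophil": 3.0},
    )
    return CohortConfig(
        subsets=subsets,
        diagnoses={"SLE": 24, "AAV": 10, "IBD": 10, "Behcet": 6, "HV": 100},
        genes_total=1500,
        ifn_program=program,
        activity={
            "SLE": ActivityModel(0.85, 4.5),
            "AAV": ActivityModel(0.10, 4.5),
            "IBD": ActivityModel(0.10, 4.5),
            "Behcet": ActivityModel(0.10, 4.5),
            "HV": ActivityModel(0.0, 4.5),
        },
        sporadic=SporadicActivation(subset="neutrophil", diagnosis="HV",
                                    prop=0.012, shift=12.0),
        background=BackgroundModules(count=8, size=60, loading=LoadingModel(0.5, 2.0)),
        noise_sd=1.0,
        baseline_mean=7.0,
        baseline_sd=1.0,
        batch_effect_sd=0.2,
        n_batches=3,
        healthy_label="HV",
        seed=seed,
    )
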