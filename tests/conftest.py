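"""Shared fixtures: small synthetic cohorts and tabular fixtures built
programmatically (nothing is read from checked-in data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ifnmod import (ActivityModel, BackgroundModules, CohortConfig,
                    ExpressionMatrix, IfnProgram, LoadingModel, SampleAnnotation,
                    SporadicActivation)


def small_cohort_config(seed: int = 0, *, noise_sd: float = 1.0,
                        sporadic: SporadicActivation | None = None,
                        background_count: int = 2) -> CohortConfig:
    """A two-lineage, four-subset cohort small enough for unit tests."""
    program = IfnProgram(
        core=20,
        blocks={("monocyte", "neutrophil"): 24, ("neutrophil",): 16,
                ("CD4",): 6, ("CD8",): 4},
        core_loading=LoadingModel(0.8, 2.0),
        subset_loading={"CD4": LoadingModel(0.7, 2.0), "CD8": LoadingModel(0.7, 2.0),
                        "monocyte": LoadingModel(0.5, 2.0),
                        "neutrophil": LoadingModel(0.5, 2.0)},
        baseline_boost={"monocyte": 2.0, "neutrophil": 3.0},
    )
    return CohortConfig(
        subsets=("CD4", "CD8", "monocyte", "neutrophil"),
        diagnoses={"SLE": 12, "AAV": 5, "HV": 30},
        genes_total=300,
        ifn_program=program,
        activity={"SLE": ActivityModel(0.85, 4.5), "AAV": ActivityModel(0.1, 4.5),
                  "HV": ActivityModel(0.0, 4.5)},
        sporadic=sporadic,
        background=BackgroundModules(count=background_count, size=40,
                                     loading=LoadingModel(0.5, 2.0)),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231101)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with known values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(df, subset="CD4")


@pytest.fixture
def toy_annotation() -> SampleAnnotation:
    df = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "subject_id": ["p1", "p2", "p3", "p4"],
        "subset": ["CD4"] * 4,
        "diagnosis": ["SLE", "SLE", "HV", "HV"],
        "centre": ["Cambridge"] * 4,
        "batch": ["b1", "b1", "b2", "b2"],
    })
    return SampleAnnotation(df)
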