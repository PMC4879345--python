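"""Identification of the type-1-interferon module within each subset.

Among the coexpression modules of one leucocyte subset, the IFN-1
module is the one that (1) captures most genes of a curated
interferon-stimulated-gene signature, (2) shows increased expression in
the target diagnosis (positive Spearman correlation of its eigengene
with the SLE indicator), and (3) correlates strongly with the curated
IFN score — the mean gene-scaled expression of the signature genes in
the same subset.  Criterion (3) guards against generic activation
modules that track diagnosis without tracking interferon exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import ExpressionMatrix, GeneSignature, SampleAnnotation, zscore_rows
from .network import Eigengene, ModuleAssignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def signature_overlap(assignment: ModuleAssignment, signature: GeneSignature
                      ) -> tuple[dict[int, int], tuple[str, ...]]:
    """Count signature genes per module label (label 0 included).

    Signature genes absent from the assignment's gene universe are
    returned separately; counts plus absentees partition the signature.
    """
    gene_to_label = dict(zip(assignment.gene_ids, (int(l) for l in assignment.labels)))
    counts: dict[int, int] = {0: 0, **{l: 0 for l in assignment.module_labels}}
    absent: list[str] = []
    for g in signature.genes:
        if g in gene_to_label:
            counts[gene_to_label[g]] += 1
        else:
            absent.append(g)
    return counts, tuple(absent)


def diagnosis_correlation(eigengene: Eigengene | pd.Series, annot: SampleAnnotation,
                          target_diagnosis: str = "SLE") -> float:
    """Spearman correlation of eigengene scores with the 0/1 diagnosis
    indicator (target diagnosis = 1, everything else = 0; midranks).

    Requires at least two samples on each side of the coding and
    non-constant scores.
    """
    scores = eigengene.scores if isinstance(eigengene, Eigengene) else eigengene
    diag = annot.column("diagnosis", scores.index)
    indicator = (diag == target_diagnosis).astype(int).to_numpy()
    n1 = int(indicator.sum())
    if n1 < 2 or (len(indicator) - n1) < 2:
        raise ValueError(
            f"diagnosis correlation needs >= 2 samples in each coded group "
            f"(got {n1} {target_diagnosis!r} vs {len(indicator) - n1} others)")
    values = scores.to_numpy(dtype=float)
    if np.std(values) == 0:
        raise ValueError("eigengene scores are constant; correlation undefined")
    return float(spearmanr(values, indicator).statistic)


def curated_ifn_score(m: ExpressionMatrix, signature: GeneSignature,
                      scaled: bool = True) -> pd.Series:
    """Per-sample curated IFN score: mean expression of signature genes.

    By default each present signature gene is z-scored first so genes
    with different dynamic ranges contribute equally (``scaled=False``
    averages raw values).  Absent signature genes are logged; at least
    one must be present.
    """
    present = [g for g in signature.genes if g in set(m.gene_ids)]
    absent = [g for g in signature.genes if g not in set(m.gene_ids)]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    if absent:
        logger.warning("curated_ifn_score: %d signature genes absent from matrix: %s",
                       len(absent), absent[:10])
    sub = m.select_genes(present)
    if scaled:
        z, _ = zscore_rows(sub.values, ddof=1)
        values = z.mean(axis=0)
    else:
        values = sub.values.mean(axis=0)
    return pd.Series(values, index=m.sample_ids, name="curated_score")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


@dataclass
class IfnModuleReport:
    """Per-module evidence and the selected IFN-1 module for one subset.

    ``table`` has one row per module label with columns
    ``size, signature_overlap, diagnosis_r, curated_r``; ``selected`` is
    the chosen label or None (with reasons in ``rejections``).
    """

    subset: str
    table: pd.DataFrame
    selected: int | None
    rejections: dict[int, str] = field(default_factory=dict)
    absent_signature_genes: tuple[str, ...] = ()
    signature_size: int = 0

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "selected": self.selected,
            "signature_size": self.signature_size,
            "absent_signature_genes": list(self.absent_signature_genes),
            "rejections": {str(k): v for k, v in self.rejections.items()},
            "modules": self.table.reset_index().to_dict(orient="records"),
        }


def identify_ifn_module(assignment: ModuleAssignment,
                        eigengenes: Mapping[int, Eigengene],
                        m: ExpressionMatrix,
                        annot: SampleAnnotation,
                        signature: GeneSignature,
                        target_diagnosis: str = "SLE",
                        min_overlap_fraction: float = 0.5,
                        min_curated_correlation: float = 0.6,
                        curated_scaled: bool = True) -> IfnModuleReport:
    """Apply the two identification criteria plus the curated cross-check.

    Selects the module with the largest signature overlap among those
    with (a) overlap >= ``min_overlap_fraction`` x signature size,
    (b) positive diagnosis correlation, and (c) eigengene-vs-curated
    Spearman >= ``min_curated_correlation``; ties break towards higher
    curated correlation.  An empty selection (with recorded reasons) is
    a valid outcome.
    """
    counts, absent = signature_overlap(assignment, signature)
    try:
        curated = curated_ifn_score(m, signature, scaled=curated_scaled)
    except ValueError as exc:
        # no signature gene in the matrix: nothing can qualify, but the
        # per-module evidence table is still useful
        logger.warning("curated score unavailable: %s", exc)
        curated = None
    need = min_overlap_fraction * len(signature)

    rows = []
    reasons_by_label: dict[int, list[str]] = {}
    for label in assignment.module_labels:
        eig = eigengenes[label]
        overlap = counts.get(label, 0)
        try:
            diag_r = diagnosis_correlation(eig, annot, target_diagnosis)
        except ValueError as exc:
            diag_r = float("nan")
            logger.warning("module %d: diagnosis correlation unavailable (%s)", label, exc)
        if curated is None or np.std(eig.scores.to_numpy()) == 0:
            curated_r = float("nan")
        else:
            cur = curated.loc[eig.scores.index]
            curated_r = float(spearmanr(eig.scores.to_numpy(), cur.to_numpy()).statistic)
        rows.append({"module_label": label,
                     "size": int((assignment.labels == label).sum()),
                     "signature_overlap": overlap,
                     "diagnosis_r": diag_r, "curated_r": curated_r})
        reasons = []
        if overlap < need:
            reasons.append(f"signature overlap {overlap}/{len(signature)} "
                           f"below minimum {need:.1f}")
        if not (diag_r > 0):
            reasons.append(f"non-positive {target_diagnosis} correlation "
                           f"({diag_r:.2f})")
        if not (curated_r >= min_curated_correlation):
            reasons.append(f"low curated-score correlation "
                           f"({curated_r:.2f} < {min_curated_correlation:.2f})")
        reasons_by_label[label] = reasons

    table = pd.DataFrame(rows).set_index("module_label") if rows else pd.DataFrame(
        columns=["size", "signature_overlap", "diagnosis_r", "curated_r"])

    qualifying = [l for l, r in reasons_by_label.items() if not r]
    selected: int | None = None
    if qualifying:
        # largest signature overlap; ties towards higher curated correlation
        selected = int(max(qualifying,
                           key=lambda l: (table.loc[l, "signature_overlap"],
                                          table.loc[l, "curated_r"])))
    else:
        logger.warning("subset %r: no module met the IFN-1 identification criteria",
                       m.subset)
    # keep notes for failing modules that presented some evidence
    rejections = {int(l): "; ".join(r) for l, r in reasons_by_label.items()
                  if r and (table.loc[l, "signature_overlap"] > 0
                            or table.loc[l, "diagnosis_r"] > 0)}
    return IfnModuleReport(subset=m.subset, table=table, selected=selected,
                           rejections=rejections, absent_signature_genes=absent,
                           signature_size=len(signature))


def build_score_table(m: ExpressionMatrix, eigengene: Eigengene,
                      curated: pd.Series, module_label: int) -> pd.DataFrame:
    """One row per sample: module interferon score and curated score."""
    return pd.DataFrame({
        "sample_id": m.sample_ids,
        "subset": m.subset,
        "module_label": module_label,
        "module_score": eigengene.scores.loc[m.sample_ids].to_numpy(),
        "curated_score": curated.loc[m.sample_ids].to_numpy(),
    })
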