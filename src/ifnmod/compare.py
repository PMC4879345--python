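"""Cross-subset comparison of the identified IFN-1 modules.

Covers the core/unique membership partition across leucocyte subsets
(Venn blocks; the genes IFN-associated in every subset are the "core"),
the per-subset distributions of module membership (kME), robust
median/MAD expression profiles by sample group, and the gene-scaled
Ward/Euclidean clustering of core genes used for the expression
heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .io import ExpressionMatrix, SampleAnnotation, zscore_rows
from .network import ModuleAssignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Disjoint partition of IFN-module genes by subset-membership pattern.

    ``blocks`` maps each non-empty subset combination (tuple in the
    original subset order) to the genes IFN-associated in exactly those
    subsets.  Blocks are disjoint and their union is the union of the
    per-subset module gene sets.
    """

    subsets: tuple[str, ...]
    blocks: dict[tuple[str, ...], frozenset[str]]

    @property
    def core(self) -> frozenset[str]:
        """Genes IFN-associated in every subset."""
        return self.blocks.get(tuple(self.subsets), frozenset())

    def unique_to(self, subset: str) -> frozenset[str]:
        return self.blocks.get((subset,), frozenset())

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.blocks.values():
            out |= genes
        return frozenset(out)

    def counts(self) -> dict[tuple[str, ...], int]:
        return {combo: len(genes) for combo, genes in self.blocks.items()}

    def lineage_unique(self, lineages: Mapping[str, str], lineage: str) -> frozenset[str]:
        """Genes confined to subsets of one lineage (e.g. all-myeloid)."""
        out: set[str] = set()
        for combo, genes in self.blocks.items():
            if combo and all(lineages.get(s) == lineage for s in combo):
                out |= genes
        return frozenset(out)

    def to_dict(self) -> dict:
        return {"subsets": list(self.subsets),
                "blocks": {"+".join(c): sorted(g) for c, g in self.blocks.items()}}


def venn_partition(assignments: Mapping[str, ModuleAssignment],
                   ifn_labels: Mapping[str, int]) -> VennPartition:
    """Partition IFN-module genes by the exact set of subsets they belong to.

    ``ifn_labels`` names each subset's IFN module; a label that does not
    exist in that subset's assignment is an error.
    """
    subsets = tuple(assignments)
    if len(subsets) < 2:
        raise ValueError("venn_partition requires at least 2 subsets")
    member_sets: dict[str, frozenset[str]] = {}
    for s in subsets:
        label = ifn_labels[s]
        if label not in assignments[s].module_labels:
            raise ValueError(f"subset {s!r} has no module labelled {label}")
        member_sets[s] = frozenset(assignments[s].genes_in(label))
    return venn_partition_from_sets(member_sets)


def venn_partition_from_sets(member_sets: Mapping[str, frozenset[str] | set[str]]
                             ) -> VennPartition:
    subsets = tuple(member_sets)
    blocks: dict[tuple[str, ...], set[str]] = {}
    universe: set[str] = set()
    for genes in member_sets.values():
        universe |= set(genes)
    for g in universe:
        combo = tuple(s for s in subsets if g in member_sets[s])
        blocks.setdefault(combo, set()).add(g)
    return VennPartition(subsets=subsets,
                         blocks={c: frozenset(v) for c, v in blocks.items()})


# ---------------------------------------------------------------------------
# kME distributions
# ---------------------------------------------------------------------------


def kme_distributions(assignments: Mapping[str, ModuleAssignment],
                      ifn_labels: Mapping[str, int]
                      ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-subset kME values of IFN-module member genes, plus a five-number
    summary (min, quartiles, max; linear-interpolation quantiles)."""
    values: dict[str, np.ndarray] = {}
    rows = []
    for s, assign in assignments.items():
        label = ifn_labels[s]
        genes = assign.genes_in(label)
        kme = assign.kme.loc[genes].to_numpy(dtype=float)
        values[s] = kme
        q = np.quantile(kme, [0.0, 0.25, 0.5, 0.75, 1.0]) if kme.size else [np.nan] * 5
        rows.append({"subset": s, "n_genes": kme.size, "min": q[0], "q1": q[1],
                     "median": q[2], "q3": q[3], "max": q[4]})
    return values, pd.DataFrame(rows).set_index("subset")


# ---------------------------------------------------------------------------
# median / MAD profiles
# ---------------------------------------------------------------------------


def _mad(x: np.ndarray, axis: int, statistic: str) -> np.ndarray:
    """Unscaled absolute-deviation dispersion (no 1.4826 consistency factor).

    ``statistic="median"`` gives median(|x - median|); ``"mean"`` gives
    mean(|x - mean|), kept as a sensitivity option.
    """
    if statistic == "median":
        centre = np.median(x, axis=axis, keepdims=True)
        return np.median(np.abs(x - centre), axis=axis)
    if statistic == "mean":
        centre = np.mean(x, axis=axis, keepdims=True)
        return np.mean(np.abs(x - centre), axis=axis)
    raise ValueError("statistic must be 'median' or 'mean'")


def dispersion_profile(m: ExpressionMatrix, genes: Sequence[str],
                       sample_ids: Sequence[str] | None = None,
                       statistic: str = "median") -> pd.DataFrame:
    """Per-gene median and MAD across a sample group (>= 3 samples).

    Returns a frame indexed by gene with columns ``median`` and ``mad``.
    """
    sub = m.select_genes(list(genes))
    if sample_ids is not None:
        sub = sub.select_samples(list(sample_ids))
    if sub.n_samples < 3:
        raise ValueError("dispersion_profile requires at least 3 samples")
    x = sub.values
    return pd.DataFrame({"median": np.median(x, axis=1),
                         "mad": _mad(x, axis=1, statistic=statistic)},
                        index=sub.gene_ids)


def group_expression_summary(m: ExpressionMatrix, genes: Sequence[str],
                             annot: SampleAnnotation,
                             group_by: str | Sequence[str] = "diagnosis",
                             statistic: str = "median") -> pd.DataFrame:
    """Long-format per-gene median and MAD by sample group.

    Groups with fewer than 3 samples are flagged (``low_n``) rather than
    erroring; empty groups simply do not appear.  Output order is by
    group then gene, so permuting input samples leaves it unchanged.
    """
    group_cols = [group_by] if isinstance(group_by, str) else list(group_by)
    sub = m.select_genes(list(genes))
    meta = annot.df.loc[sub.sample_ids, group_cols]
    rows = []
    grouped = meta.groupby(group_cols, sort=True, observed=True)
    for key, gdf in grouped:
        key = key if isinstance(key, tuple) else (key,)
        samples = list(gdf.index)
        x = sub.df.loc[:, samples].to_numpy()
        med = np.median(x, axis=1)
        mad = (_mad(x, axis=1, statistic=statistic) if len(samples) >= 2
               else np.zeros(len(genes)))
        for i, g in enumerate(sub.gene_ids):
            rows.append({"gene": g, **dict(zip(group_cols, key)),
                         "median": med[i], "mad": mad[i],
                         "n": len(samples), "low_n": len(samples) < 3})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# core-gene heatmap clustering
# ---------------------------------------------------------------------------


@dataclass
class HeatmapClustering:
    """Gene-scaled core-gene matrix with Ward/Euclidean orderings.

    ``matrix`` is genes x samples, scaled by gene over the pooled
    samples and re-ordered to the dendrogram leaf orders.
    """

    matrix: pd.DataFrame
    gene_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray

    def sample_clusters(self, k: int) -> pd.Series:
        """Flat sample clusters from the Ward tree (``maxclust`` cut)."""
        labels = fcluster(self.sample_linkage, t=k, criterion="maxclust")
        original = [s for s in self.matrix.columns]
        # linkage was computed on the pre-ordering sample sequence
        return pd.Series(labels, index=self._pooled_samples, name="cluster")

    _pooled_samples: tuple[str, ...] = ()


def cluster_core_heatmap(matrices: Mapping[str, ExpressionMatrix],
                         core_genes: Sequence[str],
                         annot: SampleAnnotation | None = None,
                         diagnoses: Sequence[str] | None = ("HV",)
                         ) -> HeatmapClustering:
    """Ward/Euclidean clustering of core genes over pooled samples.

    Samples from all subsets are pooled (restricted to ``diagnoses``
    when annotation is given), the matrix is scaled by gene over the
    pooled samples, and genes and samples are each ordered by
    Ward-linkage hierarchical clustering with Euclidean distance
    (standard recursive leaf order, no optimal reordering).
    """
    core_genes = list(core_genes)
    if not core_genes:
        raise ValueError("no core genes to cluster")
    for s, m in matrices.items():
        missing = sorted(set(core_genes) - set(m.gene_ids))
        if missing:
            raise ValueError(f"core genes missing from subset {s!r}: {missing}")
    pooled = pd.concat([m.df.loc[core_genes] for m in matrices.values()], axis=1)
    if annot is not None and diagnoses is not None:
        diag = annot.column("diagnosis", list(pooled.columns))
        keep = [s for s in pooled.columns if diag.loc[s] in set(diagnoses)]
        pooled = pooled.loc[:, keep]
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 pooled samples to cluster")
    z, _ = zscore_rows(pooled.to_numpy(), ddof=1)
    gene_link = linkage(z, method="ward", metric="euclidean")
    sample_link = linkage(z.T, method="ward", metric="euclidean")
    gene_order = [core_genes[i] for i in leaves_list(gene_link)]
    sample_order = [pooled.columns[i] for i in leaves_list(sample_link)]
    scaled = pd.DataFrame(z, index=core_genes, columns=pooled.columns)
    hm = HeatmapClustering(matrix=scaled.loc[gene_order, sample_order],
                           gene_order=tuple(gene_order),
                           sample_order=tuple(sample_order),
                           gene_linkage=gene_link, sample_linkage=sample_link)
    hm._pooled_samples = tuple(pooled.columns)
    return hm


def plot_heatmap(hm: HeatmapClustering, path: str, annot: SampleAnnotation | None = None
                 ) -> None:  # pragma: no cover - presentation only
    """Render the clustered matrix to PNG/SVG (simple raster, no dendrograms)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(hm.matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xlabel("samples (Ward order)")
    ax.set_ylabel("core IFN-1 genes (Ward order)")
    fig.colorbar(im, ax=ax, label="scaled expression (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
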