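"""Weighted gene coexpression network construction and module detection.

The classic recipe: soft-threshold the gene-gene Pearson correlation
matrix (``a_ij = |r_ij|^beta``, beta chosen for approximate scale-free
topology), convert to the topological overlap measure (TOM), cluster
genes by average-linkage hierarchical clustering on ``1 - TOM``, cut the
tree at a fixed height, discard clusters below a minimum size, and merge
modules whose eigengenes are nearly collinear.  A module eigengene is
the first principal component of the gene-scaled expression of module
genes, oriented so that a higher score means higher module expression;
kME is the correlation of a gene's profile with that eigengene.

Everything is deterministic; all parameters carry the conventional
defaults and are surfaced both on the functions and on the
:class:`WGCNA` estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, zscore_rows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------


def _as_gene_matrix(m) -> np.ndarray:
    """Accept an ExpressionMatrix or a genes x samples array."""
    if isinstance(m, ExpressionMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def pearson_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between rows, with zero-variance rows mapped to
    zero correlation (and a degenerate-row mask returned)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("correlation requires at least 2 samples")
    z, degenerate = zscore_rows(x, ddof=1)
    r = z @ z.T / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r, degenerate


def adjacency(m, power: float = 6, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency ``|r|^power`` (unsigned network).

    ``signed=True`` uses ``((1+r)/2)^power`` instead, which keeps
    anticorrelated genes apart.  The diagonal is forced to 1; entries
    lie in [0, 1].  Zero-variance genes get zero off-diagonal adjacency
    with a logged warning.
    """
    if power < 1:
        raise ValueError("soft-threshold power must be >= 1")
    x = _as_gene_matrix(m)
    r, degenerate = pearson_rows(x)
    if degenerate.any():
        logger.warning("adjacency: %d zero-variance genes have zero adjacency",
                       int(degenerate.sum()))
    if signed:
        a = ((1.0 + r) / 2.0) ** power
    else:
        a = np.abs(r) ** power
    np.fill_diagonal(a, 1.0)
    return a


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(adj), 1.0, atol=1e-10):
        raise ValueError("adjacency diagonal must be 1")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    return adj


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    For i != j, with ``l_ij = sum_{u != i,j} a_iu a_uj`` and connectivity
    ``k_i = sum_{u != i} a_iu``::

        t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    and ``t_ii = 1``.  The result is symmetric with entries in [0, 1].
    """
    a = _check_adjacency(adj)
    k = a.sum(axis=1) - np.diag(a)
    aa = a @ a
    # (A @ A)_ij includes u=i and u=j terms (a_ii a_ij + a_ij a_jj = 2 a_ij
    # given unit diagonal); remove them to sum over u not in {i, j}.
    l = aa - 2.0 * a
    numerator = l + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denominator, 1.0)  # diagonal is overwritten below
    t = numerator / denominator
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return t


# ---------------------------------------------------------------------------
# soft-threshold selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoftThresholdReport:
    """Scale-free-topology sweep over candidate powers.

    ``fit`` holds the signed R^2 of the log-log degree regression per
    candidate (negative slope counted positive); ``power`` is the
    smallest candidate whose fit reaches ``fit_target``, else the
    configured fallback (``reached_target`` False).
    """

    candidates: tuple[int, ...]
    fit: tuple[float, ...]
    mean_connectivity: tuple[float, ...]
    power: int
    fit_target: float
    reached_target: bool


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 frequency vs log10 connectivity regression
    over equal-width connectivity bins (the usual scale-free fit index)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.isclose(k.min(), k.max()):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    mean_k = np.array([k[which == b].mean() for b in np.nonzero(keep)[0]])
    p = counts[keep] / k.size
    res = linregress(np.log10(np.maximum(mean_k, 1e-12)), np.log10(p))
    return float(-np.sign(res.slope) * res.rvalue ** 2)


def pick_soft_threshold(m, candidates: Sequence[int] = tuple(range(1, 21)),
                        fit_target: float = 0.8, fallback: int = 6,
                        signed: bool = False,
                        min_mean_connectivity: float = 1.0) -> SoftThresholdReport:
    """Sweep candidate powers and pick the smallest reaching ``fit_target``.

    A candidate only qualifies while mean connectivity stays at or above
    ``min_mean_connectivity``: on unstructured data, high powers drive
    connectivity towards zero and the handful of largest correlations
    then produce a spuriously good log-log fit, so a vanishing network
    must not be selected.  Falls back to ``fallback`` (with a warning)
    when no candidate qualifies.  Requires at least 3 samples; fewer
    than 20 draws a warning since correlations are then noisy.
    """
    x = _as_gene_matrix(m)
    if x.shape[1] < 3:
        raise ValueError("soft-threshold selection requires at least 3 samples")
    if x.shape[1] < 20:
        logger.warning("pick_soft_threshold: only %d samples; correlations are noisy",
                       x.shape[1])
    candidates = tuple(int(c) for c in candidates)
    if not candidates or min(candidates) < 1:
        raise ValueError("candidates must be positive powers")
    r, _ = pearson_rows(x)
    base = np.abs(r) if not signed else (1.0 + r) / 2.0
    fits, mean_k = [], []
    for beta in candidates:
        a = base ** beta
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=1) - 1.0
        fits.append(scale_free_fit(k))
        mean_k.append(float(k.mean()))
    chosen, reached = fallback, False
    for beta, f, mk in zip(candidates, fits, mean_k):
        if f >= fit_target and mk >= min_mean_connectivity:
            chosen, reached = beta, True
            break
    if not reached:
        logger.warning("no candidate power reached scale-free fit %.2f; "
                       "falling back to power %d", fit_target, fallback)
    return SoftThresholdReport(candidates=candidates, fit=tuple(fits),
                               mean_connectivity=tuple(mean_k), power=chosen,
                               fit_target=fit_target, reached_target=reached)


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------


@dataclass
class Eigengene:
    """First principal component of a module's gene-scaled expression.

    ``scores`` is the per-sample summary (higher = higher module
    expression), ``loadings`` the unit-norm gene weights, and
    ``variance_explained`` the PC1 share of total variance.
    """

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    label: int | None = None


def _pc1(scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """PC1 of a genes x samples *scaled* matrix.

    Returns (per-sample scores, unit-norm gene loadings, variance
    explained), oriented positively against the module mean profile.
    """
    x = scaled.T  # samples x genes
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    total = float((s ** 2).sum())
    varexp = float(s[0] ** 2 / total) if total > 0 else 0.0
    mean_profile = scaled.mean(axis=0)
    orient = float(scores @ (mean_profile - mean_profile.mean()))
    if orient == 0.0:  # degenerate (e.g. perfectly opposed genes): fix sign by loading
        orient = float(loadings[0]) or 1.0
    if orient < 0:
        scores, loadings = -scores, -loadings
    return scores, loadings, varexp


def module_eigengene(m: ExpressionMatrix, genes: Sequence[str],
                     label: int | None = None) -> Eigengene:
    """Eigengene of ``genes`` in matrix ``m`` (genes scaled to z-scores).

    Errors if no module gene has nonzero variance.  Zero-variance
    members contribute zero rows (and zero loading).
    """
    genes = list(genes)
    if len(genes) == 0:
        raise ValueError("module must contain at least one gene")
    sub = m.select_genes(genes)
    z, degenerate = zscore_rows(sub.values, ddof=1)
    if degenerate.all():
        raise ValueError("all module genes have zero variance")
    scores, loadings, varexp = _pc1(z)
    return Eigengene(scores=pd.Series(scores, index=m.sample_ids, name=label),
                     loadings=pd.Series(loadings, index=genes, name=label),
                     variance_explained=varexp, label=label)


def module_membership(m: ExpressionMatrix, eigengene: Eigengene) -> pd.Series:
    """kME: Pearson correlation of every gene in ``m`` with the eigengene.

    Computed for all genes, member or not.  Zero-variance genes get
    kME 0 with a warning.
    """
    e = eigengene.scores
    if list(e.index) != m.sample_ids:
        e = e.loc[m.sample_ids]
    ez = np.asarray(e, dtype=float)
    if ez.std(ddof=1) == 0:
        raise ValueError("eigengene scores are constant")
    ez = (ez - ez.mean()) / ez.std(ddof=1)
    z, degenerate = zscore_rows(m.values, ddof=1)
    kme = z @ ez / (m.n_samples - 1)
    np.clip(kme, -1.0, 1.0, out=kme)
    if degenerate.any():
        logger.warning("module_membership: %d zero-variance genes given kME 0",
                       int(degenerate.sum()))
        kme[degenerate] = 0.0
    return pd.Series(kme, index=m.gene_ids, name="kME")


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


def detect_modules(tom: np.ndarray, min_size: int = 30, cut_height: float = 0.99,
                   merge_threshold: float = 0.25,
                   expr: np.ndarray | None = None) -> np.ndarray:
    """Cluster genes on ``1 - TOM`` and return integer module labels.

    Average-linkage hierarchical clustering, static cut at
    ``cut_height``, clusters below ``min_size`` labelled 0 (unassigned).
    When ``expr`` (genes x samples, aligned to the TOM) is given,
    modules whose eigengenes have dissimilarity ``1 - cor`` below
    ``merge_threshold`` are merged iteratively.  Surviving labels are
    re-indexed 1..K by decreasing module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    t = np.asarray(tom, dtype=float)
    if not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("TOM must be symmetric")
    n = t.shape[0]
    d = 1.0 - (t + t.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for lab in np.unique(raw):
        idx = np.nonzero(raw == lab)[0]
        if idx.size >= min_size:
            labels[idx] = next_label
            next_label += 1

    if expr is not None and merge_threshold > 0:
        labels = _merge_by_eigengene(labels, np.asarray(expr, dtype=float),
                                     merge_threshold)
    return _relabel_by_size(labels)


def _merge_by_eigengene(labels: np.ndarray, expr: np.ndarray,
                        merge_threshold: float) -> np.ndarray:
    labels = labels.copy()
    while True:
        labs = [l for l in np.unique(labels) if l != 0]
        if len(labs) < 2:
            return labels
        scores = []
        for l in labs:
            z, _ = zscore_rows(expr[labels == l], ddof=1)
            scores.append(_pc1(z)[0])
        s = np.asarray(scores)
        sz, _ = zscore_rows(s, ddof=1)
        corr = sz @ sz.T / (s.shape[1] - 1)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] < merge_threshold:
            labels[labels == labs[j]] = labs[i]
        else:
            return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    labs = [l for l in np.unique(labels) if l != 0]
    # decreasing size; ties broken by original label for determinism
    order = sorted(labs, key=lambda l: (-(labels == l).sum(), l))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# assignment container and estimator
# ---------------------------------------------------------------------------


@dataclass
class ModuleAssignment:
    """Gene -> module labels with per-gene module membership (kME).

    Labels are positive integers ordered by decreasing module size;
    0 means unassigned.  ``kme`` is each gene's correlation with its own
    module's eigengene (NaN for unassigned genes).
    """

    gene_ids: tuple[str, ...]
    labels: np.ndarray
    kme: pd.Series

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("labels and gene_ids differ in length")
        finite = self.kme.dropna()
        if len(finite) and (finite.abs() > 1 + 1e-9).any():
            raise ValueError("kME outside [-1, 1]")

    @property
    def module_labels(self) -> list[int]:
        return [int(l) for l in np.unique(self.labels) if l != 0]

    def genes_in(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}

    def label_of(self, gene: str) -> int:
        return int(self.labels[self.gene_ids.index(gene)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids,
                             "module_label": self.labels,
                             "kME": self.kme.to_numpy()})


class WGCNA(BaseEstimator):
    """Coexpression module discovery as a scikit-learn style transformer.

    ``fit`` expects samples x genes (a DataFrame keeps gene/sample
    names); it soft-thresholds correlations, builds the TOM, detects and
    merges modules, and computes eigengenes and kME.  ``transform`` maps
    (new) samples to per-module eigengene scores using the scaling and
    loadings learned at fit time.

    Parameters
    ----------
    power : int or "auto"
        Soft-threshold power; "auto" runs the scale-free sweep.
    power_candidates, fit_target, fallback_power
        Sweep configuration for ``power="auto"``.
    min_module_size, cut_height, merge_threshold
        Tree-cut parameters (see :func:`detect_modules`).
    signed : bool
        Use a signed network instead of the unsigned default.
    """

    def __init__(self, power: int | str = "auto",
                 power_candidates: tuple[int, ...] = tuple(range(1, 21)),
                 fit_target: float = 0.8, fallback_power: int = 6,
                 min_module_size: int = 30, cut_height: float = 0.99,
                 merge_threshold: float = 0.25, signed: bool = False):
        self.power = power
        self.power_candidates = power_candidates
        self.fit_target = fit_target
        self.fallback_power = fallback_power
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_threshold = merge_threshold
        self.signed = signed

    # -- helpers -----------------------------------------------------------
    def _to_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(X.T)
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X.T,
                          index=[f"g{i}" for i in range(X.shape[1])],
                          columns=[f"s{j}" for j in range(X.shape[0])])
        return ExpressionMatrix(df)

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None) -> "WGCNA":
        m = self._to_matrix(X)
        if isinstance(self.power, str):
            if self.power != "auto":
                raise ValueError("power must be an integer or 'auto'")
            self.soft_threshold_ = pick_soft_threshold(
                m, candidates=self.power_candidates, fit_target=self.fit_target,
                fallback=self.fallback_power, signed=self.signed)
        else:
            self.soft_threshold_ = SoftThresholdReport(
                candidates=(int(self.power),), fit=(float("nan"),),
                mean_connectivity=(float("nan"),), power=int(self.power),
                fit_target=self.fit_target, reached_target=True)
        power = self.soft_threshold_.power
        adj = adjacency(m, power=power, signed=self.signed)
        tom = topological_overlap(adj)
        z, _ = zscore_rows(m.values, ddof=1)
        labels = detect_modules(tom, min_size=self.min_module_size,
                                cut_height=self.cut_height,
                                merge_threshold=self.merge_threshold, expr=z)

        self.gene_ids_ = tuple(m.gene_ids)
        self.sample_ids_ = tuple(m.sample_ids)
        self.labels_ = labels
        self.modules_ = {int(l): [g for g, lab in zip(m.gene_ids, labels) if lab == l]
                         for l in np.unique(labels) if l != 0}
        self.eigengenes_ = {}
        kme_own = pd.Series(np.nan, index=m.gene_ids, name="kME")
        kme_cols = {}
        for label, genes in self.modules_.items():
            eig = module_eigengene(m, genes, label=label)
            self.eigengenes_[label] = eig
            kme_all = module_membership(m, eig)
            kme_cols[label] = kme_all
            kme_own.loc[genes] = kme_all.loc[genes]
        self.kme_table_ = pd.DataFrame(kme_cols) if kme_cols else pd.DataFrame(index=m.gene_ids)
        self.assignment_ = ModuleAssignment(gene_ids=tuple(m.gene_ids),
                                            labels=labels, kme=kme_own)
        mu = m.values.mean(axis=1)
        sd = m.values.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        self._scale_mu_, self._scale_sd_ = mu, sd
        self.n_features_in_ = m.n_genes
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-module eigengene scores for samples x genes input."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("WGCNA instance is not fitted")
        m = self._to_matrix(X)
        if tuple(m.gene_ids) != self.gene_ids_:
            raise ValueError("transform requires the same genes (and order) as fit")
        z = (m.values - self._scale_mu_[:, None]) / self._scale_sd_[:, None]
        out = {}
        for label, eig in self.eigengenes_.items():
            idx = [m.gene_ids.index(g) for g in eig.loadings.index]
            out[label] = z[idx, :].T @ eig.loadings.to_numpy()
        return pd.DataFrame(out, index=m.sample_ids)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        self.fit(X)
        return pd.DataFrame({l: e.scores for l, e in self.eigengenes_.items()})
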