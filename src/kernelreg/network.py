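"""Weighted co-expression networks: adjacency, TOM, modules, hubs, traits.

The construction follows the standard weighted-network recipe: unsigned
soft-thresholded adjacency a_ij = |cor(i, j)|^beta, topological overlap

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical clustering on 1 - TOM, a deterministic
static tree cut (the cut height is chosen, among the dendrogram's merge
heights, to maximize the number of coherent clusters of at least
``min_size`` genes), iterative merging of modules whose eigengene
dissimilarity falls below ``merge_cut``, module-eigengene/trait Pearson
correlation, and intramodular-connectivity hub ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: minimum eigengene variance-explained for a cluster to count as a module;
#: pure-noise clusters of n genes over s samples sit near (1 + sqrt(n/s))^2 / n
MIN_MODULE_COHERENCE = 0.2

#: minimum |cor(gene, module eigengene)| (kME) to stay in a module
MIN_MODULE_MEMBERSHIP = 0.3

UNASSIGNED = "unassigned"


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-thresholded co-expression adjacency with unit diagonal."""

    gene_ids: pd.Index
    values: np.ndarray
    beta: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency must be square and match gene_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = v

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ModuleAssignment:
    """gene -> module label map; background genes carry ``unassigned``."""

    labels: pd.Series
    min_size: int

    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def genes_of(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class ModuleEigengene:
    """First principal component of a module's standardized expression."""

    module: str
    scores: pd.Series
    variance_explained: float


def filter_network_genes(matrix: ExpressionMatrix, min_mean_fpkm: float = 1.0) -> ExpressionMatrix:
    """Retain genes whose mean FPKM across all samples is strictly above threshold."""
    keep = matrix.values.mean(axis=1) > min_mean_fpkm
    if not keep.any():
        raise ValueError("no genes pass the mean-FPKM filter")
    logger.info("filter_network_genes: %d/%d genes retained", int(keep.sum()), len(keep))
    return ExpressionMatrix(matrix.values.loc[keep], matrix.sample_meta)


def compute_adjacency(matrix: ExpressionMatrix, beta: int) -> AdjacencyMatrix:
    """Unsigned adjacency |cor|^beta; zero-variance genes are dropped with a warning."""
    if matrix.values.shape[1] < 3:
        raise ValueError("adjacency requires >= 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = matrix.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        dropped = matrix.gene_ids[sd == 0].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance genes from network", stacklevel=2)
        x = x[sd > 0]
        gene_ids = matrix.gene_ids[sd > 0]
    else:
        gene_ids = matrix.gene_ids
    cor = np.corrcoef(x)
    adj = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(gene_ids=gene_ids, values=adj, beta=beta)


def compute_tom(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix; symmetric, in [0, 1], unit diagonal."""
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu * a_uj (diagonal of a is 0)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.gene_ids, columns=adj.gene_ids)


def compute_eigengene(matrix: ExpressionMatrix, module_genes, module: str = "") -> ModuleEigengene:
    """First right-singular vector of the module's row-standardized expression.

    The score vector is unit-norm with sign fixed so its correlation with
    the module's mean standardized expression is nonnegative;
    ``variance_explained`` is sigma_1^2 / sum sigma^2.  Constant genes
    are dropped before standardization.
    """
    genes = pd.Index(module_genes)
    if len(genes) == 0:
        raise ValueError("empty module")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    x = x[sd > 0]
    if x.shape[0] == 0:
        raise ValueError("module contains only constant genes")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True, ddof=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return ModuleEigengene(
        module=module,
        scores=pd.Series(scores, index=matrix.samples, name=module),
        variance_explained=var_explained,
    )


def _cut_tree(link: np.ndarray, heights: np.ndarray, matrix: ExpressionMatrix,
              gene_ids: pd.Index, min_size: int, min_coherence: float) -> np.ndarray:
    """Static tree cut: pick the merge height maximizing coherent big clusters."""
    candidate_heights = np.unique(link[:, 2])
    best_labels, best_score, best_height = None, (-1, -1), None
    eps = 1e-9
    for h in np.concatenate([candidate_heights - eps, candidate_heights[-1:] + eps]):
        labels = fcluster(link, t=h, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        big = sizes[sizes >= min_size].index
        n_modules = n_assigned = 0
        for cluster in big:
            genes = gene_ids[labels == cluster]
            eg = compute_eigengene(matrix, genes)
            if eg.variance_explained >= min_coherence:
                n_modules += 1
                n_assigned += len(genes)
        # most coherent big clusters; among ties, the cut covering most genes
        score = (n_modules, n_assigned)
        if score > best_score:
            best_labels, best_score, best_height = labels, score, h
    logger.info(
        "static cut at height %.4f: %d qualifying clusters covering %d genes",
        best_height, best_score[0], best_score[1],
    )
    return best_labels


def _merge_modules(matrix: ExpressionMatrix, labels: pd.Series, merge_cut: float) -> pd.Series:
    """Iteratively merge the closest module pair while eigengene dissimilarity < cut."""
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            return labels
        scores = {
            m: compute_eigengene(matrix, labels.index[labels == m], m).scores.to_numpy()
            for m in modules
        }
        best_pair, best_diss = None, np.inf
        for i, mi in enumerate(modules):
            for mj in modules[i + 1:]:
                r = np.corrcoef(scores[mi], scores[mj])[0, 1]
                diss = 1.0 - r
                if diss < best_diss:
                    best_pair, best_diss = (mi, mj), diss
        if best_diss >= merge_cut:
            return labels
        mi, mj = best_pair
        labels[labels == mj] = mi
        logger.info("merged modules %s <- %s (dissimilarity %.3f)", mi, mj, best_diss)


def detect_modules(
    matrix: ExpressionMatrix,
    beta: int,
    *,
    min_size: int = 50,
    merge_cut: float = 0.15,
    min_coherence: float = MIN_MODULE_COHERENCE,
    min_kme: float = MIN_MODULE_MEMBERSHIP,
) -> tuple[ModuleAssignment, dict[str, ModuleEigengene]]:
    """Detect co-expression modules on 1 - TOM and merge similar ones.

    Average-linkage clustering of the TOM dissimilarity is cut at the
    height yielding the most coherent clusters of >= ``min_size`` genes;
    smaller or incoherent clusters dissolve to ``unassigned``.  Modules
    whose eigengenes correlate above 1 - ``merge_cut`` are merged
    iteratively (closest pair first) with eigengenes recomputed after
    each merge.  A final membership pass reverts genes with
    |cor(gene, eigengene)| < ``min_kme`` to ``unassigned``.  Final
    labels are M1, M2, ... in decreasing module size.
    """
    if len(matrix.gene_ids) < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned", stacklevel=2)
        labels = pd.Series(UNASSIGNED, index=matrix.gene_ids)
        return ModuleAssignment(labels=labels, min_size=min_size), {}

    adj = compute_adjacency(matrix, beta)
    tom = compute_tom(adj)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    link = linkage(squareform(diss, checks=False), method="average")
    raw = _cut_tree(link, link[:, 2], matrix, tom.index, min_size, min_coherence)

    labels = pd.Series(UNASSIGNED, index=tom.index, dtype=object)
    sizes = pd.Series(raw).value_counts()
    for cluster in sizes.index:
        if sizes[cluster] < min_size:
            continue
        genes = tom.index[raw == cluster]
        if compute_eigengene(matrix, genes).variance_explained < min_coherence:
            continue
        labels[genes] = f"raw{cluster}"

    labels = labels.reindex(matrix.gene_ids, fill_value=UNASSIGNED)
    labels = _merge_modules(matrix, labels, merge_cut)

    # membership cleanup: genes only loosely correlated with their module
    # eigengene (|kME| < min_kme) revert to unassigned
    for module in sorted(set(labels) - {UNASSIGNED}):
        genes = labels.index[labels == module]
        eg = compute_eigengene(matrix, genes, module)
        x = matrix.values.loc[genes].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        e = eg.scores.to_numpy()
        ec = e - e.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = np.abs(xc @ ec) / (norms * np.linalg.norm(ec))
        weak = genes[(kme < min_kme) | (norms == 0)]
        if len(weak):
            logger.info("module %s: %d weak-membership genes unassigned", module, len(weak))
            labels[weak] = UNASSIGNED
        if (labels == module).sum() < min_size:
            labels[labels == module] = UNASSIGNED

    # relabel by decreasing size, deterministic tie-break on first gene
    modules = sorted(
        set(labels) - {UNASSIGNED},
        key=lambda m: (-int((labels == m).sum()), str(labels.index[labels == m][0])),
    )
    rename = {old: f"M{i + 1}" for i, old in enumerate(modules)}
    labels = labels.map(lambda v: rename.get(v, UNASSIGNED))
    assignment = ModuleAssignment(labels=labels, min_size=min_size)
    eigengenes = {
        m: compute_eigengene(matrix, assignment.genes_of(m), m) for m in assignment.modules()
    }
    logger.info("detect_modules: %d modules, %d genes unassigned",
                len(eigengenes), int((labels == UNASSIGNED).sum()))
    return assignment, eigengenes


def module_trait_correlation(
    eigengenes: dict[str, ModuleEigengene],
    traits: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-tailed p for every (module eigengene, trait) pair.

    Missing trait values are handled pairwise-complete with the retained
    sample count logged and reported in column ``n``.
    """
    rows = []
    for module, eg in sorted(eigengenes.items()):
        scores = eg.scores
        for trait in traits.columns:
            t = traits[trait].reindex(scores.index)
            mask = t.notna()
            n = int(mask.sum())
            if n < 3:
                r, p = np.nan, np.nan
            else:
                if n < len(scores):
                    logger.info("module %s / trait %s: %d complete samples", module, trait, n)
                res = stats.pearsonr(scores[mask], t[mask])
                r, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {"module": module, "trait": trait, "r": r, "p": p,
                 "significant": bool(p < alpha) if np.isfinite(p) else False, "n": n}
            )
    return pd.DataFrame(rows)


def extract_hubs(
    matrix: ExpressionMatrix,
    assignment: ModuleAssignment,
    *,
    beta: int,
    top_n: int = 30,
    use_soft: bool = True,
) -> dict[str, pd.DataFrame]:
    """Top-``top_n`` genes per module by intramodular connectivity.

    k_i = sum over other module members of a_ij with a the soft
    adjacency |cor|^beta (``use_soft=False`` switches to raw |cor|
    sums).  Ties break on gene id.  The whole-network connectivity over
    all assigned genes is reported alongside as ``k_total``.
    """
    hubs = {}
    power = beta if use_soft else 1
    assigned = assignment.labels.index[assignment.labels != UNASSIGNED]
    if len(assigned) == 0:
        return hubs
    whole = compute_adjacency(ExpressionMatrix(matrix.values.loc[assigned], matrix.sample_meta), power)
    aw = whole.values.copy()
    np.fill_diagonal(aw, 0.0)
    k_total = pd.Series(aw.sum(axis=1), index=whole.gene_ids)

    for module in assignment.modules():
        genes = assignment.genes_of(module)
        sub = ExpressionMatrix(matrix.values.loc[genes], matrix.sample_meta)
        adj = compute_adjacency(sub, power)
        a = adj.values.copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)

        table = (
            pd.DataFrame({"gene_id": adj.gene_ids, "k": k})
            .assign(k_total=lambda d: k_total.reindex(d["gene_id"]).to_numpy())
            .sort_values(["k", "gene_id"], ascending=[False, True], kind="mergesort")
            .head(top_n)
            .reset_index(drop=True)
        )
        hubs[module] = table
    return hubs


def export_network(
    tom: pd.DataFrame,
    assignment: ModuleAssignment | None = None,
    *,
    weight_threshold: float = 0.20,
) -> pd.DataFrame:
    """Undirected edge list of TOM weights >= threshold, each pair once.

    Rows are ordered by matrix gene order (row-major upper triangle);
    module labels are attached when an assignment is given.
    """
    genes = tom.index
    values = tom.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = values[iu, ju] >= weight_threshold
    rows = pd.DataFrame(
        {
            "source": genes[iu[keep]],
            "target": genes[ju[keep]],
            "weight": values[iu[keep], ju[keep]],
        }
    )
    if assignment is not None:
        rows["source_module"] = assignment.labels.reindex(rows["source"]).to_numpy()
        rows["target_module"] = assignment.labels.reindex(rows["target"]).to_numpy()
    return rows
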