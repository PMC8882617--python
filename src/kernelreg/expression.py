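"""Expression-matrix container, QC, PCA, differential expression, enrichment.

The differential-expression stage applies the standard FPKM-era filter
(max group-mean FPKM > 1, BH-adjusted q < 0.05, |log2 fold change| > 1)
on top of a two-sample homoscedastic t-test computed on log2(FPKM + 1).
Externally computed p-values (e.g. from a count-based engine) can be
supplied instead of the built-in test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: pseudocount added to group means before forming log2 fold changes
FOLD_CHANGE_EPS = 0.01


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix plus per-sample metadata.

    ``values`` is indexed by gene id with one column per sample;
    ``sample_meta`` is indexed by sample name with columns
    ``genotype``, ``stage``, ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = [c for c in ("genotype", "stage", "replicate") if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match value columns in order")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, genotype: str, stage: str) -> list[str]:
        """Sample names of one (genotype, stage) replicate group."""
        meta = self.sample_meta
        mask = (meta["genotype"] == genotype) & (meta["stage"] == stage)
        return list(meta.index[mask])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.sample_meta)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(FPKM + 1); metadata is preserved."""
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative expression value in input")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), matrix.sample_meta)


def replicate_correlation(matrix: ExpressionMatrix, genotype: str, stage: str) -> pd.DataFrame:
    """Pearson r over all genes for every replicate pair of one group.

    Zero-variance replicates yield an undefined correlation, reported as
    NaN with a warning.
    """
    samples = matrix.group_samples(genotype, stage)
    if len(samples) < 2:
        raise ValueError(f"group ({genotype}, {stage}) has fewer than 2 replicates")
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a = matrix.values[samples[i]].to_numpy(dtype=float)
            b = matrix.values[samples[j]].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance replicate in ({genotype}, {stage}); correlation undefined",
                    stacklevel=2,
                )
                r = np.nan
            else:
                r = stats.pearsonr(a, b).statistic
            rows.append({"sample_a": samples[i], "sample_b": samples[j], "r": r})
    return pd.DataFrame(rows)


def pca_samples(matrix: ExpressionMatrix, n_components: int | None = None):
    """Sample-level PCA of a (log-transformed) matrix via gene-centered SVD.

    Returns ``(scores, variance_explained)`` where ``scores`` is a samples
    x components DataFrame and ``variance_explained`` the per-component
    fraction of total centered variance.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(len(s), n_components or len(s))
    total = (s**2).sum()
    var_frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = pd.DataFrame(
        (s[:k] * vt[:k].T),
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, var_frac


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    *,
    min_fpkm: float = 1.0,
    max_q: float = 0.05,
    min_abs_log2fc: float = 1.0,
    external_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two (genotype, stage) groups.

    The built-in test is a two-sample pooled-variance t-test on
    log2(FPKM + 1); ``external_p`` (indexed by gene id) overrides it.
    log2 fold change is formed from raw group means with a pseudocount.
    A gene passes iff max(group means) > ``min_fpkm``, q < ``max_q`` and
    |log2FC| > ``min_abs_log2fc``.
    """
    sa = matrix.group_samples(*group_a)
    sb = matrix.group_samples(*group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 replicates")

    a = matrix.values[sa].to_numpy(dtype=float)
    b = matrix.values[sb].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + FOLD_CHANGE_EPS) / (mean_b + FOLD_CHANGE_EPS))

    if external_p is not None:
        p = external_p.reindex(matrix.gene_ids).to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ValueError("external_p missing values for some genes")
    else:
        la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance: identical groups are null, distinct are extreme
        degenerate = np.isnan(p)
        if degenerate.any():
            same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            p[degenerate & same] = 1.0
            p[degenerate & ~same] = 0.0
    q = bh_adjust(p)

    passes = (np.maximum(mean_a, mean_b) > min_fpkm) & (q < max_q) & (np.abs(log2fc) > min_abs_log2fc)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "mean_fpkm_a": mean_a,
            "mean_fpkm_b": mean_b,
            "passes": passes,
        }
    ).set_index("gene_id")


def term_enrichment(
    gene_list,
    term_to_genes: dict[str, set],
    universe,
    *,
    max_q: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene list.

    ``p`` is the probability of observing at least the seen overlap when
    drawing ``len(gene_list)`` genes from the universe; BH adjustment
    across terms gives ``q`` and ``significant`` flags q < ``max_q``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(gene_list)
    if not selected <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for term, genes in term_to_genes.items():
        genes = set(genes) & universe
        k = len(genes & selected)
        # P[X >= k] for X ~ Hypergeom(M=m, n=|term|, N=n_sel)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, m, len(genes), n_sel))
        rows.append({"term": term, "overlap": k, "term_size": len(genes), "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows).set_index("term")
    result["q_value"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    result["significant"] = result["q_value"] < max_q
    return result
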