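"""Seven-way cis/trans regulatory-divergence assignment from allele counts.

Three decisions drive the classification of each SNP:

* **P set** — chi-square test of the parental allele ratio against 1:1,
  formed across the two homozygous parental libraries (parent-1 allele
  from the P1 library over parent-2 allele from the P2 library) after
  scaling to equal library sizes.
* **H set** — chi-square test of the hybrid allelic ratio against 1:1 on
  replicate-pooled counts.
* **T set** — two-tailed pooled-variance t-test comparing per-replicate
  hybrid log2 allelic ratios with per-replicate parental log2 ratios.

With significance at p < 0.05 in each set, the pattern is: cis-only when
P and H are significant but T is not; trans-only when P and T are but H
is not; cis+trans / cis x trans when all three are significant with the
H and P log2 ratios sharing / opposing sign; compensatory when H and T
are significant but P is not; conserved when none is; ambiguous for every
other combination.

Gene-level calls take the modal SNP pattern when it reaches a 60%
majority, else the gene stays unassigned.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: pseudocount used in every log2 allelic ratio (Haldane–Anscombe)
RATIO_PSEUDOCOUNT = 0.5

PATTERNS = (
    "cis-only",
    "trans-only",
    "cis+trans",
    "cisxtrans",
    "compensatory",
    "conserved",
    "ambiguous",
)


@dataclass
class SnpAlleleCounts:
    """Allele-resolved read counts at one SNP across libraries.

    ``hybrid``, ``parent1`` and ``parent2`` are (n_replicates, 2) integer
    arrays of (allele-1, allele-2) counts; allele 1 always denotes the
    parent-1 allele.  ``pos`` is 1-based (VCF convention).
    ``library_sizes`` optionally maps ``parent1``/``parent2`` to total
    mapped reads for parental library-size normalization.
    """

    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hybrid: np.ndarray
    parent1: np.ndarray
    parent2: np.ndarray
    library_sizes: dict | None = None

    def __post_init__(self) -> None:
        for name in ("hybrid", "parent1", "parent2"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n_replicates, 2)")
            if (arr < 0).any():
                raise ValueError(f"{name} counts must be nonnegative")
            setattr(self, name, arr)
        n = {self.hybrid.shape[0], self.parent1.shape[0], self.parent2.shape[0]}
        if len(n) != 1:
            raise ValueError("replicate counts must align across libraries")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def parental_scale(self) -> tuple[float, float]:
        """Scale factors bringing both parental libraries to the mean size."""
        if not self.library_sizes:
            return 1.0, 1.0
        s1 = float(self.library_sizes["parent1"])
        s2 = float(self.library_sizes["parent2"])
        mean = (s1 + s2) / 2.0
        return mean / s1, mean / s2


@dataclass
class SnpRegulatoryCall:
    gene_id: str
    chrom: str
    pos: int
    p_P: float
    p_H: float
    p_T: float
    log2_ratio_P: float
    log2_ratio_H: float
    pattern: str


@dataclass
class GeneRegulatoryCall:
    gene_id: str
    pattern: str
    supporting_fraction: float
    n_snps: int


def filter_snps(
    counts: list[SnpAlleleCounts],
    genomic_sites: set,
    *,
    min_depth: int = 20,
    min_het_reads: int = 1,
) -> tuple[list[SnpAlleleCounts], pd.DataFrame]:
    """Apply the four SNP eligibility rules.

    A site is retained iff (a) it also appears in the genomic evidence
    set, (b) the parental allele types diverge in every parental
    replicate (each library's own allele is its strict majority), (c)
    the hybrid shows both alleles in every replicate (>=
    ``min_het_reads`` reads each), and (d) every hybrid and parental
    replicate has total depth >= ``min_depth``.

    Returns the retained records and a per-site log of exclusion reasons.
    """
    kept, log_rows = [], []
    for rec in counts:
        reason = None
        if rec.site not in genomic_sites and (rec.chrom, rec.pos) not in genomic_sites:
            reason = "absent_from_genomic_set"
        elif (rec.parent1[:, 0] <= rec.parent1[:, 1]).any() or (
            rec.parent2[:, 1] <= rec.parent2[:, 0]
        ).any():
            reason = "parental_alleles_not_divergent"
        elif (rec.hybrid < min_het_reads).any():
            reason = "hybrid_not_heterozygous"
        elif (
            (rec.hybrid.sum(axis=1) < min_depth).any()
            or (rec.parent1.sum(axis=1) < min_depth).any()
            or (rec.parent2.sum(axis=1) < min_depth).any()
        ):
            reason = "depth_below_threshold"
        if reason is None:
            kept.append(rec)
        log_rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "gene_id": rec.gene_id,
             "retained": reason is None, "reason": reason or ""}
        )
    log = pd.DataFrame(log_rows)
    logger.info("filter_snps: %d/%d sites retained", len(kept), len(counts))
    return kept, log


def allelic_imbalance_test(allele1_total: float, allele2_total: float) -> tuple[float, float]:
    """Chi-square goodness-of-fit of pooled allele counts against 1:1.

    Returns ``(statistic, p)``; a zero total is undefined and reported
    as (nan, nan).
    """
    a, b = float(allele1_total), float(allele2_total)
    if a < 0 or b < 0:
        raise ValueError("allele totals must be nonnegative")
    total = a + b
    if total == 0:
        return float("nan"), float("nan")
    exp = total / 2.0
    statistic = (a - exp) ** 2 / exp + (b - exp) ** 2 / exp
    return statistic, float(stats.chi2.sf(statistic, df=1))


def ratio_difference_test(hybrid_ratios, parental_ratios) -> tuple[float, float]:
    """Two-tailed pooled-variance t-test between per-replicate log2 ratios."""
    h = np.asarray(hybrid_ratios, dtype=float)
    p = np.asarray(parental_ratios, dtype=float)
    if h.size < 2 or p.size < 2:
        raise ValueError("need >= 2 ratios per side")
    if np.var(h) == 0.0 and np.var(p) == 0.0:
        if np.isclose(h.mean(), p.mean()):
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p set to 0", stacklevel=2)
        return float(np.inf * np.sign(h.mean() - p.mean())), 0.0
    res = stats.ttest_ind(h, p, equal_var=True)
    t, pval = float(res.statistic), float(res.pvalue)
    if np.isnan(pval):
        t, pval = 0.0, 1.0
    return t, pval


def classify_regulatory_pattern(
    sig_P: bool,
    sig_H: bool,
    sig_T: bool,
    log2_ratio_P: float,
    log2_ratio_H: float,
) -> str:
    """Map the three significance decisions (and ratio signs) to a pattern."""
    if sig_P and sig_H and not sig_T:
        return "cis-only"
    if sig_P and not sig_H and sig_T:
        return "trans-only"
    if sig_P and sig_H and sig_T:
        if log2_ratio_P == 0.0 or log2_ratio_H == 0.0:
            warnings.warn("zero log2 ratio with all sets significant; sign undefined", stacklevel=2)
            return "ambiguous"
        return "cis+trans" if (log2_ratio_P > 0) == (log2_ratio_H > 0) else "cisxtrans"
    if not sig_P and sig_H and sig_T:
        return "compensatory"
    if not (sig_P or sig_H or sig_T):
        return "conserved"
    return "ambiguous"


def _pooled_log2_ratio(a: float, b: float) -> float:
    return float(np.log2((a + RATIO_PSEUDOCOUNT) / (b + RATIO_PSEUDOCOUNT)))


def call_snp(rec: SnpAlleleCounts, *, alpha: float = 0.05) -> SnpRegulatoryCall:
    """Run the P/H/T tests at one SNP and classify its pattern."""
    s1, s2 = rec.parental_scale()
    hyb_a1, hyb_a2 = rec.hybrid[:, 0].sum(), rec.hybrid[:, 1].sum()
    par_a1 = rec.parent1[:, 0].astype(float) * s1
    par_a2 = rec.parent2[:, 1].astype(float) * s2

    _, p_H = allelic_imbalance_test(hyb_a1, hyb_a2)
    _, p_P = allelic_imbalance_test(par_a1.sum(), par_a2.sum())
    hybrid_ratios = np.log2((rec.hybrid[:, 0] + RATIO_PSEUDOCOUNT) / (rec.hybrid[:, 1] + RATIO_PSEUDOCOUNT))
    parental_ratios = np.log2((par_a1 + RATIO_PSEUDOCOUNT) / (par_a2 + RATIO_PSEUDOCOUNT))
    _, p_T = ratio_difference_test(hybrid_ratios, parental_ratios)

    log2_ratio_H = _pooled_log2_ratio(hyb_a1, hyb_a2)
    log2_ratio_P = _pooled_log2_ratio(par_a1.sum(), par_a2.sum())
    pattern = classify_regulatory_pattern(
        p_P < alpha, p_H < alpha, p_T < alpha, log2_ratio_P, log2_ratio_H
    )
    return SnpRegulatoryCall(
        gene_id=rec.gene_id,
        chrom=rec.chrom,
        pos=rec.pos,
        p_P=p_P,
        p_H=p_H,
        p_T=p_T,
        log2_ratio_P=log2_ratio_P,
        log2_ratio_H=log2_ratio_H,
        pattern=pattern,
    )


def aggregate_gene_pattern(
    snp_calls: list[SnpRegulatoryCall],
    *,
    majority: float = 0.60,
) -> GeneRegulatoryCall:
    """Gene-level call: modal SNP pattern if it reaches the majority rule."""
    if not snp_calls:
        raise ValueError("need >= 1 SNP call")
    gene_ids = {c.gene_id for c in snp_calls}
    if len(gene_ids) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(gene_ids)}")
    counts = Counter(c.pattern for c in snp_calls)
    # deterministic tie-break on pattern name
    modal, n_modal = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    fraction = n_modal / len(snp_calls)
    pattern = modal if fraction >= majority else "unassigned"
    return GeneRegulatoryCall(
        gene_id=snp_calls[0].gene_id,
        pattern=pattern,
        supporting_fraction=fraction,
        n_snps=len(snp_calls),
    )


def run_ase_pipeline(
    counts: list[SnpAlleleCounts],
    genomic_sites: set,
    *,
    alpha: float = 0.05,
    min_depth: int = 20,
    min_het_reads: int = 1,
    majority: float = 0.60,
) -> dict:
    """Filter -> per-SNP tests -> classification -> gene aggregation -> summary.

    Returns a dict with ``snp_calls`` and ``gene_calls`` DataFrames (the
    latter includes the per-gene H/P log2 ratios behind the scatter-style
    output), ``summary`` pattern fractions over assigned+unassigned genes,
    and the ``filter_log``.
    """
    kept, filter_log = filter_snps(
        counts, genomic_sites, min_depth=min_depth, min_het_reads=min_het_reads
    )
    snp_calls = [call_snp(rec, alpha=alpha) for rec in kept]

    by_gene: dict[str, list[SnpRegulatoryCall]] = {}
    for call in snp_calls:
        by_gene.setdefault(call.gene_id, []).append(call)

    gene_rows = []
    for gene_id in sorted(by_gene):
        calls = by_gene[gene_id]
        agg = aggregate_gene_pattern(calls, majority=majority)
        gene_rows.append(
            {
                "gene_id": gene_id,
                "pattern": agg.pattern,
                "supporting_fraction": agg.supporting_fraction,
                "n_snps": agg.n_snps,
                "log2_ratio_P": float(np.mean([c.log2_ratio_P for c in calls])),
                "log2_ratio_H": float(np.mean([c.log2_ratio_H for c in calls])),
            }
        )
    gene_calls = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "pattern", "supporting_fraction", "n_snps",
                 "log2_ratio_P", "log2_ratio_H"],
    ).set_index("gene_id") if gene_rows else pd.DataFrame(
        columns=["pattern", "supporting_fraction", "n_snps", "log2_ratio_P", "log2_ratio_H"]
    )

    n_genes = len(gene_calls)
    summary = {
        pattern: (float((gene_calls["pattern"] == pattern).sum() / n_genes) if n_genes else 0.0)
        for pattern in PATTERNS + ("unassigned",)
    }
    snp_df = pd.DataFrame([vars(c) for c in snp_calls]) if snp_calls else pd.DataFrame(
        columns=["gene_id", "chrom", "pos", "p_P", "p_H", "p_T",
                 "log2_ratio_P", "log2_ratio_H", "pattern"]
    )
    logger.info("run_ase_pipeline: %d SNP calls on %d genes", len(snp_calls), n_genes)
    return {
        "snp_calls": snp_df,
        "gene_calls": gene_calls,
        "summary": summary,
        "filter_log": filter_log,
    }
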