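"""Additive/nonadditive inheritance-mode classification of hybrid expression.

A gene is additive when its F1 expression is statistically consistent
with the mid-parent value (MPV), and nonadditive otherwise.  Nonadditive
genes subdivide by where the F1 mean falls relative to the parents:
above the higher parent (over-dominance), between the parents
(dominance, closed interval), or below the lower parent
(under-dominance).

The test is a two-tailed homoscedastic (pooled-variance) t-test of the
F1 replicates against per-replicate mid-parent values formed by index
pairing: MPV_r = (P1_r + P2_r) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

MODES = ("additive", "over-dominance", "dominance", "under-dominance")


@dataclass
class TrioExpression:
    """Replicate FPKM vectors for one gene in an F1/P1/P2 trio."""

    gene_id: str
    f1: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    stage: str = ""

    def __post_init__(self) -> None:
        for name in ("f1", "p1", "p2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs >= 2 replicates")
            if (arr < 0).any():
                raise ValueError(f"{name} has negative expression values")
            setattr(self, name, arr)
        if self.p1.size != self.p2.size:
            raise ValueError("parent replicate counts must match to form paired MPVs")


@dataclass
class InheritanceCall:
    gene_id: str
    p_value: float
    mode: str


def classify_inheritance(trio: TrioExpression, alpha: float = 0.05) -> InheritanceCall:
    """Classify one trio as additive / over-dominance / dominance / under-dominance.

    p >= ``alpha`` in the F1-vs-MPV t-test means additive; otherwise the
    F1 mean against the parental means decides the nonadditive mode.
    Boundary ties (F1 mean exactly at a parent mean) count as dominance.
    """
    mpv = (trio.p1 + trio.p2) / 2.0
    if np.var(trio.f1) == 0.0 and np.var(mpv) == 0.0:
        if np.isclose(trio.f1.mean(), mpv.mean()):
            p = 1.0
        else:
            warnings.warn(
                f"{trio.gene_id}: zero pooled variance with unequal means; p set to 0",
                stacklevel=2,
            )
            p = 0.0
    else:
        res = stats.ttest_ind(trio.f1, mpv, equal_var=True)
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
    if p >= alpha:
        mode = "additive"
    else:
        m = trio.f1.mean()
        lo, hi = sorted([trio.p1.mean(), trio.p2.mean()])
        if m > hi:
            mode = "over-dominance"
        elif m < lo:
            mode = "under-dominance"
        else:
            mode = "dominance"
    return InheritanceCall(gene_id=trio.gene_id, p_value=p, mode=mode)


def trios_from_matrix(
    matrix: ExpressionMatrix,
    f1_genotype: str,
    p1_genotype: str,
    p2_genotype: str,
    stage: str,
    gene_ids=None,
) -> list[TrioExpression]:
    """Extract per-gene trios for one stage from an expression matrix."""
    groups = {}
    for name, genotype in (("f1", f1_genotype), ("p1", p1_genotype), ("p2", p2_genotype)):
        samples = matrix.group_samples(genotype, stage)
        if len(samples) < 2:
            raise ValueError(f"genotype {genotype} at {stage} has fewer than 2 replicates")
        groups[name] = matrix.values[samples].to_numpy(dtype=float)
    ids = matrix.gene_ids if gene_ids is None else pd.Index(gene_ids)
    positions = matrix.gene_ids.get_indexer(ids)
    if (positions < 0).any():
        raise KeyError("gene_ids not present in matrix")
    return [
        TrioExpression(
            gene_id=str(gid),
            f1=groups["f1"][i],
            p1=groups["p1"][i],
            p2=groups["p2"][i],
            stage=stage,
        )
        for gid, i in zip(ids, positions)
    ]


def classify_all(trios: list[TrioExpression], alpha: float = 0.05) -> pd.DataFrame:
    """Classify a collection of trios; returns gene_id-indexed calls."""
    calls = [classify_inheritance(t, alpha=alpha) for t in trios]
    return pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls],
         "p_value": [c.p_value for c in calls],
         "mode": [c.mode for c in calls]}
    ).set_index("gene_id")


def summarize_modes(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-mode counts and fractions (fractions sum to 1)."""
    if len(calls) == 0:
        raise ValueError("empty call collection")
    counts = calls["mode"].value_counts().reindex(MODES, fill_value=0)
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()},
    ).rename_axis("mode")
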