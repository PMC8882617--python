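import numpy as np
import pandas as pd
import pytest

from kernelreg import ExpressionMatrix


def make_matrix(values: np.ndarray, genotypes, stage="DAP12", gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from an array and per-column genotypes."""
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    reps, seen = [], {}
    for g in genotypes:
        seen[g] = seen.get(g, 0) + 1
        reps.append(seen[g])
    samples = [f"{g}_{stage}_{r}" for g, r in zip(genotypes, reps)]
    meta = pd.DataFrame(
        {"genotype": list(genotypes), "stage": stage, "replicate": reps},
        index=pd.Index(samples, name="sample"),
    )
    vals = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return ExpressionMatrix(vals, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
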