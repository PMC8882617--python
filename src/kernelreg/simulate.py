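"""Synthetic data generators with planted ground truth.

Three generators mirror the statistical structure each analysis stage
assumes:

* :func:`simulate_regulatory_counts` — per-SNP allele counts in a hybrid
  and its two parental libraries under configurable cis (``c``) and trans
  (``t``) log2 effects, covering the six non-ambiguous regulatory
  divergence categories.
* :func:`simulate_trio_expression` — FPKM-scale replicate expression for
  an F1/parent trio under additive, dominance, over-dominance and
  under-dominance inheritance modes.
* :func:`simulate_module_expression` — a block-correlated latent-factor
  expression matrix with planted co-expression modules, hub genes, and
  kernel traits driven by the module factors.

Every generator returns a ground-truth table so that downstream
classifiers can be scored by recovery rather than by eyeballing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ase import SnpAlleleCounts

REGULATORY_CATEGORIES = (
    "cis-only",
    "trans-only",
    "cis+trans",
    "cisxtrans",
    "compensatory",
    "conserved",
)

INHERITANCE_MODES = ("additive", "dominance", "over-dominance", "under-dominance")

TRAIT_NAMES = ("FKW", "DKW", "TKL", "TKW")


@dataclass
class SimulationConfig:
    """Parameters shared by the three generators.

    Attributes
    ----------
    seed:
        Seed for the internal PRNG; a fixed seed gives byte-identical
        outputs.
    n_replicates:
        Biological replicates per library (hybrid, each parent).
    genes_per_category:
        Genes simulated per regulatory category / inheritance mode.
    read_depth_per_snp:
        Mean total read depth per SNP per replicate library.
    nb_dispersion:
        Negative-binomial dispersion phi (variance = m + phi * m^2) of
        the per-replicate SNP depths.  The default 0 (Poisson) keeps the
        replicate-pooled parental chi-square calibrated at its nominal
        level; positive values add biological overdispersion, under
        which that test is knowingly anticonservative.
    cis_effect, trans_effect:
        Magnitudes of the cis and trans log2 effects used for the
        non-null regulatory categories (both alleles' ratio scales).
    delta:
        log2 offset beyond the parental range for over-/under-dominance
        (F1 mean = high parent * 2**delta, resp. low parent * 2**-delta).
    dominance_weight:
        Position of the dominance-mode F1 mean on the segment from the
        low to the high parent: F1 = mu1 + w * (mu2 - mu1).  1.0 is
        complete high-parent dominance; the default 0.75 plants partial
        dominance strictly inside the parental range so the planted mode
        is identifiable from finite replicates.
    noise_sd:
        log2-scale standard deviation of the multiplicative (lognormal)
        expression noise.
    n_modules, genes_per_module, n_background:
        Module-structure dimensions for the network generator.
    n_hub_genes, hub_loading:
        Number of genes per module planted at the elevated hub loading.
    n_samples:
        Samples in the module matrix (default 24 = 8 genotypes x 3 reps).
    factor_loading:
        Loading of ordinary module genes on their latent factor, in [0, 1].
    trait_noise_sd:
        SD of the Gaussian noise added to the factor driving each trait.
    """

    seed: int = 0
    n_replicates: int = 3
    genes_per_category: int = 100
    read_depth_per_snp: float = 200.0
    nb_dispersion: float = 0.0
    cis_effect: float = 2.0
    trans_effect: float = 2.0
    delta: float = 1.0
    dominance_weight: float = 0.75
    noise_sd: float = 0.1
    n_modules: int = 5
    genes_per_module: int = 60
    n_background: int = 100
    n_hub_genes: int = 10
    hub_loading: float = 0.98
    n_samples: int = 24
    factor_loading: float = 0.9
    trait_noise_sd: float = 0.1

    def validate(self) -> None:
        counts = {
            "n_replicates": self.n_replicates,
            "genes_per_category": self.genes_per_category,
            "n_modules": self.n_modules,
            "genes_per_module": self.genes_per_module,
            "n_hub_genes": self.n_hub_genes,
            "n_samples": self.n_samples,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.read_depth_per_snp <= 0:
            raise ValueError("read_depth_per_snp must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")
        for name in ("factor_loading", "hub_loading"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.dominance_weight <= 1.0:
            raise ValueError("dominance_weight must lie in (0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive for over/under-dominance")
        if self.n_background < 0:
            raise ValueError("n_background must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draw parameterized by (mean, dispersion).

    var = mean + dispersion * mean**2; dispersion == 0 falls back to Poisson.
    """
    if mean <= 0:
        raise ValueError(f"nonpositive depth mean {mean}; rejected configuration")
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def category_effects(config: SimulationConfig) -> dict[str, tuple[float, float]]:
    """Map each regulatory category to a (c, t) effect pair.

    The observable signals are the hybrid allelic log2 ratio (= c) and the
    parental log2 ratio (= c + t).  For the cis x trans category the trans
    effect is set to -(c + t_mag) so both observable ratios have magnitude
    |c| resp. |t_mag| with opposite signs, keeping its detectability on par
    with the other categories.
    """
    c, t = config.cis_effect, config.trans_effect
    return {
        "cis-only": (c, 0.0),
        "trans-only": (0.0, t),
        "cis+trans": (c, t),
        "cisxtrans": (c, -(c + t)),
        "compensatory": (c, -c),
        "conserved": (0.0, 0.0),
    }


def simulate_regulatory_counts(
    config: SimulationConfig,
) -> tuple[list[SnpAlleleCounts], pd.DataFrame]:
    """Simulate per-SNP allele counts for the six regulatory categories.

    One SNP per gene.  Per replicate, the hybrid total depth is
    negative-binomial around ``read_depth_per_snp`` and the allele-1 count
    is Binomial(depth, 2**c / (1 + 2**c)).  The parents are two separate
    homozygous libraries whose mean depths differ by the factor
    2**(c + t), split symmetrically so the total parental depth stays near
    2 * read_depth_per_snp.

    Returns the count records and a ground-truth table with one row per
    gene.  Effect signs alternate between consecutive genes of a category.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    effects = category_effects(config)
    n_rep = config.n_replicates
    depth = config.read_depth_per_snp

    records: list[SnpAlleleCounts] = []
    truth_rows = []
    pos = 0
    for category in REGULATORY_CATEGORIES:
        c0, t0 = effects[category]
        for g in range(config.genes_per_category):
            sign = 1.0 if g % 2 == 0 else -1.0
            c, t = sign * c0, sign * t0
            pos += 1000
            gene_id = f"gene_{category.replace('+', 'p').replace('x', 'x')}_{g:04d}"

            frac1 = 2.0**c / (1.0 + 2.0**c)
            hyb_depth = _nb_draw(rng, depth, config.nb_dispersion, n_rep)
            hyb_a1 = rng.binomial(hyb_depth, frac1)
            hybrid = np.stack([hyb_a1, hyb_depth - hyb_a1], axis=1)

            half = (c + t) / 2.0
            p1_depth = _nb_draw(rng, depth * 2.0**half, config.nb_dispersion, n_rep)
            p2_depth = _nb_draw(rng, depth * 2.0**-half, config.nb_dispersion, n_rep)
            parent1 = np.stack([p1_depth, np.zeros(n_rep, dtype=np.int64)], axis=1)
            parent2 = np.stack([np.zeros(n_rep, dtype=np.int64), p2_depth], axis=1)

            records.append(
                SnpAlleleCounts(
                    gene_id=gene_id,
                    chrom="chr1",
                    pos=pos,
                    ref="A",
                    alt="G",
                    hybrid=hybrid,
                    parent1=parent1,
                    parent2=parent2,
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "regulatory_category": category,
                    "inheritance_mode": "",
                    "module": "",
                    "cis_effect": c,
                    "trans_effect": t,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_trio_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an F1/P1/P2 expression matrix under the four inheritance modes.

    Parent means are drawn per gene with mu1 < mu2 (mu1 ~ U(2, 10),
    mu2 = 3 * mu1); the F1 mean follows the mode map (mid-parent for
    additive, ``dominance_weight`` along the parental segment for
    dominance, 2**±delta beyond the parental range for over/under
    dominance).  Replicates multiply the mode mean by lognormal noise
    2**N(0, noise_sd).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n_rep = config.n_replicates
    n = config.genes_per_category

    gene_ids, truth_rows, rows = [], [], []
    for mode in INHERITANCE_MODES:
        mu1 = rng.uniform(2.0, 10.0, size=n)
        mu2 = 3.0 * mu1
        if mode == "additive":
            f1 = (mu1 + mu2) / 2.0
        elif mode == "dominance":
            f1 = mu1 + config.dominance_weight * (mu2 - mu1)
        elif mode == "over-dominance":
            f1 = mu2 * 2.0**config.delta
        else:
            f1 = mu1 * 2.0**-config.delta
        means = np.stack([f1, mu1, mu2], axis=1)  # F1, P1, P2
        noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=(n, 3, n_rep))
        values = means[:, :, None] * noise
        for g in range(n):
            gene_id = f"gene_{mode}_{g:04d}"
            gene_ids.append(gene_id)
            rows.append(values[g].reshape(-1))
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "regulatory_category": "",
                    "inheritance_mode": mode,
                    "module": "",
                }
            )

    genotypes = ["F1", "P1", "P2"]
    samples = [f"{g}_DAP12_{r + 1}" for g in genotypes for r in range(n_rep)]
    meta = pd.DataFrame(
        {
            "genotype": [g for g in genotypes for _ in range(n_rep)],
            "stage": "DAP12",
            "replicate": [r + 1 for _ in genotypes for r in range(n_rep)],
        },
        index=pd.Index(samples, name="sample"),
    )
    values_df = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return ExpressionMatrix(values_df, meta), pd.DataFrame(truth_rows)


def simulate_module_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a block-correlated module matrix, kernel traits, and truth.

    One latent factor per module is drawn i.i.d. N(0, 1) per sample.  A
    module gene with loading ``lam`` is ``lam * factor +
    sqrt(1 - lam^2) * eps``; the first ``n_hub_genes`` of each module use
    ``hub_loading``, the rest ``factor_loading``.  Background genes are
    pure noise.  The latent signal is mapped affinely onto an FPKM-like
    scale (10 + 2z, floored at 0) so pairwise Pearson correlations are
    preserved exactly and every gene passes a mean-FPKM > 1 filter.

    Each of the four kernel traits (FKW, DKW, TKL, TKW) equals one module
    factor plus N(0, trait_noise_sd) noise, cycling through factors.
    """
    config.validate()
    if config.genes_per_module < 50:
        warnings.warn(
            "genes_per_module < 50: planted modules fall below the minimum "
            "detectable module size of 50 genes",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed + 2)
    n_s = config.n_samples
    factors = rng.standard_normal((config.n_modules, n_s))

    gene_ids, truth_rows, blocks = [], [], []
    for m in range(config.n_modules):
        label = f"M{m + 1}"
        lam = np.full(config.genes_per_module, config.factor_loading)
        n_hub = min(config.n_hub_genes, config.genes_per_module)
        lam[:n_hub] = config.hub_loading
        eps = rng.standard_normal((config.genes_per_module, n_s))
        z = lam[:, None] * factors[m] + np.sqrt(1.0 - lam[:, None] ** 2) * eps
        blocks.append(z)
        for g in range(config.genes_per_module):
            gene_ids.append(f"gene_{label}_{g:04d}")
            truth_rows.append(
                {
                    "gene_id": gene_ids[-1],
                    "regulatory_category": "",
                    "inheritance_mode": "",
                    "module": label,
                    "is_hub": g < n_hub,
                }
            )
    if config.n_background:
        blocks.append(rng.standard_normal((config.n_background, n_s)))
        for g in range(config.n_background):
            gene_ids.append(f"gene_bg_{g:04d}")
            truth_rows.append(
                {
                    "gene_id": gene_ids[-1],
                    "regulatory_category": "",
                    "inheritance_mode": "",
                    "module": "unassigned",
                    "is_hub": False,
                }
            )
    z = np.concatenate(blocks, axis=0)
    values = np.maximum(10.0 + 2.0 * z, 0.0)

    n_geno = max(1, n_s // 3)
    samples, genos, reps = [], [], []
    for s in range(n_s):
        geno = f"G{s // 3 + 1}" if s // 3 < n_geno else f"G{n_geno}"
        rep = s % 3 + 1
        samples.append(f"{geno}_DAP12_{rep}")
        genos.append(geno)
        reps.append(rep)
    meta = pd.DataFrame(
        {"genotype": genos, "stage": "DAP12", "replicate": reps},
        index=pd.Index(samples, name="sample"),
    )
    values_df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    trait_data = {}
    for j, trait in enumerate(TRAIT_NAMES):
        factor = factors[j % config.n_modules]
        trait_data[trait] = factor + rng.normal(0.0, config.trait_noise_sd, size=n_s)
    traits = pd.DataFrame(trait_data, index=pd.Index(samples, name="sample"))

    return ExpressionMatrix(values_df, meta), traits, pd.DataFrame(truth_rows)
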