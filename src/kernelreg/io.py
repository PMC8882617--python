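"""File formats, run configuration, and the end-to-end pipeline driver.

Formats
-------
* Expression TSV: first column ``gene_id``; remaining columns named
  ``<genotype>_<stage>_<rep>`` (stage and replicate carry no further
  underscores; the genotype may).
* Allele-count TSV: long format with columns ``chrom  pos  gene_id
  library  replicate  allele1_count  allele2_count`` where library is
  one of ``hybrid``/``parent1``/``parent2``.
* Variants: VCF with 1-based POS; only biallelic records are used.
* Traits TSV: ``sample`` plus one column per trait.

Every file written by :func:`run_all` embeds the seed and a hash of the
resolved configuration so outputs are traceable to their run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import ase as ase_mod
from . import inheritance as inh_mod
from . import network as net_mod
from .expression import ExpressionMatrix, differential_expression
from .simulate import (
    SimulationConfig,
    simulate_module_expression,
    simulate_regulatory_counts,
    simulate_trio_expression,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression


def _parse_sample_name(name: str) -> tuple[str, str, int]:
    parts = name.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(f"malformed sample column {name!r}; expected <genotype>_<stage>_<rep>")
    genotype, stage, rep = parts
    try:
        rep_i = int(rep)
    except ValueError as exc:
        raise ValueError(f"malformed replicate in sample column {name!r}") from exc
    return genotype, stage, rep_i


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Load an expression TSV, deriving sample metadata from column names."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {path}: {dupes[:5]}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"non-numeric cells in columns {bad[:5]} of {path}")
    parsed = [_parse_sample_name(c) for c in values.columns]
    meta = pd.DataFrame(
        parsed, columns=["genotype", "stage", "replicate"],
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values, meta)


# -------------------------------------------------------------- allele counts


def write_allele_counts_tsv(counts: list[ase_mod.SnpAlleleCounts], path) -> None:
    rows = []
    for rec in counts:
        for library, arr in (("hybrid", rec.hybrid), ("parent1", rec.parent1), ("parent2", rec.parent2)):
            for r in range(arr.shape[0]):
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "gene_id": rec.gene_id,
                        "ref": rec.ref,
                        "alt": rec.alt,
                        "library": library,
                        "replicate": r + 1,
                        "allele1_count": int(arr[r, 0]),
                        "allele2_count": int(arr[r, 1]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_counts_tsv(path) -> list[ase_mod.SnpAlleleCounts]:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "gene_id", "library", "replicate", "allele1_count", "allele2_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele-count TSV missing columns {sorted(missing)}")
    records = []
    for (chrom, pos, gene_id), grp in df.groupby(["chrom", "pos", "gene_id"], sort=False):
        arrays = {}
        for library, sub in grp.groupby("library"):
            sub = sub.sort_values("replicate")
            arrays[library] = sub[["allele1_count", "allele2_count"]].to_numpy(dtype=np.int64)
        try:
            records.append(
                ase_mod.SnpAlleleCounts(
                    gene_id=str(gene_id),
                    chrom=str(chrom),
                    pos=int(pos),
                    ref=str(grp["ref"].iloc[0]) if "ref" in grp else "N",
                    alt=str(grp["alt"].iloc[0]) if "alt" in grp else "N",
                    hybrid=arrays["hybrid"],
                    parent1=arrays["parent1"],
                    parent2=arrays["parent2"],
                )
            )
        except KeyError as exc:
            raise ValueError(f"site {chrom}:{pos} missing library {exc}") from exc
    return records


# --------------------------------------------------------------------- VCF


def write_variants_vcf(counts: list[ase_mod.SnpAlleleCounts], path) -> None:
    """Write the genomic evidence set as a minimal VCF (1-based positions)."""
    chroms = sorted({rec.chrom for rec in counts})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(counts, key=lambda r: (r.chrom, r.pos)):
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path) -> set[tuple[str, int, str, str]]:
    """Biallelic site keys (chrom, 1-based pos, ref, alt) from a VCF."""
    sites = set()
    skipped = 0
    for variant in VCF(str(path)):
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        sites.add((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    if skipped:
        logger.info("read_variants_vcf: skipped %d multiallelic records", skipped)
    return sites


# ------------------------------------------------------------------- traits


def write_traits_tsv(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("sample").to_csv(path, sep="\t")


def read_traits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    cols = ["gene_id", "regulatory_category", "inheritance_mode", "module"]
    truth.reindex(columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Thresholds and dimensions for an end-to-end run.

    Stage-specific soft powers follow the study design: beta 9
    everywhere except DAP8, which uses 6.
    """

    seed: int = 0
    out_dir: str = "kernelreg_out"
    alpha: float = 0.05
    fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    min_fpkm: float = 1.0
    min_depth: int = 20
    majority: float = 0.60
    beta: int = 9
    beta_by_stage: dict = field(default_factory=lambda: {"DAP8": 6})
    min_module_size: int = 50
    merge_cut: float = 0.15
    edge_threshold: float = 0.20
    top_n_hubs: int = 30
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def beta_for(self, stage: str) -> int:
        return int(self.beta_by_stage.get(stage, self.beta))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # paths must not perturb the config hash
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def run_all(config: RunConfig) -> dict:
    """Simulate every input, run all stages, and write the report bundle.

    The pipeline chains DEG calling and inheritance classification on
    the trio matrix, the seven-way regulatory assignment on the allele
    counts, and module detection / trait correlation / hub extraction /
    edge export on the 24-sample module matrix.  A ``summary.json``
    gathers pattern fractions, mode fractions, and the module-trait
    table; all randomness flows from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    logger.info("run_all: seed=%d hash=%s", config.seed, stamp["config_hash"])

    # --- trio stage: DEG + inheritance -----------------------------------
    trio_matrix, trio_truth = simulate_trio_expression(sim)
    write_expression_tsv(trio_matrix, out / "trio_expression.tsv")
    stage = trio_matrix.sample_meta["stage"].iloc[0]
    deg = differential_expression(
        trio_matrix, ("F1", stage), ("P2", stage),
        min_fpkm=config.min_fpkm, max_q=config.fdr, min_abs_log2fc=config.min_abs_log2fc,
    )
    deg.to_csv(out / "deg.tsv", sep="\t")
    trios = inh_mod.trios_from_matrix(trio_matrix, "F1", "P1", "P2", stage)
    calls = inh_mod.classify_all(trios, alpha=config.alpha)
    calls.to_csv(out / "inheritance.tsv", sep="\t")
    mode_summary = inh_mod.summarize_modes(calls)

    # --- ASE stage --------------------------------------------------------
    counts, ase_truth = simulate_regulatory_counts(sim)
    write_allele_counts_tsv(counts, out / "allele_counts.tsv")
    write_variants_vcf(counts, out / "parents.vcf")
    genomic_sites = read_variants_vcf(out / "parents.vcf")
    ase_result = ase_mod.run_ase_pipeline(
        counts, genomic_sites,
        alpha=config.alpha, min_depth=config.min_depth, majority=config.majority,
    )
    ase_result["snp_calls"].to_csv(out / "snp_calls.tsv", sep="\t", index=False)
    ase_result["gene_calls"].to_csv(out / "gene_calls.tsv", sep="\t")

    # --- network stage ----------------------------------------------------
    module_matrix, traits, module_truth = simulate_module_expression(sim)
    write_expression_tsv(module_matrix, out / "module_expression.tsv")
    write_traits_tsv(traits, out / "traits.tsv")
    network_summary = run_network_stage(
        module_matrix, traits, config, out, stage=stage,
    )

    truth = pd.concat([trio_truth, ase_truth, module_truth], ignore_index=True)
    write_truth_tsv(truth, out / "ground_truth.tsv")

    summary = {
        **stamp,
        "settings": {
            "deg_filter": "group-mean FPKM > 1",
            "mpv_pairing": "index-matched replicate pairs",
            "t_set_units": "per-replicate log2 allelic ratios",
            "parental_ratio": "cross-library, equal-size normalized",
        },
        "n_deg": int(deg["passes"].sum()),
        "inheritance_mode_fractions": {
            m: float(mode_summary.loc[m, "fraction"]) for m in mode_summary.index
        },
        "regulatory_pattern_fractions": ase_result["summary"],
        **network_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary


def run_network_stage(
    matrix: ExpressionMatrix,
    traits: pd.DataFrame | None,
    config: RunConfig,
    out: Path,
    *,
    stage: str = "",
) -> dict:
    """Network construction through edge export; returns its summary slice."""
    filtered = net_mod.filter_network_genes(matrix, config.min_fpkm)
    beta = config.beta_for(stage)
    assignment, eigengenes = net_mod.detect_modules(
        filtered, beta, min_size=config.min_module_size, merge_cut=config.merge_cut,
    )
    assignment.labels.rename("module").rename_axis("gene_id").to_csv(
        out / "module_assignment.tsv", sep="\t"
    )
    hubs = net_mod.extract_hubs(filtered, assignment, beta=beta, top_n=config.top_n_hubs)
    if hubs:
        hub_table = pd.concat([t.assign(module=m) for m, t in hubs.items()], ignore_index=True)
    else:
        hub_table = pd.DataFrame(columns=["gene_id", "k", "k_total", "module"])
    hub_table.to_csv(out / "hub_genes.tsv", sep="\t", index=False)

    adj = net_mod.compute_adjacency(filtered, beta)
    tom = net_mod.compute_tom(adj)
    edges = net_mod.export_network(tom, assignment, weight_threshold=config.edge_threshold)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    summary: dict = {"n_modules": len(eigengenes)}
    if traits is None:
        logger.warning("no traits table; module-trait correlation skipped")
        summary["module_trait"] = None
        return summary
    assoc = net_mod.module_trait_correlation(eigengenes, traits, alpha=config.alpha)
    assoc.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    summary["module_trait"] = [
        {k: (round(v, 10) if isinstance(v, float) else (bool(v) if isinstance(v, np.bool_) else v))
         for k, v in row.items()}
        for row in assoc.to_dict("records")
    ]
    return summary
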