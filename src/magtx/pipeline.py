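"""End-to-end pipeline orchestration.

Runs count -> expression -> community profile -> pathway calls ->
denitrification profile -> amino-acid matrix -> family profile from a
single validated configuration, writing tidy TSV outputs plus a manifest
(input checksums, configuration, seed, package version) so identical
configuration and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import count_library
from .expression import community_profile, expression_table, top_expressed
from .model_io import (
    DEFAULT_MIN_IDENTITY,
    SamFilterStats,
    read_annotation_table,
    read_cost_table,
    read_genome_bins,
    read_gff3,
    read_pathway_definitions,
    read_sam_subset,
)
from .pathways import (
    DEFAULT_COMPLETENESS_THRESHOLD,
    amino_acid_matrix,
    call_all_pathways,
    denitrification_profile,
    functional_family_profile,
)

logger = logging.getLogger("magtx")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    fasta: str
    gff: str
    bins: str
    dna_sam: str
    rna_sam: str
    pathways: str
    annotations: str
    cost_table: str
    outdir: str
    min_identity: float = DEFAULT_MIN_IDENTITY
    stranded_dna: str = "no"
    stranded_rna: str = "yes"
    library_size_mode: str = "mapped"
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD
    include_unbinned: bool = False
    n_permutations: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 <= self.min_identity <= 1:
            raise ConfigError(
                f"min_identity must be in [0,1], got {self.min_identity}")
        if not 0 < self.completeness_threshold <= 1:
            raise ConfigError("completeness_threshold must be in (0,1]")
        for mode in (self.stranded_dna, self.stranded_rna):
            if mode not in ("yes", "no", "reverse"):
                raise ConfigError(f"bad stranded mode {mode!r}")
        for name in ("fasta", "gff", "bins", "dna_sam", "rna_sam",
                     "pathways", "annotations", "cost_table"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"input {name} not found: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the manifest of written outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    bins = read_genome_bins(config.fasta, config.bins)
    orfs = read_gff3(config.gff, bins)
    logger.info("stage=load bins=%d orfs=%d", len(bins), len(orfs))

    expr_frames = []
    count_tables = {}
    for lib, sam, stranded in (("dna", config.dna_sam, config.stranded_dna),
                               ("rna", config.rna_sam, config.stranded_rna)):
        stats = SamFilterStats()
        records = read_sam_subset(sam, min_identity=config.min_identity,
                                  stats=stats)
        table = count_library(records, bins, orfs, library_id=lib,
                              stranded=stranded,
                              library_size_mode=config.library_size_mode,
                              filter_stats=stats)
        table.check_partition()
        count_tables[lib] = table
        logger.info(
            "stage=count lib=%s assigned=%d no_feature=%d ambiguous=%d "
            "filtered_identity=%d unmapped=%d", lib, table.n_assigned,
            table.n_no_feature, table.n_ambiguous,
            table.n_filtered_identity, table.n_unmapped)
        rows = pd.DataFrame(
            [{"orf_id": o, "count": c}
             for o, c in sorted(table.feature_counts.items())])
        rows["library"] = lib
        outputs[f"counts_{lib}"] = outdir / f"counts_{lib}.tsv"
        rows.to_csv(outputs[f"counts_{lib}"], sep="\t", index=False)

        etab = expression_table(table, bins, orfs)
        df = etab.data.copy()
        df["library"] = lib
        expr_frames.append(df)
        if lib == "rna":
            rna_expr = etab

    outputs["expr"] = outdir / "expr.tsv"
    pd.concat(expr_frames).to_csv(outputs["expr"], sep="\t", index=False)

    include = None
    if not config.include_unbinned:
        include = [b.bin_id for b in bins if b.bin_id != "unbinned"]
    community = pd.concat([
        community_profile(count_tables[lib], bins, include).as_frame()
        for lib in ("dna", "rna")])
    outputs["community"] = outdir / "community.tsv"
    community.to_csv(outputs["community"], sep="\t", index=False)
    logger.info("stage=community bins=%d", community["bin_id"].nunique())

    pathway_defs = read_pathway_definitions(config.pathways)
    genome_bins = [b for b in bins if b.bin_id != "unbinned"]
    calls = call_all_pathways(
        pathway_defs, genome_bins, rna_expr,
        completeness_threshold=config.completeness_threshold)
    outputs["pathway_calls"] = outdir / "pathway_calls.tsv"
    calls.to_csv(outputs["pathway_calls"], sep="\t", index=False)
    logger.info("stage=pathways calls=%d present=%d", len(calls),
                int(calls["present"].sum()))

    annotations = read_annotation_table(config.annotations)
    denitro = denitrification_profile(genome_bins, annotations, rna_expr)
    outputs["denitrification"] = outdir / "denitrification.tsv"
    denitro.to_csv(outputs["denitrification"], sep="\t", index=False)

    cost = read_cost_table(config.cost_table)
    aa_matrix, aa_stats = amino_acid_matrix(
        calls, cost, n_permutations=config.n_permutations, seed=config.seed)
    outputs["aa_matrix"] = outdir / "aa_matrix.tsv"
    aa_matrix.to_csv(outputs["aa_matrix"], sep="\t", index=False)
    outputs["aa_cost_stats"] = outdir / "aa_cost_stats.tsv"
    aa_stats.to_csv(outputs["aa_cost_stats"], sep="\t", index=False)

    families = functional_family_profile(genome_bins, annotations, rna_expr)
    outputs["family_profile"] = outdir / "family_profile.tsv"
    families.to_csv(outputs["family_profile"], sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {name: _sha256(getattr(config, name))
                   for name in ("fasta", "gff", "bins", "dna_sam", "rna_sam",
                                "pathways", "annotations", "cost_table")},
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    logger.info("stage=done outputs=%d", len(outputs))
    return outputs


def summarize_community(outdir: str | Path, top_k: int = 5) -> dict:
    """JSON-ready summary of a finished run: per-bin abundance/expression
    fractions, top-k expressed ORFs per bin, pathway-presence counts."""
    outdir = Path(outdir)
    community = pd.read_csv(outdir / "community.tsv", sep="\t")
    expr = pd.read_csv(outdir / "expr.tsv", sep="\t")
    calls = pd.read_csv(outdir / "pathway_calls.tsv", sep="\t")

    fractions = {
        lib: {row.bin_id: row.fraction
              for row in community[community["library"] == lib].itertuples()}
        for lib in community["library"].unique()
    }
    rna = expr[expr["library"] == "rna"]
    top = {}
    for bin_id, grp in rna.groupby("bin_id"):
        ranked = grp.sort_values(["rel_expr", "orf_id"],
                                 ascending=[False, True], kind="mergesort")
        top[bin_id] = [
            {"orf_id": r.orf_id, "rel_expr": None if pd.isna(r.rel_expr)
             else float(r.rel_expr)}
            for r in ranked.head(top_k).itertuples()]
    presence = (calls[calls["present"]]
                .groupby("bin_id")["pathway_id"].count().to_dict())
    return {
        "fractions": fractions,
        "top_expressed": top,
        "pathways_present": {k: int(v) for k, v in presence.items()},
    }
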