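"""RPKM, median-relativized expression, and community abundance profiles.

RPKM = 1e9 * count / (library_size * length_bp) normalizes a read count by
sequencing depth and feature length. Within each genome, an ORF's relative
expression is its RPKM divided by the median RPKM over *all* the genome's
predicted ORFs (zero-count ORFs included); 1 = median expression. Genome-
level abundance/expression proxies are length-normalized read densities
(mapped reads / genome length), reported as fractions of the included bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountTable
from .model_io import GenomeBin, OrfFeature


def rpkm(count: int | float, orf_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if orf_length_bp <= 0:
        raise ValueError("orf_length_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return 1e9 * count / (library_size * orf_length_bp)


@dataclass
class ExpressionTable:
    """Per-ORF count/RPKM/relative expression for one library.

    ``rel_expr`` is NaN for genomes whose median RPKM is 0 (at least half
    the ORFs unexpressed); such genomes are listed in
    ``undefined_median_bins``. No pseudocounts are applied anywhere.
    """

    library_id: str
    data: pd.DataFrame  # columns: orf_id, bin_id, count, rpkm, rel_expr
    genome_median_rpkm: dict[str, float]
    undefined_median_bins: tuple[str, ...] = ()
    library_size: int = 0

    def rpkm_of(self, orf_id: str) -> float:
        return float(self.data.set_index("orf_id").loc[orf_id, "rpkm"])

    def orf_rpkm(self) -> Mapping[str, float]:
        return dict(zip(self.data["orf_id"], self.data["rpkm"]))

    def orf_count(self) -> Mapping[str, int]:
        return dict(zip(self.data["orf_id"], self.data["count"]))

    def orf_rel_expr(self) -> Mapping[str, float]:
        return dict(zip(self.data["orf_id"], self.data["rel_expr"]))


def _orf_bin_map(genome_bins: Sequence[GenomeBin],
                 orfs: Sequence[OrfFeature]) -> dict[str, str]:
    bin_of_contig = {cid: b.bin_id for b in genome_bins
                     for cid in b.contig_ids}
    out = {}
    for o in orfs:
        if o.contig_id not in bin_of_contig:
            raise ValueError(f"ORF {o.orf_id} on contig {o.contig_id!r} "
                             f"not covered by any bin")
        out[o.orf_id] = bin_of_contig[o.contig_id]
    return out


def expression_table(
    counts: CountTable,
    genome_bins: Sequence[GenomeBin],
    orfs: Sequence[OrfFeature],
) -> ExpressionTable:
    """Build the per-ORF expression table for one counted library.

    The genome median is taken over every predicted ORF of the genome,
    including those with zero counts — the literal reading of relativizing
    against "the median RPKM across the genome". With an even number of
    ORFs the median is the mean of the two middle values.
    """
    bin_of = _orf_bin_map(genome_bins, orfs)
    rows = []
    for o in orfs:
        c = counts.feature_counts.get(o.orf_id, 0)
        rows.append({
            "orf_id": o.orf_id,
            "bin_id": bin_of[o.orf_id],
            "count": c,
            "rpkm": rpkm(c, o.length_bp, counts.library_size),
        })
    df = pd.DataFrame(rows, columns=["orf_id", "bin_id", "count", "rpkm"])

    medians: dict[str, float] = {}
    undefined: list[str] = []
    rel = np.full(len(df), np.nan)
    for bin_id, grp in df.groupby("bin_id", sort=False):
        med = float(np.median(grp["rpkm"].to_numpy()))
        medians[bin_id] = med
        if med > 0:
            rel[grp.index] = grp["rpkm"].to_numpy() / med
        else:
            undefined.append(bin_id)
            warnings.warn(
                f"genome {bin_id}: median RPKM is 0 (>= half of ORFs "
                f"unexpressed); relative expression undefined", stacklevel=2)
    df["rel_expr"] = rel
    return ExpressionTable(
        library_id=counts.library_id, data=df, genome_median_rpkm=medians,
        undefined_median_bins=tuple(undefined),
        library_size=counts.library_size)


def relative_expression(table: ExpressionTable) -> Mapping[str, float]:
    """Per-ORF relative expression (RPKM / genome median RPKM)."""
    return table.orf_rel_expr()


@dataclass
class CommunityProfile:
    """Per-genome length-normalized read density and community fractions."""

    library_id: str
    read_density: dict[str, float]  # bin_id -> mapped reads per bp
    fraction: dict[str, float]      # bin_id -> share of summed densities
    included_bins: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"bin_id": b, "library": self.library_id,
              "read_density": self.read_density[b],
              "fraction": self.fraction[b]}
             for b in self.included_bins])


def community_profile(
    counts: CountTable,
    genome_bins: Sequence[GenomeBin],
    include: Sequence[str] | None = None,
) -> CommunityProfile:
    """Length-normalized genome read densities and their fractions.

    density(bin) = total mapped reads on the bin's contigs / bin length;
    fraction(bin) = density / sum of densities over the included bins.
    DNA libraries yield relative abundance, RNA libraries relative
    expression of each genome. ``include`` defaults to all bins in
    ``genome_bins`` (pass an explicit list to fold in or drop the unbinned
    pool).
    """
    bins_by_id = {b.bin_id: b for b in genome_bins}
    if include is None:
        include = [b.bin_id for b in genome_bins]
    if not include:
        raise ValueError("include list must be non-empty")
    density = {}
    for bin_id in include:
        b = bins_by_id[bin_id]
        if b.total_length_bp <= 0:
            raise ValueError(f"bin {bin_id} has non-positive length")
        density[bin_id] = counts.genome_counts.get(bin_id, 0) / b.total_length_bp
    total = sum(density.values())
    if total == 0:
        fraction = {b: float("nan") for b in include}
    else:
        fraction = {b: d / total for b, d in density.items()}
    return CommunityProfile(
        library_id=counts.library_id, read_density=density,
        fraction=fraction, included_bins=tuple(include))


def top_expressed(table: ExpressionTable, bin_id: str, k: int
                  ) -> pd.DataFrame:
    """Top-k ORFs of a genome by relative expression.

    Stable descending sort on rel_expr; ties broken by orf_id so the
    ranking is deterministic. k beyond the genome's ORF count returns the
    full ranking.
    """
    sub = table.data[table.data["bin_id"] == bin_id]
    ranked = sub.sort_values(["rel_expr", "orf_id"],
                             ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
    return ranked.head(k)
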