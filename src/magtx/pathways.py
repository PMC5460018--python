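"""Pathway presence calls and pathway-level expression aggregation.

Aggregation rules (gene -> reaction -> pathway):

* multi-subunit enzyme complex (e.g. hydrazine synthase hzsABC): the
  complex is only as expressed as its least-expressed subunit -> minimum
  over subunit RPKMs;
* isozymes / multi-copy genes catalysing the same reaction: the reaction
  runs on the most-expressed alternative -> maximum over enzyme groups;
* pathway expression: arithmetic mean of reaction RPKMs over reactions
  that have at least one assigned enzyme group (optionally zero-filling
  unassigned reactions).

A pathway is called present in a genome when every key reaction has an
assigned enzyme group and the fraction of assigned reactions meets the
completeness threshold. Since the genome median is a single positive
constant, relativizing before or after any min/max/mean aggregation gives
identical results; values here are relativized after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .model_io import (
    AMINO_ACIDS,
    CostTable,
    EnzymeGroup,
    GenomeBin,
    PathwayDefinition,
    Reaction,
)

DEFAULT_COMPLETENESS_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# Enzyme-level aggregation
# ---------------------------------------------------------------------------

def enzyme_group_rpkm(group: EnzymeGroup,
                      orf_rpkm: Mapping[str, float]) -> float:
    """RPKM of one enzyme group: min over complex subunits, else the gene's
    own RPKM (max over members for a multi-copy single group)."""
    values = [orf_rpkm[m] for m in group.member_orf_ids]
    return min(values) if group.kind == "complex" else max(values)


def group_is_assigned(group: EnzymeGroup, genome_orfs: frozenset[str] | set[str]
                      ) -> bool:
    """A group resolves in a genome iff all its members are that genome's
    ORFs (a complex missing a subunit elsewhere cannot be evaluated)."""
    return all(m in genome_orfs for m in group.member_orf_ids)


def reaction_rpkm(reaction: Reaction, orf_rpkm: Mapping[str, float],
                  genome_orfs: set[str] | frozenset[str]) -> float:
    """Maximum over the reaction's assigned isozyme groups.

    Raises if no group is assigned; callers exclude such reactions.
    """
    values = [enzyme_group_rpkm(g, orf_rpkm) for g in reaction.enzymes
              if group_is_assigned(g, genome_orfs)]
    if not values:
        raise ValueError(
            f"reaction {reaction.reaction_id}: no assigned enzyme group")
    return max(values)


# ---------------------------------------------------------------------------
# Pathway calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayCall:
    bin_id: str
    pathway_id: str
    present: bool
    completeness: float
    key_ok: bool
    pathway_rpkm: float         # NaN when no reaction is assigned
    rel_pathway_expr: float     # NaN when median undefined or rpkm NaN
    n_assigned_reactions: int


def _genome_orfs(expr: ExpressionTable, bin_id: str) -> set[str]:
    df = expr.data
    return set(df.loc[df["bin_id"] == bin_id, "orf_id"])


def pathway_call(
    pathway: PathwayDefinition,
    bin_id: str,
    expr: ExpressionTable,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
    unassigned_as_zero: bool = False,
) -> PathwayCall:
    """Call pathway presence and expression for one genome.

    present = (every key reaction assigned) AND (completeness >= threshold);
    pathway RPKM averages reaction RPKMs over assigned reactions, or over
    all reactions with unassigned ones as zero when ``unassigned_as_zero``.
    Relative pathway expression divides by the genome's median ORF RPKM.
    """
    if not 0 < completeness_threshold <= 1:
        raise ValueError("completeness_threshold must be in (0, 1]")
    genome_orfs = _genome_orfs(expr, bin_id)
    orf_rpkm = expr.orf_rpkm()

    assigned = [r for r in pathway.reactions
                if any(group_is_assigned(g, genome_orfs) for g in r.enzymes)]
    key_ok = all(
        any(group_is_assigned(g, genome_orfs) for g in r.enzymes)
        for r in pathway.reactions if r.is_key)
    completeness = len(assigned) / len(pathway.reactions)
    present = key_ok and completeness >= completeness_threshold

    if assigned:
        values = [reaction_rpkm(r, orf_rpkm, genome_orfs) for r in assigned]
        if unassigned_as_zero:
            values += [0.0] * (len(pathway.reactions) - len(assigned))
        p_rpkm = float(np.mean(values))
    else:
        p_rpkm = float("nan")

    median = expr.genome_median_rpkm.get(bin_id, float("nan"))
    rel = p_rpkm / median if (median and median > 0) else float("nan")
    return PathwayCall(
        bin_id=bin_id, pathway_id=pathway.pathway_id, present=present,
        completeness=completeness, key_ok=key_ok, pathway_rpkm=p_rpkm,
        rel_pathway_expr=rel, n_assigned_reactions=len(assigned))


def call_all_pathways(
    pathways: Sequence[PathwayDefinition],
    bins: Sequence[GenomeBin],
    expr: ExpressionTable,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
    unassigned_as_zero: bool = False,
) -> pd.DataFrame:
    """Tidy bin x pathway call table."""
    rows = []
    for b in bins:
        for p in pathways:
            c = pathway_call(p, b.bin_id, expr,
                             completeness_threshold=completeness_threshold,
                             unassigned_as_zero=unassigned_as_zero)
            rows.append(vars(c) if not hasattr(c, "__dataclass_fields__")
                        else {f: getattr(c, f)
                              for f in c.__dataclass_fields__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Denitrification marker profile
# ---------------------------------------------------------------------------

#: Denitrification / DNRA steps with their marker-gene alternatives.
#: Each alternative is (marker code, aggregation kind): a 'complex' code's
#: annotated ORFs are subunits (min), a 'single' code's are copies (max);
#: alternatives within a step are isozymes (max).
DENITRIFICATION_STEPS: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
    ("NO3->NO2", (("narGHIJ", "complex"), ("napABCGH", "complex"))),
    ("NO2->NH4", (("nrfHA", "complex"),)),
    ("NO2->NO", (("nirK", "single"), ("nirS", "single"))),
    ("NO->N2O", (("norBC", "complex"), ("norZ", "single"))),
    ("N2O->N2", (("nosZ", "single"),)),
)


def denitrification_profile(
    bins: Sequence[GenomeBin],
    annotations: pd.DataFrame,
    expr: ExpressionTable,
) -> pd.DataFrame:
    """Per-genome presence/expression of nitrogen-reduction steps.

    Columns: bin_id, step, present, step_rpkm, log2_step_rpkm,
    zero_subunit_flag. ``zero_subunit_flag`` marks a present step one of
    whose complex subunits has zero counts (e.g. narI unexpressed while
    narGH are), in which case the complex contributes RPKM 0 by the min
    rule. log2 is NaN at step RPKM 0 — no pseudocount is applied.
    """
    markers = annotations[annotations["namespace"] == "marker"]
    orf_rpkm = expr.orf_rpkm()
    orf_count = expr.orf_count()
    rows = []
    for b in bins:
        genome_orfs = _genome_orfs(expr, b.bin_id)
        code_members: dict[str, list[str]] = {}
        for row in markers.itertuples():
            if row.orf_id in genome_orfs:
                code_members.setdefault(row.family_code, []).append(row.orf_id)
        for step, alternatives in DENITRIFICATION_STEPS:
            values = []
            zero_subunit = False
            for code, kind in alternatives:
                members = code_members.get(code, [])
                if not members:
                    continue
                vals = [orf_rpkm[m] for m in members]
                if kind == "complex":
                    values.append(min(vals))
                    if any(orf_count[m] == 0 for m in members):
                        zero_subunit = True
                else:
                    values.append(max(vals))
            present = bool(values)
            step_rpkm = max(values) if values else float("nan")
            log2_rpkm = (math.log2(step_rpkm)
                         if present and step_rpkm > 0 else float("nan"))
            rows.append({
                "bin_id": b.bin_id, "step": step, "present": present,
                "step_rpkm": step_rpkm, "log2_step_rpkm": log2_rpkm,
                "zero_subunit_flag": present and zero_subunit,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Amino-acid biosynthesis / degradation and biosynthetic cost
# ---------------------------------------------------------------------------

def aa_pathway_id(amino_acid: str, direction: str) -> str:
    """Conventional pathway id for an amino-acid pathway, e.g.
    ``Val_biosynthesis`` / ``Val_degradation``."""
    if direction not in ("biosynthesis", "degradation"):
        raise ValueError("direction must be biosynthesis|degradation")
    return f"{amino_acid}_{direction}"


def amino_acid_matrix(
    pathway_calls: pd.DataFrame,
    cost_table: CostTable,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """20 x 2 amino-acid pathway matrix per genome, plus cost association.

    ``pathway_calls`` is the tidy output of :func:`call_all_pathways`
    restricted (by pathway id convention) to amino-acid pathways. Returns

    * a matrix frame (bin_id, amino_acid, cost_rank, direction, present,
      rel_pathway_expr, auxotroph) where auxotroph marks genomes whose
      biosynthesis pathway for that amino acid is absent, and
    * per-genome statistics (bin_id, n_degraded, rank_sum, p_value): a
      two-sided permutation rank-sum test asking whether the cost ranks of
      amino acids *with* a degradation pathway differ from a random draw of
      ranks — low mean rank-sum (remember rank 1 = most costly) means the
      genome degrades preferentially cheap amino acids.
    """
    calls = pathway_calls.set_index(["bin_id", "pathway_id"])
    rng = np.random.default_rng(seed)
    ranks = np.array([cost_table.rank(aa) for aa in AMINO_ACIDS], dtype=float)

    matrix_rows = []
    stat_rows = []
    for bin_id in sorted(pathway_calls["bin_id"].unique()):
        degraded = np.zeros(len(AMINO_ACIDS), dtype=bool)
        for i, aa in enumerate(AMINO_ACIDS):
            for direction in ("biosynthesis", "degradation"):
                pid = aa_pathway_id(aa, direction)
                try:
                    row = calls.loc[(bin_id, pid)]
                except KeyError:
                    present, rel = False, float("nan")
                else:
                    present = bool(row["present"])
                    rel = float(row["rel_pathway_expr"]) if present else float("nan")
                if direction == "degradation" and present:
                    degraded[i] = True
                matrix_rows.append({
                    "bin_id": bin_id, "amino_acid": aa,
                    "cost_rank": int(ranks[i]), "direction": direction,
                    "present": present, "rel_pathway_expr": rel,
                })
            bio_present = matrix_rows[-2]["present"]  # biosynthesis row
            matrix_rows[-2]["auxotroph"] = not bio_present
            matrix_rows[-1]["auxotroph"] = not bio_present

        n_deg = int(degraded.sum())
        if 0 < n_deg < len(AMINO_ACIDS):
            observed = float(ranks[degraded].sum())
            null = np.empty(n_permutations)
            for j in range(n_permutations):
                null[j] = rng.permutation(ranks)[:n_deg].sum()
            center = null.mean()
            p = float(np.mean(np.abs(null - center)
                              >= abs(observed - center)))
        else:
            observed, p = float("nan"), float("nan")
        stat_rows.append({"bin_id": bin_id, "n_degraded": n_deg,
                          "rank_sum": observed, "p_value": p})
    return pd.DataFrame(matrix_rows), pd.DataFrame(stat_rows)


# ---------------------------------------------------------------------------
# Functional family inventories (peptidases, hydrolases, transporters)
# ---------------------------------------------------------------------------

def functional_family_profile(
    bins: Sequence[GenomeBin],
    annotations: pd.DataFrame,
    expr: ExpressionTable,
    namespaces: Sequence[str] = ("peptidase", "glycoside_hydrolase",
                                 "transporter"),
) -> pd.DataFrame:
    """Per-genome family inventories stratified by subcellular location.

    One row per (bin, namespace, family_code, location) with the member ORF
    count and mean relative expression; families with no members in a
    genome yield no row.
    """
    expr_df = expr.data[["orf_id", "bin_id", "rel_expr"]]
    ann = annotations[annotations["namespace"].isin(namespaces)]
    merged = ann.merge(expr_df, on="orf_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["bin_id", "namespace", "family_code",
                                     "location", "n_orfs", "mean_rel_expr"])
    out = (merged
           .groupby(["bin_id", "namespace", "family_code", "location"],
                    as_index=False)
           .agg(n_orfs=("orf_id", "size"),
                mean_rel_expr=("rel_expr", "mean")))
    return out.sort_values(["bin_id", "namespace", "family_code",
                            "location"]).reset_index(drop=True)
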