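"""Domain types and file I/O for genome-resolved metatranscriptomics.

The pipeline consumes the outputs of an upstream assembly/binning/annotation
workflow: binned contigs (FASTA + a contig->bin assignment table), predicted
ORFs (GFF3 CDS features), read alignments (text SAM, single-end merged
reads), and plain-TSV side tables (pathway definitions, functional family
annotations, amino-acid biosynthetic-cost ranks).

Coordinate convention: GFF3 is 1-based inclusive on disk; everything in
memory is 0-based half-open, converted only at the I/O boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

logger = logging.getLogger("magtx")

#: Pool id for contigs present in the FASTA but absent from the assignment
#: table; they still receive reads but belong to no genome bin.
UNBINNED = "unbinned"

#: Minimum ORF length in nucleotides; shorter CDS records are dropped with a
#: warning (matches the upstream gene caller's minimum).
MIN_ORF_LENGTH_BP = 60

#: Default minimum alignment identity for read filtering (species-level ANI
#: threshold used by the upstream mapper).
DEFAULT_MIN_IDENTITY = 0.95

VALID_LOCATIONS = frozenset(
    {"extracellular", "outer_membrane", "periplasm", "cytoplasmic",
     "inner_membrane", "unknown"}
)
VALID_NAMESPACES = frozenset(
    {"peptidase", "glycoside_hydrolase", "transporter", "marker"}
)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBin:
    """A metagenome-assembled genome (MAG): its contigs and ORF roster."""

    bin_id: str
    taxonomy: str
    contigs: tuple[tuple[str, int], ...]  # (contig_id, length_bp)
    orf_ids: tuple[str, ...] = ()

    @property
    def total_length_bp(self) -> int:
        return sum(length for _, length in self.contigs)

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.contigs)


@dataclass(frozen=True)
class OrfFeature:
    """A located ORF. ``start``/``end`` are 0-based half-open on the contig."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    families: tuple[tuple[str, str], ...] = ()  # (namespace, family_code)
    location: str = "unknown"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise DataError(
                f"ORF {self.orf_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise DataError(f"ORF {self.orf_id}: strand must be '+' or '-'")
        if self.location not in VALID_LOCATIONS:
            raise DataError(f"ORF {self.orf_id}: bad location {self.location!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned single-end read.

    ``aligned_blocks`` are half-open reference intervals covered by the
    alignment (sorted, non-overlapping, non-empty). ``identity_fraction`` is
    1 - edit_distance / aligned_read_length, where aligned_read_length
    excludes soft-clipped bases; an explicit per-record identity (``XI`` tag)
    overrides the edit-distance computation when present.
    """

    read_id: str
    contig_id: str
    pos: int
    aligned_blocks: tuple[tuple[int, int], ...]
    read_strand: str
    identity_fraction: float
    n_best_hits: int = 1

    def __post_init__(self) -> None:
        if not self.aligned_blocks:
            raise DataError(f"read {self.read_id}: no aligned blocks")
        prev_end = -1
        for s, e in self.aligned_blocks:
            if not (0 <= s < e) or s < prev_end:
                raise DataError(
                    f"read {self.read_id}: blocks must be sorted, "
                    f"non-overlapping, non-empty")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.aligned_blocks[0][0], self.aligned_blocks[-1][1]


@dataclass(frozen=True)
class EnzymeGroup:
    """One enzyme catalysing a reaction: a single gene or a multi-subunit
    complex. Alternative groups within a reaction are isozymes."""

    kind: str  # 'single' or 'complex'
    member_orf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("single", "complex"):
            raise DataError(f"enzyme group kind must be single|complex, "
                            f"got {self.kind!r}")
        if not self.member_orf_ids:
            raise DataError("enzyme group with no members")


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    is_key: bool
    enzymes: tuple[EnzymeGroup, ...]


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise DataError(f"pathway {self.pathway_id}: no reactions")


#: 3-letter amino-acid codes, alphabetical.
AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)


@dataclass(frozen=True)
class CostTable:
    """Biosynthetic cost ranks for the 20 amino acids (1 = most costly)."""

    ranks: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.ranks) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.ranks)
            extra = set(self.ranks) - set(AMINO_ACIDS)
            raise DataError(
                f"cost table must cover exactly the 20 amino acids "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})")
        if sorted(self.ranks.values()) != list(range(1, 21)):
            raise DataError("cost ranks must be a permutation of 1..20")

    def rank(self, amino_acid: str) -> int:
        try:
            return self.ranks[amino_acid]
        except KeyError:
            raise DataError(f"amino acid {amino_acid!r} missing from cost table")


# ---------------------------------------------------------------------------
# Genomes: FASTA + bin assignment table
# ---------------------------------------------------------------------------

def read_genome_bins(
    fasta_paths: str | Path | Sequence[str | Path],
    bin_table_path: str | Path,
    taxonomy: dict[str, str] | None = None,
) -> list[GenomeBin]:
    """Read binned contigs: FASTA file(s) plus a contig->bin TSV.

    Contigs present in the FASTA but absent from the table fall into the
    ``unbinned`` pool. A contig assigned to two bins, or a table contig
    missing from the FASTA, is a hard error.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    contig_lengths: dict[str, int] = {}
    for fp in fasta_paths:
        for rec in SeqIO.parse(str(fp), "fasta"):
            if rec.id in contig_lengths:
                raise DataError(f"duplicate contig {rec.id!r} in FASTA input")
            contig_lengths[rec.id] = len(rec.seq)

    table = pd.read_csv(bin_table_path, sep="\t", dtype=str)
    _require_columns(table, ["contig_id", "bin_id"], bin_table_path)
    dup = table["contig_id"][table["contig_id"].duplicated()]
    if not dup.empty:
        raise DataError(
            f"contig(s) assigned to more than one bin: {sorted(set(dup))}")

    assignment: dict[str, str] = {}
    for contig_id, bin_id in zip(table["contig_id"], table["bin_id"]):
        if contig_id not in contig_lengths:
            raise DataError(
                f"contig {contig_id!r} in bin table but not in FASTA input")
        assignment[contig_id] = bin_id

    by_bin: dict[str, list[tuple[str, int]]] = {}
    for contig_id, length in contig_lengths.items():
        bin_id = assignment.get(contig_id, UNBINNED)
        by_bin.setdefault(bin_id, []).append((contig_id, length))

    taxonomy = taxonomy or {}
    return [
        GenomeBin(bin_id=bin_id, taxonomy=taxonomy.get(bin_id, ""),
                  contigs=tuple(sorted(contigs)))
        for bin_id, contigs in sorted(by_bin.items())
    ]


def write_bin_assignment(bins: Iterable[GenomeBin], path: str | Path) -> None:
    """Write the contig->bin assignment TSV (unbinned pool omitted)."""
    rows = [
        {"contig_id": cid, "bin_id": b.bin_id}
        for b in bins if b.bin_id != UNBINNED
        for cid in b.contig_ids
    ]
    pd.DataFrame(rows, columns=["contig_id", "bin_id"]).to_csv(
        path, sep="\t", index=False)


def contig_to_bin(bins: Iterable[GenomeBin]) -> dict[str, str]:
    """Flatten bins to a contig->bin_id map, checking the partition property."""
    mapping: dict[str, str] = {}
    for b in bins:
        for cid in b.contig_ids:
            if cid in mapping:
                raise DataError(f"contig {cid!r} appears in bins "
                                f"{mapping[cid]!r} and {b.bin_id!r}")
            mapping[cid] = b.bin_id
    return mapping


# ---------------------------------------------------------------------------
# ORFs: GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    genome_bins: Sequence[GenomeBin] | None = None,
    min_length_bp: int = MIN_ORF_LENGTH_BP,
) -> list[OrfFeature]:
    """Read CDS features from GFF3 into 0-based half-open ORFs.

    CDS shorter than ``min_length_bp`` are excluded with a warning. A CDS on
    a contig unknown to ``genome_bins`` (when given) is a hard error.
    Overlapping CDS are retained; overlap is resolved at counting time.
    """
    known_contigs: set[str] | None = None
    if genome_bins is not None:
        known_contigs = {cid for b in genome_bins for cid in b.contig_ids}

    orfs: list[OrfFeature] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "CDS":
            continue
        if known_contigs is not None and feat.seqid not in known_contigs:
            raise DataError(
                f"CDS on unknown contig {feat.seqid!r} in {path}")
        orf_id = feat.attributes.get("ID", [None])[0]
        if orf_id is None:
            raise DataError(f"CDS without ID attribute in {path}")
        start = feat.start - 1  # GFF 1-based inclusive -> 0-based half-open
        end = feat.end
        if end - start < min_length_bp:
            warnings.warn(
                f"excluding ORF {orf_id}: length {end - start} nt < "
                f"{min_length_bp} nt minimum", stacklevel=2)
            continue
        product = feat.attributes.get("product", [""])[0]
        orfs.append(OrfFeature(orf_id=orf_id, contig_id=feat.seqid,
                               start=start, end=end, strand=feat.strand,
                               product=product))
    orfs.sort(key=lambda o: (o.contig_id, o.start, o.orf_id))
    return orfs


def write_gff3(orfs: Iterable[OrfFeature], path: str | Path,
               source: str = "magtx") -> None:
    """Write ORFs as GFF3 CDS features (internal coords back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in sorted(orfs, key=lambda o: (o.contig_id, o.start, o.orf_id)):
            attrs = f"ID={o.orf_id}"
            if o.product:
                attrs += f";product={o.product}"
            fh.write("\t".join([
                o.contig_id, source, "CDS", str(o.start + 1), str(o.end),
                ".", o.strand, "0", attrs]) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write contig sequences to FASTA."""
    records = [SeqRecord(Seq(seq), id=cid, description="")
               for cid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments: SAM
# ---------------------------------------------------------------------------

@dataclass
class SamFilterStats:
    """Bookkeeping for records dropped before counting."""

    n_records: int = 0
    n_unmapped: int = 0
    n_filtered_identity: int = 0
    n_missing_identity: int = 0
    n_passed: int = 0


# CIGAR op codes consuming the reference
_REF_CONSUMING_MATCH = {0, 7, 8}  # M, =, X
_REF_CONSUMING_GAP = {2, 3}       # D, N


def _blocks_from_cigar(pos: int, cigartuples, deletions_covered: bool
                       ) -> tuple[tuple[int, int], ...]:
    blocks: list[list[int]] = []
    ref = pos
    open_block = False
    for op, length in cigartuples:
        if op in _REF_CONSUMING_MATCH:
            if open_block and blocks[-1][1] == ref:
                blocks[-1][1] = ref + length
            else:
                blocks.append([ref, ref + length])
                open_block = True
            ref += length
        elif op in _REF_CONSUMING_GAP:
            if deletions_covered and open_block and blocks[-1][1] == ref:
                # deletion/skip treated as covered: extend the footprint
                blocks[-1][1] = ref + length
            else:
                open_block = False
            ref += length
        # I, S, H, P consume no reference
    return tuple((s, e) for s, e in blocks)


def read_sam_subset(
    path: str | Path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    missing_identity: str = "drop",
    deletions_covered: bool = True,
    stats: SamFilterStats | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a text SAM file, filtering by identity.

    Identity is 1 - NM / aligned_read_length (soft clips excluded from the
    denominator); an explicit ``XI:f`` tag overrides it. Records without
    either are dropped (``missing_identity='drop'``, with a warning) or
    accepted (``'accept'``). Unmapped records are dropped and counted.

    With ``deletions_covered`` (default) reference positions spanned by
    deletion/skip operations are part of the aligned footprint, so a gapped
    alignment has one contiguous block; prokaryotic ORFs are unspliced, so
    this is the appropriate default for intersection-strict counting.
    """
    if missing_identity not in ("drop", "accept"):
        raise ValueError("missing_identity must be 'drop' or 'accept'")
    if stats is None:
        stats = SamFilterStats()
    warned_missing = False
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            stats.n_records += 1
            if rec.is_unmapped:
                # htslib demotes records whose RNAME is absent from the
                # header to unmapped but leaves their CIGAR intact; a truly
                # unmapped record carries no CIGAR.
                if rec.cigarstring is not None:
                    raise DataError(
                        f"read {rec.query_name}: reference contig absent "
                        f"from SAM header in {path}")
                stats.n_unmapped += 1
                continue
            if rec.has_tag("XI"):
                identity = float(rec.get_tag("XI"))
            elif rec.has_tag("NM"):
                aligned_len = rec.query_alignment_length
                identity = 1.0 - rec.get_tag("NM") / aligned_len
            else:
                stats.n_missing_identity += 1
                if missing_identity == "drop":
                    if not warned_missing:
                        warnings.warn(
                            f"dropping record(s) without NM/XI identity "
                            f"information in {path}", stacklevel=2)
                        warned_missing = True
                    continue
                identity = 1.0
            if identity < min_identity:
                stats.n_filtered_identity += 1
                continue
            blocks = _blocks_from_cigar(
                rec.reference_start, rec.cigartuples, deletions_covered)
            if not blocks:
                stats.n_unmapped += 1
                continue
            n_best = rec.get_tag("NH") if rec.has_tag("NH") else 1
            stats.n_passed += 1
            yield AlignmentRecord(
                read_id=rec.query_name,
                contig_id=rec.reference_name,
                pos=rec.reference_start,
                aligned_blocks=blocks,
                read_strand="-" if rec.is_reverse else "+",
                identity_fraction=identity,
                n_best_hits=n_best,
            )


# ---------------------------------------------------------------------------
# Side tables: pathways, annotations, cost ranks
# ---------------------------------------------------------------------------

def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read pathway definitions from TSV.

    Columns: pathway_id, pathway_name, reaction_id, is_key (0/1),
    group_kind (single|complex), members (comma-separated ORF ids). One row
    per enzyme group; rows sharing a reaction_id are isozyme alternatives.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        df, ["pathway_id", "pathway_name", "reaction_id", "is_key",
             "group_kind", "members"], path)
    pathways: list[PathwayDefinition] = []
    for (pid, pname), pgroup in df.groupby(["pathway_id", "pathway_name"],
                                           sort=False):
        reactions = []
        for rid, rgroup in pgroup.groupby("reaction_id", sort=False):
            keys = set(rgroup["is_key"].astype(int))
            if len(keys) != 1:
                raise DataError(
                    f"reaction {rid}: inconsistent is_key flags")
            groups = tuple(
                EnzymeGroup(kind=row.group_kind,
                            member_orf_ids=tuple(row.members.split(",")))
                for row in rgroup.itertuples()
            )
            reactions.append(
                Reaction(reaction_id=rid, is_key=bool(keys.pop()),
                         enzymes=groups))
        pathways.append(PathwayDefinition(pathway_id=pid, name=pname,
                                          reactions=tuple(reactions)))
    if not pathways:
        raise DataError(f"no pathway rows in {path}")
    return pathways


def write_pathway_definitions(pathways: Iterable[PathwayDefinition],
                              path: str | Path) -> None:
    rows = [
        {"pathway_id": p.pathway_id, "pathway_name": p.name,
         "reaction_id": r.reaction_id, "is_key": int(r.is_key),
         "group_kind": g.kind, "members": ",".join(g.member_orf_ids)}
        for p in pathways for r in p.reactions for g in r.enzymes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read functional annotations: orf_id, namespace, family_code, location.

    Unknown location labels map to 'unknown' with a warning; unknown
    namespaces are a hard error (they select aggregation semantics).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["orf_id", "namespace", "family_code", "location"],
                     path)
    bad_ns = set(df["namespace"]) - VALID_NAMESPACES
    if bad_ns:
        raise DataError(f"unknown annotation namespace(s): {sorted(bad_ns)}")
    bad_loc = set(df["location"]) - VALID_LOCATIONS
    if bad_loc:
        warnings.warn(f"unknown location label(s) {sorted(bad_loc)} mapped "
                      f"to 'unknown'", stacklevel=2)
        df.loc[df["location"].isin(bad_loc), "location"] = "unknown"
    return df


def apply_annotations(orfs: Sequence[OrfFeature],
                      annotations: pd.DataFrame) -> list[OrfFeature]:
    """Attach family tags and subcellular locations to ORFs."""
    fams: dict[str, list[tuple[str, str]]] = {}
    locs: dict[str, str] = {}
    for row in annotations.itertuples():
        fams.setdefault(row.orf_id, []).append((row.namespace, row.family_code))
        locs[row.orf_id] = row.location
    return [
        replace(o, families=tuple(fams.get(o.orf_id, ())),
                location=locs.get(o.orf_id, o.location))
        for o in orfs
    ]


def read_cost_table(path: str | Path) -> CostTable:
    """Read amino-acid cost ranks: columns amino_acid, cost_rank."""
    df = pd.read_csv(path, sep="\t", dtype={"amino_acid": str,
                                            "cost_rank": int})
    _require_columns(df, ["amino_acid", "cost_rank"], path)
    return CostTable(ranks=dict(zip(df["amino_acid"], df["cost_rank"])))


def write_cost_table(table: CostTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.ranks.items()), columns=["amino_acid", "cost_rank"]
    ).to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str],
                     path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
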