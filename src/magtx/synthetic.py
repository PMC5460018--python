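"""Synthetic granule communities with known ground truth.

Generates multi-genome communities in exactly the formats the pipeline
consumes (FASTA, GFF3, SAM, TSV side tables) together with truth tables,
so that every downstream stage — counting, normalization, community
profiling, pathway calling — can be validated by parameter recovery
without any external data.

Statistical model:

* community composition ~ Dirichlet(concentration) over genomes;
* within-genome transcript levels ~ log-normal(mu, sigma) per ORF;
* read counts ~ Poisson; DNA expected reads on a region are proportional
  to abundance x region length, RNA expected reads on an ORF to
  abundance x ORF length x transcript level, with a configurable
  noise fraction of RNA reads falling on intergenic sequence;
* emitted reads are fixed-length (shorter only when their source region
  is shorter), error-free, perfect-identity and fully inside their source
  region, so intersection-strict counting recovers the truth exactly.

All randomness derives from a single integer seed through fixed
substreams (genomes / composition / expression / DNA counts / RNA
counts), so identical seeds give byte-identical outputs and any library
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import CountTable
from .model_io import (
    AMINO_ACIDS,
    CostTable,
    DataError,
    EnzymeGroup,
    GenomeBin,
    OrfFeature,
    PathwayDefinition,
    Reaction,
    write_bin_assignment,
    write_cost_table,
    write_fasta,
    write_gff3,
    write_pathway_definitions,
)
from .pathways import aa_pathway_id

# substream indices for the seed-splitting scheme
_STREAM_GENOMES = 0
_STREAM_COMPOSITION = 1
_STREAM_EXPRESSION = 2
_STREAM_DNA = 3
_STREAM_RNA = 4
_STREAM_PATHWAYS = 5
_STREAM_ANNOTATIONS = 6
_STREAM_COST = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(stream,)))


@dataclass(frozen=True)
class GenomeSpec:
    bin_id: str
    n_contigs: int
    total_length_bp: int
    n_orfs: int


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for the synthetic community.

    Defaults: five genomes spanning 0.5-4 Mb (the size range of draft
    genomes binned from granular-sludge communities), flat Dirichlet
    composition, log-normal(0, 1) transcript levels, 5% intergenic RNA
    noise, 125 bp error-free reads.
    """

    genomes: tuple[GenomeSpec, ...] = (
        GenomeSpec("G1", 3, 4_000_000, 2600),
        GenomeSpec("G2", 2, 3_000_000, 2000),
        GenomeSpec("G3", 2, 2_400_000, 1600),
        GenomeSpec("G4", 1, 1_600_000, 1100),
        GenomeSpec("G5", 1, 500_000, 340),
    )
    dirichlet_concentration: float = 1.0
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    noise_fraction: float = 0.05
    dna_depth: int = 2_000_000
    rna_depth: int = 2_000_000
    read_length: int = 125
    orf_shape: float = 2.0   # Gamma shape for ORF length (codons)
    orf_scale: float = 150.0  # Gamma scale for ORF length (codons)


@dataclass
class CommunityTruth:
    """Ground truth for one simulated community."""

    seed: int
    spec: CommunitySpec
    bins: list[GenomeBin]
    orfs: list[OrfFeature]
    sequences: dict[str, str]
    abundance: dict[str, float]       # bin_id -> simplex weight
    expression: dict[str, float]      # orf_id -> relative transcript level

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-12:
            raise DataError(f"true abundance sums to {total}, not 1")
        if any(v <= 0 for v in self.expression.values()):
            raise DataError("all true expression values must be positive")


# ---------------------------------------------------------------------------
# Genomes and ORFs
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _orf_lengths(rng: np.random.Generator, n: int, shape: float,
                 scale: float) -> np.ndarray:
    """ORF lengths in nt: 3 x Gamma(shape, scale) codons, floored at 60."""
    codons = np.maximum(rng.gamma(shape, scale, size=n).round().astype(int),
                        20)
    return 3 * codons


def _place_orfs(rng: np.random.Generator, contig_len: int,
                lengths: Sequence[int]) -> list[int]:
    """Non-overlapping uniform placement via a random partition of slack."""
    slack = contig_len - sum(lengths)
    if slack < 0:
        raise DataError(
            f"cannot pack {len(lengths)} ORFs totalling {sum(lengths)} nt "
            f"into a {contig_len} nt contig")
    gaps = rng.multinomial(slack, np.ones(len(lengths) + 1)
                           / (len(lengths) + 1))
    starts = []
    pos = 0
    for gap, length in zip(gaps, lengths):
        pos += gap
        starts.append(pos)
        pos += length
    return starts


def simulate_genomes(
    spec: CommunitySpec, seed: int, max_retries: int = 10,
) -> tuple[list[GenomeBin], list[OrfFeature], dict[str, str]]:
    """Simulate binned genomes with non-overlapping ORFs.

    Deterministic for a fixed seed. ORF lengths are redrawn up to
    ``max_retries`` times per contig if they do not fit; persistent
    infeasibility is an error.
    """
    rng = _rng(seed, _STREAM_GENOMES)
    bins: list[GenomeBin] = []
    orfs: list[OrfFeature] = []
    sequences: dict[str, str] = {}
    for g in spec.genomes:
        # split genome into contigs (roughly equal with random jitter)
        props = rng.dirichlet(np.full(g.n_contigs, 10.0))
        contig_lens = np.maximum((props * g.total_length_bp).astype(int), 1)
        contig_lens[-1] += g.total_length_bp - contig_lens.sum()
        contigs = []
        orf_alloc = np.diff(np.round(
            np.cumsum(contig_lens) / g.total_length_bp * g.n_orfs
        ).astype(int), prepend=0)
        orf_serial = 0
        for ci, (clen, n_orfs_here) in enumerate(zip(contig_lens, orf_alloc),
                                                 start=1):
            contig_id = f"{g.bin_id}_c{ci}"
            contigs.append((contig_id, int(clen)))
            sequences[contig_id] = _random_sequence(rng, int(clen))
            if n_orfs_here == 0:
                continue
            for attempt in range(max_retries):
                lengths = _orf_lengths(rng, int(n_orfs_here), spec.orf_shape,
                                       spec.orf_scale)
                if lengths.sum() <= clen:
                    break
            else:
                raise DataError(
                    f"{contig_id}: could not place {n_orfs_here} ORFs in "
                    f"{clen} nt after {max_retries} retries")
            starts = _place_orfs(rng, int(clen), lengths.tolist())
            for start, length in zip(starts, lengths):
                orf_serial += 1
                orfs.append(OrfFeature(
                    orf_id=f"{g.bin_id}_{orf_serial:05d}",
                    contig_id=contig_id,
                    start=int(start), end=int(start + length),
                    strand="+" if rng.random() < 0.5 else "-",
                ))
        bins.append(GenomeBin(
            bin_id=g.bin_id, taxonomy="synthetic",
            contigs=tuple(contigs),
            orf_ids=tuple(o.orf_id for o in orfs
                          if o.contig_id.startswith(g.bin_id + "_c"))))
    return bins, orfs, sequences


def simulate_composition(n_genomes: int, concentration: float,
                         seed: int) -> np.ndarray:
    """Dirichlet community composition on the simplex."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = _rng(seed, _STREAM_COMPOSITION)
    draw = rng.dirichlet(np.full(n_genomes, concentration))
    return draw / draw.sum()  # exact simplex (Dirichlet sums to ~1 in fp)


def simulate_community(spec: CommunitySpec, seed: int) -> CommunityTruth:
    """Full community truth: genomes + composition + transcript levels."""
    bins, orfs, sequences = simulate_genomes(spec, seed)
    abundance_vec = simulate_composition(
        len(spec.genomes), spec.dirichlet_concentration, seed)
    abundance = {b.bin_id: float(a) for b, a in zip(bins, abundance_vec)}
    rng = _rng(seed, _STREAM_EXPRESSION)
    expression = {
        o.orf_id: float(rng.lognormal(spec.expression_mu,
                                      spec.expression_sigma))
        for o in orfs
    }
    return CommunityTruth(seed=seed, spec=spec, bins=bins, orfs=orfs,
                          sequences=sequences, abundance=abundance,
                          expression=expression)


# ---------------------------------------------------------------------------
# Read counts and SAM emission
# ---------------------------------------------------------------------------

def _regions(truth: CommunityTruth) -> pd.DataFrame:
    """Partition every contig into ORF regions and intergenic gaps."""
    contig_bin = {cid: b.bin_id for b in truth.bins for cid in b.contig_ids}
    contig_len = {cid: length for b in truth.bins
                  for cid, length in b.contigs}
    by_contig: dict[str, list[OrfFeature]] = {}
    for o in truth.orfs:
        by_contig.setdefault(o.contig_id, []).append(o)
    rows = []
    for cid, length in contig_len.items():
        pos = 0
        for o in sorted(by_contig.get(cid, []), key=lambda o: o.start):
            if o.start > pos:
                rows.append((contig_bin[cid], cid, pos, o.start, "", "+"))
            rows.append((contig_bin[cid], cid, o.start, o.end, o.orf_id,
                         o.strand))
            pos = o.end
        if pos < length:
            rows.append((contig_bin[cid], cid, pos, length, "", "+"))
    return pd.DataFrame(rows, columns=["bin_id", "contig_id", "start", "end",
                                       "orf_id", "strand"])


def simulate_counts(
    truth: CommunityTruth,
    library: str,
    sam_path: str | Path | None = None,
) -> pd.DataFrame:
    """Draw Poisson read counts per region for one library.

    ``library`` is ``'dna'`` (expected reads proportional to
    abundance x region length over the whole genome) or ``'rna'``
    (abundance x length x transcript level over ORFs, plus a
    ``noise_fraction`` share of reads on intergenic sequence). Returns the
    truth count table (columns bin_id, contig_id, start, end, orf_id — ""
    for intergenic — strand, count). When ``sam_path`` is given, each
    counted read is emitted as a perfect-identity single-block SAM record
    fully inside its source region.
    """
    if library not in ("dna", "rna"):
        raise ValueError("library must be 'dna' or 'rna'")
    spec = truth.spec
    regions = _regions(truth)
    ab = regions["bin_id"].map(truth.abundance).to_numpy()
    length = (regions["end"] - regions["start"]).to_numpy()
    is_orf = (regions["orf_id"] != "").to_numpy()

    if library == "dna":
        weights = ab * length
        lam = spec.dna_depth * weights / weights.sum()
        rng = _rng(truth.seed, _STREAM_DNA)
    else:
        expr = regions["orf_id"].map(truth.expression).fillna(0.0).to_numpy()
        if not np.any(expr[is_orf] > 0):
            raise DataError("RNA library with all transcript levels zero")
        w_orf = np.where(is_orf, ab * length * expr, 0.0)
        w_noise = np.where(~is_orf, ab * length, 0.0)
        lam = np.zeros(len(regions))
        lam += (1 - spec.noise_fraction) * spec.rna_depth \
            * w_orf / w_orf.sum()
        if spec.noise_fraction > 0 and w_noise.sum() > 0:
            lam += spec.noise_fraction * spec.rna_depth \
                * w_noise / w_noise.sum()
        rng = _rng(truth.seed, _STREAM_RNA)

    counts = rng.poisson(lam)
    out = regions.copy()
    out["count"] = counts
    if sam_path is not None:
        _emit_sam(truth, out, library, Path(sam_path), rng)
    return out


def _emit_sam(truth: CommunityTruth, counts: pd.DataFrame, library: str,
              path: Path, rng: np.random.Generator) -> None:
    """Write one perfect-identity single-block record per counted read.

    RNA reads from ORF regions are on the ORF strand (strand-specific
    protocol); DNA and intergenic reads get a random strand.
    """
    contig_len = {cid: length for b in truth.bins
                  for cid, length in b.contigs}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid in sorted(contig_len):
            fh.write(f"@SQ\tSN:{cid}\tLN:{contig_len[cid]}\n")
        serial = 0
        for row in counts.itertuples():
            if row.count == 0:
                continue
            region_len = row.end - row.start
            rlen = min(truth.spec.read_length, region_len)
            starts = row.start + rng.integers(
                0, region_len - rlen + 1, size=row.count)
            seq_full = truth.sequences[row.contig_id]
            stranded = library == "rna" and row.orf_id != ""
            for s in np.sort(starts):
                serial += 1
                if stranded:
                    reverse = row.strand == "-"
                else:
                    reverse = rng.random() < 0.5
                flag = 16 if reverse else 0
                fh.write("\t".join([
                    f"{library}_read_{serial:08d}", str(flag),
                    row.contig_id, str(s + 1), "44", f"{rlen}M", "*", "0",
                    "0", seq_full[s:s + rlen], "*", "NM:i:0"]) + "\n")


def counts_to_table(counts: pd.DataFrame, truth: CommunityTruth,
                    library_id: str) -> CountTable:
    """Convert a truth count table to a :class:`CountTable` directly
    (bypassing SAM emission and read assignment)."""
    feature = (counts[counts["orf_id"] != ""]
               .groupby("orf_id")["count"].sum().to_dict())
    genome = counts.groupby("bin_id")["count"].sum().to_dict()
    table = CountTable(library_id=library_id)
    table.feature_counts = {o.orf_id: int(feature.get(o.orf_id, 0))
                            for o in truth.orfs}
    table.genome_counts = {b.bin_id: int(genome.get(b.bin_id, 0))
                           for b in truth.bins}
    table.n_assigned = sum(table.feature_counts.values())
    table.n_no_feature = int(counts.loc[counts["orf_id"] == "",
                                        "count"].sum())
    table.library_size = table.n_assigned + table.n_no_feature
    return table


# ---------------------------------------------------------------------------
# Pathway truth
# ---------------------------------------------------------------------------

PATHWAY_TRUTH_CLASSES = ("complete", "missing_non_key", "missing_key",
                         "absent")


def simulate_pathways(
    truth: CommunityTruth,
    n_pathways: int = 8,
    seed: int | None = None,
    completeness_threshold: float = 0.75,
) -> tuple[list[PathwayDefinition], pd.DataFrame]:
    """Random pathways plus per-genome presence truth.

    Each pathway has 2-8 reactions, ~30% flagged key (at least one key and
    one non-key). Each genome independently holds a complete, missing one
    non-key reaction, missing one key reaction, or absent gene set; the
    truth table records the class, the resulting completeness and the
    expected presence call at ``completeness_threshold``. Enzyme groups are
    singles or 2-3-subunit complexes over the genome's own ORFs.
    """
    rng = _rng(truth.seed if seed is None else seed, _STREAM_PATHWAYS)
    orfs_by_bin: dict[str, list[str]] = {
        b.bin_id: list(b.orf_ids) for b in truth.bins}
    pathways: list[PathwayDefinition] = []
    truth_rows = []
    for p in range(1, n_pathways + 1):
        pid = f"pwy{p:03d}"
        n_rxn = int(rng.integers(2, 9))
        is_key = rng.random(n_rxn) < 0.3
        if not is_key.any():
            is_key[0] = True
        if is_key.all():
            is_key[-1] = False
        reactions_members: list[list[EnzymeGroup]] = [[] for _ in range(n_rxn)]
        for b in truth.bins:
            cls = PATHWAY_TRUTH_CLASSES[int(rng.integers(0, 4))]
            if cls == "complete":
                held = np.ones(n_rxn, dtype=bool)
            elif cls == "missing_non_key":
                held = np.ones(n_rxn, dtype=bool)
                non_key = np.flatnonzero(~is_key)
                held[rng.choice(non_key)] = False
            elif cls == "missing_key":
                held = np.ones(n_rxn, dtype=bool)
                held[rng.choice(np.flatnonzero(is_key))] = False
            else:
                held = np.zeros(n_rxn, dtype=bool)
            pool = orfs_by_bin[b.bin_id]
            for ri in np.flatnonzero(held):
                n_groups = int(rng.integers(1, 3))
                for _ in range(n_groups):
                    if rng.random() < 0.5:
                        members = tuple(rng.choice(pool, size=1))
                        kind = "single"
                    else:
                        members = tuple(rng.choice(
                            pool, size=int(rng.integers(2, 4)),
                            replace=False))
                        kind = "complex"
                    reactions_members[ri].append(
                        EnzymeGroup(kind=kind, member_orf_ids=members))
            completeness = held.sum() / n_rxn
            key_ok = bool(held[is_key].all())
            truth_rows.append({
                "bin_id": b.bin_id, "pathway_id": pid, "class": cls,
                "completeness_truth": completeness, "key_ok_truth": key_ok,
                "present_truth": key_ok and
                completeness >= completeness_threshold,
            })
        reactions = tuple(
            Reaction(reaction_id=f"{pid}_r{ri + 1}", is_key=bool(is_key[ri]),
                     enzymes=tuple(groups) if groups else (
                         # keep empty reactions representable: a group of a
                         # non-existent ORF never resolves in any genome
                         EnzymeGroup(kind="single",
                                     member_orf_ids=(f"{pid}_r{ri+1}_none",)),))
            for ri, groups in enumerate(reactions_members)
        )
        pathways.append(PathwayDefinition(pathway_id=pid, name=f"pathway {p}",
                                          reactions=reactions))
    return pathways, pd.DataFrame(truth_rows)


def simulate_aa_pathways(
    truth: CommunityTruth, seed: int | None = None,
    p_biosynthesis: float = 0.8, p_degradation: float = 0.5,
) -> tuple[list[PathwayDefinition], pd.DataFrame]:
    """Amino-acid biosynthesis/degradation pathways with presence truth.

    Each genome holds each direction's pathway independently (biosynthesis
    more often than degradation, loosely like real communities where most
    genomes synthesize more amino acids than they catabolize). Held
    pathways are complete two-reaction chains over the genome's ORFs.
    """
    rng = _rng(truth.seed if seed is None else seed, _STREAM_PATHWAYS + 100)
    truth_rows = []
    pathways = []
    for aa in AMINO_ACIDS:
        for direction, p_hold in (("biosynthesis", p_biosynthesis),
                                  ("degradation", p_degradation)):
            pid = aa_pathway_id(aa, direction)
            groups_per_reaction: list[list[EnzymeGroup]] = [[], []]
            for b in truth.bins:
                held = bool(rng.random() < p_hold)
                truth_rows.append({"bin_id": b.bin_id, "amino_acid": aa,
                                   "direction": direction, "present": held})
                if held:
                    pool = list(b.orf_ids)
                    for ri in range(2):
                        groups_per_reaction[ri].append(EnzymeGroup(
                            kind="single",
                            member_orf_ids=tuple(rng.choice(pool, size=1))))
            reactions = tuple(
                Reaction(reaction_id=f"{pid}_r{ri + 1}", is_key=(ri == 0),
                         enzymes=tuple(groups) if groups else (
                             EnzymeGroup(kind="single",
                                         member_orf_ids=(f"{pid}_none",)),))
                for ri, groups in enumerate(groups_per_reaction)
            )
            pathways.append(PathwayDefinition(
                pathway_id=pid, name=f"{aa} {direction}",
                reactions=reactions))
    return pathways, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Annotations and cost table
# ---------------------------------------------------------------------------

_MARKER_CODES = {
    "narGHIJ": 4, "napABCGH": 5, "nrfHA": 2, "nirK": 1, "nirS": 1,
    "norBC": 2, "norZ": 1, "nosZ": 1,
}
_FAMILY_CODES = {
    "peptidase": ("S08A", "S01C", "M23B", "M16A", "C26"),
    "glycoside_hydrolase": ("GH13", "GH3", "GH16", "GH2", "GH109"),
    "transporter": ("2.A.3", "3.A.1", "2.A.1", "1.B.14"),
}
_LOCATIONS = ("extracellular", "outer_membrane", "periplasm", "cytoplasmic",
              "inner_membrane")


def simulate_annotations(
    truth: CommunityTruth, seed: int | None = None,
    marker_prob: float = 0.6, n_family_orfs: int = 30,
) -> pd.DataFrame:
    """Random marker-gene and family annotations over the community's ORFs.

    Each genome carries each denitrification marker group with probability
    ``marker_prob`` (subunit count per the gene cluster), plus
    ``n_family_orfs`` ORFs annotated to peptidase / glycoside-hydrolase /
    transporter families with random subcellular locations.
    """
    rng = _rng(truth.seed if seed is None else seed, _STREAM_ANNOTATIONS)
    rows = []
    for b in truth.bins:
        pool = list(b.orf_ids)
        rng.shuffle(pool)
        cursor = 0
        for code, n_sub in _MARKER_CODES.items():
            if rng.random() < marker_prob and cursor + n_sub <= len(pool):
                for orf_id in pool[cursor:cursor + n_sub]:
                    rows.append({"orf_id": orf_id, "namespace": "marker",
                                 "family_code": code,
                                 "location": "cytoplasmic"})
                cursor += n_sub
        for _ in range(min(n_family_orfs, len(pool) - cursor)):
            orf_id = pool[cursor]
            cursor += 1
            ns = rng.choice(list(_FAMILY_CODES))
            rows.append({
                "orf_id": orf_id, "namespace": ns,
                "family_code": str(rng.choice(_FAMILY_CODES[ns])),
                "location": str(rng.choice(_LOCATIONS)),
            })
    return pd.DataFrame(rows, columns=["orf_id", "namespace", "family_code",
                                       "location"])


def simulate_cost_table(seed: int) -> CostTable:
    """A random cost-rank permutation (synthetic stand-in for published
    biosynthetic-cost rankings, which are user input in real analyses)."""
    rng = _rng(seed, _STREAM_COST)
    perm = rng.permutation(20) + 1
    return CostTable(ranks={aa: int(r) for aa, r in zip(AMINO_ACIDS, perm)})


# ---------------------------------------------------------------------------
# Emission to disk
# ---------------------------------------------------------------------------

def emit_community(truth: CommunityTruth, outdir: str | Path,
                   write_sam: bool = True) -> dict[str, Path]:
    """Write the community in pipeline input formats plus truth tables.

    Emits genomes.fasta, orfs.gff3, bins.tsv, pathways.tsv, annotations.tsv,
    cost.tsv, truth_* tables and (optionally) dna.sam / rna.sam.
    Deterministic given the truth's seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genomes.fasta"
    write_fasta(truth.sequences, paths["fasta"])
    paths["gff"] = outdir / "orfs.gff3"
    write_gff3(truth.orfs, paths["gff"])
    paths["bins"] = outdir / "bins.tsv"
    write_bin_assignment(truth.bins, paths["bins"])

    pathway_defs, pathway_truth = simulate_pathways(truth)
    aa_defs, aa_truth = simulate_aa_pathways(truth)
    paths["pathways"] = outdir / "pathways.tsv"
    write_pathway_definitions(pathway_defs + aa_defs, paths["pathways"])
    paths["truth_pathways"] = outdir / "truth_pathways.tsv"
    pathway_truth.to_csv(paths["truth_pathways"], sep="\t", index=False)
    paths["truth_aa_pathways"] = outdir / "truth_aa_pathways.tsv"
    aa_truth.to_csv(paths["truth_aa_pathways"], sep="\t", index=False)

    paths["annotations"] = outdir / "annotations.tsv"
    simulate_annotations(truth).to_csv(paths["annotations"], sep="\t",
                                       index=False)
    paths["cost"] = outdir / "cost.tsv"
    write_cost_table(simulate_cost_table(truth.seed), paths["cost"])

    abundance = pd.DataFrame(sorted(truth.abundance.items()),
                             columns=["bin_id", "abundance"])
    paths["truth_abundance"] = outdir / "truth_abundance.tsv"
    abundance.to_csv(paths["truth_abundance"], sep="\t", index=False)
    expr = pd.DataFrame(sorted(truth.expression.items()),
                        columns=["orf_id", "expression"])
    paths["truth_expression"] = outdir / "truth_expression.tsv"
    expr.to_csv(paths["truth_expression"], sep="\t", index=False)

    for lib in ("dna", "rna"):
        sam = outdir / f"{lib}.sam" if write_sam else None
        counts = simulate_counts(truth, lib, sam_path=sam)
        paths[f"truth_counts_{lib}"] = outdir / f"truth_counts_{lib}.tsv"
        counts.to_csv(paths[f"truth_counts_{lib}"], sep="\t", index=False)
        if sam is not None:
            paths[f"sam_{lib}"] = sam
    return paths
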