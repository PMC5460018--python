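"""Shared fixtures: tiny synthetic communities and hand-built tables."""

from __future__ import annotations

import numpy as np
import pytest

from magtx.counting import CountTable
from magtx.expression import expression_table
from magtx.model_io import AlignmentRecord, GenomeBin, OrfFeature
from magtx.synthetic import CommunitySpec, GenomeSpec, simulate_community


@pytest.fixture(scope="session")
def tiny_spec() -> CommunitySpec:
    """Two small genomes, zero noise — fast enough for per-test runs."""
    return CommunitySpec(
        genomes=(GenomeSpec("G1", 2, 60_000, 40),
                 GenomeSpec("G2", 1, 40_000, 25)),
        noise_fraction=0.0,
        dna_depth=8_000,
        rna_depth=8_000,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return simulate_community(tiny_spec, seed=11)


def build_expression(bin_rpkms: dict[str, list[float]],
                     orf_length: int = 1000, library_size: int = 1_000_000):
    """Expression table from chosen per-genome RPKM values.

    With ORFs of 1 kb and a library of 1e6 mapped reads, RPKM equals the
    read count, so integer RPKM targets are realized exactly.
    """
    bins, orfs = [], []
    counts = CountTable(library_id="rna")
    counts.library_size = library_size
    for bin_id, rpkms in bin_rpkms.items():
        contig_id = f"{bin_id}_c1"
        pos = 0
        orf_ids = []
        for i, value in enumerate(rpkms):
            orf_id = f"{bin_id}_{i + 1:03d}"
            orfs.append(OrfFeature(orf_id=orf_id, contig_id=contig_id,
                                   start=pos, end=pos + orf_length,
                                   strand="+"))
            count = value * library_size * orf_length / 1e9
            assert count == int(count), "choose RPKMs realizable as counts"
            counts.feature_counts[orf_id] = int(count)
            orf_ids.append(orf_id)
            pos += orf_length + 10
        bins.append(GenomeBin(bin_id=bin_id, taxonomy="",
                              contigs=((contig_id, pos + 1000),),
                              orf_ids=tuple(orf_ids)))
        counts.genome_counts[bin_id] = sum(
            counts.feature_counts[o] for o in orf_ids)
    counts.n_assigned = sum(counts.feature_counts.values())
    return bins, orfs, expression_table(counts, bins, orfs)


def random_assignment_instance(rng: np.random.Generator):
    """A random (read, ORF layout) pair on a 300 bp contig.

    Coordinates are drawn from a small grid so overlaps, shared boundaries
    and off-by-one cases are common.
    """
    orfs = []
    for i in range(rng.integers(0, 5)):
        start = int(rng.integers(0, 220))
        length = int(rng.integers(60, 81))
        orfs.append(OrfFeature(
            orf_id=f"o{i}", contig_id="c", start=start,
            end=min(start + length, 300),
            strand="+" if rng.random() < 0.5 else "-"))
    blocks = []
    pos = int(rng.integers(0, 200))
    for _ in range(rng.integers(1, 4)):
        length = int(rng.integers(5, 40))
        end = min(pos + length, 300)
        if end <= pos:
            break
        blocks.append((pos, end))
        pos = end + int(rng.integers(1, 15))
    if not blocks:
        blocks = [(0, 30)]
    record = AlignmentRecord(
        read_id="r", contig_id="c", pos=blocks[0][0],
        aligned_blocks=tuple(blocks),
        read_strand="+" if rng.random() < 0.5 else "-",
        identity_fraction=1.0)
    stranded = ("yes", "no", "reverse")[rng.integers(0, 3)]
    return record, orfs, stranded
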