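# magtx

Genome-resolved metatranscriptomics for granular microbial communities.

Anammox (anaerobic ammonium oxidation) granules are dense consortia of
anammox bacteria and heterotrophs whose interactions — nitrate recycling to
nitrite, degradation of extracellular polymeric substances (EPS), amino-acid
and B-vitamin exchange — can be read out by mapping DNA and mRNA reads onto
metagenome-assembled genomes (MAGs). `magtx` implements that readout as a
reusable, tested pipeline: it consumes binned genomes (FASTA + contig→bin
table), predicted ORFs (GFF3), read alignments (text SAM) and plain-TSV
annotation/pathway tables, and produces per-ORF, per-genome and per-pathway
expression profiles. A synthetic-community simulator with known ground
truth makes every stage verifiable without sequencing data.

## The quantities it computes

For ORF *i* with read count *c<sub>i</sub>* and length *L<sub>i</sub>* (bp)
in a library of *N* mapped reads:

- **RPKM**: RPKM<sub>i</sub> = 10⁹ · c<sub>i</sub> / (N · L<sub>i</sub>) —
  count normalized by sequencing depth and ORF length.
- **Relative expression**: RPKM<sub>i</sub> / median(RPKM over *all* ORFs of
  the genome, zero-count ORFs included). A value of 1 is median expression;
  the median is undefined (flagged, never imputed) when at least half the
  genome is silent.
- **Genome abundance/expression**: reads mapped to a MAG divided by its
  genome length (read density), reported as each MAG's fraction of the
  summed densities — relative abundance from the DNA library, relative
  expression from the mRNA library.
- **Pathway expression**: mean of reaction-level RPKMs, where a
  multi-subunit enzyme complex (e.g. hydrazine synthase *hzsABC*) takes the
  **minimum** over its subunits and isozymes/multi-copy genes take the
  **maximum** over alternatives. A pathway is *present* when every key
  reaction has an assigned enzyme and the fraction of assigned reactions
  meets a completeness threshold (default 0.75).
- **Counting** is intersection-strict: a read is assigned to an ORF only if
  every aligned base lies inside it and no base implicates a second ORF;
  ambiguous and non-coding reads still count toward genome totals.
  Alignments are pre-filtered at 95% identity by default.

Downstream profiles reproduce the standard figure panels of a
genome-resolved study: a denitrification step matrix (nar/nap, nrf,
nirK/nirS, norBC/norZ, nosZ — with a flag for complexes whose subunit is
silent), peptidase/glycoside-hydrolase/transporter inventories stratified
by subcellular location, and amino-acid biosynthesis/degradation calls with
auxotrophy detection and a permutation rank-sum test linking degradation
repertoires to biosynthetic cost ranks.

## Worked example

Simulate a two-genome community (an anammox-like and a heterotroph-like
genome, zero intergenic noise, 50k reads per library), profile it, and rank
the most expressed ORFs:

```python
from magtx import (CommunitySpec, GenomeSpec, simulate_community,
                   simulate_counts, counts_to_table, community_profile,
                   expression_table, top_expressed)

spec = CommunitySpec(
    genomes=(GenomeSpec("AMX", 2, 60_000, 40),
             GenomeSpec("CHB", 1, 40_000, 25)),
    noise_fraction=0.0, dna_depth=50_000, rna_depth=50_000)
truth = simulate_community(spec, seed=11)

dna = counts_to_table(simulate_counts(truth, "dna"), truth, "dna")
rna = counts_to_table(simulate_counts(truth, "rna"), truth, "rna")

abundance = community_profile(dna, truth.bins)
expression = community_profile(rna, truth.bins)
for b in ("AMX", "CHB"):
    print(f"{b}: true={truth.abundance[b]:.3f} "
          f"abundance={abundance.fraction[b]:.3f} "
          f"expression={expression.fraction[b]:.3f}")

expr = expression_table(rna, truth.bins, truth.orfs)
print(top_expressed(expr, "AMX", 3)[["orf_id", "rpkm", "rel_expr"]]
      .to_string(index=False))
```

Output:

```
AMX: true=0.446 abundance=0.439 expression=0.489
CHB: true=0.554 abundance=0.561 expression=0.511
   orf_id         rpkm  rel_expr
AMX_00031 74519.285526  6.771196
AMX_00017 69658.209597  6.329495
AMX_00011 51006.527351  4.634709
```

The length-normalized read densities recover the simulated Dirichlet
composition (`true`) to within sampling noise, and the top-ranked ORFs are
those the simulator assigned the highest transcript levels — `rel_expr`
reads as fold-change over the genome's median ORF (6.8× median for the
top hit).

The same analysis runs from the shell:

```sh
magtx simulate --seed 3 --outdir sim
magtx run --config cfg.yaml        # count → expr → community → pathways →
                                   # denitro → aa-matrix → families
magtx summarize --outdir out
```

`magtx run` writes tidy TSVs plus `manifest.json` (input/output SHA-256
checksums, config, seed, version); identical config and inputs give
byte-identical outputs.

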