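# Methods

## Scope and data model

`magtx` quantifies gene expression across a community of binned genomes
(MAGs). It deliberately starts *after* assembly, binning, ORF calling and
database annotation: those steps are consumed as files (FASTA, contig→bin
TSV, GFF3 CDS features, SAM alignments, annotation/pathway/cost TSVs), and
the pipeline owns everything from read-to-ORF assignment onwards.

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive convention is converted exactly once at the I/O boundary, and the
conversion is self-inverse (a 60 nt CDS at GFF 11..70 becomes [10, 70) and
writes back as 11..70). CDS under 60 nt are excluded with a warning,
mirroring the minimum ORF length of the upstream gene caller.

## Alignment filtering

Only single-end text SAM is supported; paired reads are expected to be
merged upstream. Records are filtered at a minimum alignment identity
(default 0.95, the species-level ANI criterion commonly used for read
mapping). SAM does not standardize identity, so it is computed as
1 − NM / aligned_read_length, where the denominator excludes soft-clipped
bases; an explicit `XI:f` tag overrides this when a mapper provides its own
definition. Records with neither tag are dropped with a warning (or
accepted by flag). A record whose reference name is absent from the header
is a hard error — htslib demotes such records to unmapped but leaves the
CIGAR intact, which is how they are distinguished from genuinely unmapped
reads.

Reference positions spanned by deletion (and skip) CIGAR operations are
treated as covered by default, giving each alignment a single contiguous
genomic footprint. Prokaryotic ORFs are unspliced, so a read bridging a
small deletion inside an ORF should still be attributable to it; the
alternative per-block semantics is available via `deletions_covered=False`.
Upstream multi-mapping resolution ("one random best location per read") is
assumed; a record advertising multiple best hits is used at its recorded
location, since the record carries no alternative placement to re-draw.

## Intersection-strict counting

For each aligned position the set of strand-compatible ORFs covering it is
formed, and the sets are intersected across all positions of all blocks:
exactly one survivor → assigned; none → no_feature; several → ambiguous.
The indexed implementation exploits the equivalence that the surviving
ORFs are those containing every block in full (interval-tree containment
query), and is validated against a literal per-base oracle on randomized
instances. Ambiguous and no_feature reads are excluded from feature counts
but still tallied against their contig's bin, so genome totals include
intergenic transcription and coverage. Assigned + no_feature + ambiguous
partition the identity-passing mapped records; this is asserted.

The RNA library is counted strand-specifically by default (the protocol is
stranded); the DNA library is unstranded. The RPKM denominator
(`library_size`) defaults to all identity-passing mapped reads —
sequencing-depth normalization at the mapping level — with
feature-assigned-only as a configurable alternative.

## Expression

RPKM = 10⁹ · count / (library_size · ORF length in bp). Relative expression
divides each ORF's RPKM by the median RPKM over **all** predicted ORFs of
its genome, zero-count ORFs included — the literal reading of a
genome-wide median, and the conservative one (excluding silent ORFs would
inflate the denominator's robustness artificially). Even ORF counts use
the mean of the two middle values. When a genome's median is 0 (at least
half its ORFs silent), relative expression is flagged undefined for that
genome; no pseudocounts are used anywhere, zeros propagate.

Genome-level abundance (DNA) and expression (RNA) are read densities —
mapped reads on the bin's contigs divided by bin length — reported as
fractions of the summed densities over the included bins. The unbinned
pool can be included or excluded by flag; both framings are meaningful
(community fractions over recovered genomes vs. share of the whole
assembly).

## Pathway aggregation and presence

Gene → reaction → pathway aggregation uses: minimum over the subunits of a
multi-gene enzyme complex (a complex is only as expressed as its scarcest
subunit), maximum over isozymes/multi-copy genes (the reaction runs on the
most-expressed alternative), arithmetic mean over a pathway's reactions.
Reactions with no assigned enzyme group are excluded from the mean rather
than zero-filled — a reaction-level RPKM only exists where genes do — with
zero-fill exposed as a flag for sensitivity analysis. Because the genome
median is a single positive constant, relativizing before or after any of
these min/max/mean steps is mathematically identical; values are
relativized after aggregation.

Presence requires all key reactions assigned *and* completeness (fraction
of reactions with ≥1 assigned group) ≥ a threshold. The threshold defaults
to 0.75: rule-based pathway inference engines apply curated per-pathway
rules that a flat cutoff can only approximate, and 0.75 tolerates one
missing reaction in a four-reaction pathway while rejecting half-empty
reconstructions. An enzyme group resolves in a genome only if **all** its
members are that genome's ORFs, so one shared definition table serves a
multi-genome community.

The denitrification profile applies the same rules to marker-gene
annotations (namespace `marker`): nitrate reduction via the nar complex or
the periplasmic nap complex, DNRA via nrfHA, nitrite reduction via
nirK/nirS isozymes, NO reduction via the norBC complex or norZ, N₂O
reduction via nosZ. A present step whose complex has a zero-count subunit
is flagged (`zero_subunit_flag`) — by the min rule its RPKM is 0 and its
log2 is reported as NaN, not pseudocounted.

Amino-acid pathways follow the id convention `<AAA>_biosynthesis` /
`<AAA>_degradation` (three-letter codes). An absent biosynthesis pathway is
an auxotrophy call. The cost-association statistic is the sum of
biosynthetic-cost ranks (1 = most costly; ranks are an input table, a
permutation of 1..20) over amino acids with a degradation pathway, tested
two-sided against a permutation null that reassigns which ranks are
degraded (default 10,000 permutations, seeded, reproducible). Genomes
degrading none or all amino acids get an undefined p-value.

## Synthetic communities

The simulator emulates the statistical structure the estimators assume:

- genomes of differing sizes split into contigs, with non-overlapping ORFs
  whose lengths are 3 × round(Gamma(shape 2, scale 150)) nt (mean ≈ 900 nt,
  floored at 60) placed by a uniform random partition of the intergenic
  slack;
- community composition ~ Dirichlet(concentration 1.0 by default) over
  five genomes of 0.5–4 Mb, the genome-size range typical of draft MAGs
  from granular sludge;
- per-ORF transcript levels ~ log-normal(μ=0, σ=1);
- Poisson counts: DNA expected reads on a region ∝ abundance × region
  length (so intergenic DNA coverage arises naturally and no separate DNA
  noise term is needed); RNA expected reads on an ORF ∝ abundance × length
  × transcript level, with a `noise_fraction` (default 0.05) of RNA reads
  placed on intergenic sequence in proportion to abundance × length;
- emitted reads are fixed-length (125 bp, the HiSeq read length; shorter
  only when the source region is shorter), error-free, perfect-identity,
  single-block, and fully inside their source region, so
  intersection-strict counting recovers the truth table *exactly* — the
  end-to-end identity oracle used throughout the tests. Intergenic truth
  counts are recorded too, so emitted SAM reads always equal the truth
  total.

All randomness flows from one integer seed through fixed named substreams
(genomes, composition, expression, DNA counts, RNA counts, pathways,
annotations, cost table), so identical seeds give byte-identical outputs
and any library can be regenerated independently.

What the simulator does **not** model: sequencing errors and quality
scores, strain-level variation, GC/coverage biases, chimeric assembly or
binning contamination, operonic correlation of expression. Passing
recovery tests therefore demonstrates the correctness of the estimators
under their own assumptions, not robustness to real-data artifacts —
identity filtering, for instance, is exercised with separately constructed
degraded records rather than simulated errors.

Pathway truth uses four per-(genome, pathway) classes — complete, missing
one non-key reaction, missing one key reaction, absent — with expected
completeness and the presence call at threshold 0.75 recorded at
generation time, making recovery checks exact for every class.

## Test problem sizes

Unit and acceptance tests run on small communities (two genomes of
30–60 kb, thousands of reads) where the identity oracle is exact, plus the
default five-genome community at 2×10⁶ DNA reads for abundance recovery
(20 replicate seeds, direct count-table path). The randomized
assignment-oracle comparison uses 10,000 instances on a 300 bp grid where
boundary and overlap collisions are frequent. These sizes were chosen so
the full suite illustrates each property at comfortable statistical power
while remaining quick to run routinely.

## Process-performance arithmetic

Total nitrogen across a stage boundary is the sum of ammonia, nitrite and
nitrate (all mg N/l); stage removal is 1 − TN_effluent/TN_influent. The
package ships the steady-state measurements of the two-stage
partial-nitritation/anammox reactor it was developed around; across its
anammox stage these give 85.8% total-nitrogen removal, consistent with the
>80% operating regime the biomass was sampled in.

## Known limitations

- BAM/CRAM, paired-end records and spliced (eukaryotic) features are out
  of scope by design.
- Multi-mapper reallocation is upstream's responsibility; no fractional or
  EM reassignment is performed.
- Pathway presence with a flat completeness threshold approximates, but
  does not reproduce, curated rule-based inference.
- Between-sample normalization (TPM, DESeq-style size factors) is not
  provided: the design targets a single time point, where within-genome
  median relativization is the appropriate scale.
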