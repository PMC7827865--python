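# Methods

This note documents the models and procedures implemented in `plastiddr`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and the record model

All coordinates are 0-based half-open on a circular genome; GenBank's
1-based inclusive convention exists only at the I/O boundary. An interval
may wrap the replication origin (`start > end`); a feature crossing the
origin is stored as a single wrapping exon rather than two joined exons,
so exon count minus one is always the intron count. Exon lists are kept
in transcription order (for minus-strand genes the genomically-last exon
comes first), which makes splicing, codon extraction and CDS-to-genome
coordinate mapping uniform across all strand/wrap combinations.
Ambiguity codes other than N are rejected at construction: the editing
survey needs unambiguous C/T calls, and silently degrading them would
corrupt edit ratios downstream. Pseudogene status on input comes from
`/pseudo`-type qualifiers or from a `gene` feature lacking any typed
child feature.

## Large-repeat detection and orientation

The repeat pair is found by exact k-mer seeding (k = 21) of the circular
sequence against itself (direct candidates share a diagonal, the constant
circular offset between copies) and against its reverse complement
(inverted candidates share an anti-diagonal, the constant sum of paired
positions). K-mers occurring more than 10 times are dropped as
low-complexity. Co-linear seeds closer than 100 bp are merged, bridging
isolated substitutions between near-identical copies; runs shorter than
half the minimum repeat length are discarded before extension. Extension
is ungapped and mismatch-tolerant: a mismatch is crossed only when at
least 16 of the following 20 bases match, which distinguishes the
diverged repeat interior (≥ 98% identity at the default divergence
ceiling) from the random flank, where about a quarter of bases match by
chance; the reported boundary never ends on a mismatch. The longest
candidate whose copies do not overlap and whose identity is at least
1 − `max_divergence` wins; ties break to the smaller start coordinate.

Defaults: `min_len` 5,000 bp and `max_divergence` 0.02. Deposited
lycophyte repeats run 7,308–16,531 bp and are near-identical, so these
settings catch all of them while excluding small dispersed repeats.
The genome without any qualifying pair returns `None` — for this genome
class that is a finding (repeat loss), not a failure. Boundaries of a
*maximal* repeat can exceed a planted repeat by a few bases when flank
positions match by chance (expected ≈ 1/3 base per edge); callers
comparing against planted truth should allow one seed length.

The quadripartite partition names the inter-repeat arc containing the
marker genes psbA, rbcL and rpoB as the LSC. Length cannot be the primary
rule because most *Selaginella* SSCs are longer than their LSCs; the
marker set is this package's own operational rule, and `label_basis`
records when the length fallback was used instead. Reported coordinates
can be canonicalized by rotating the LSC start to zero.

Junction-amplicon prediction tests a DR or IR hypothesis *in silico*: if
the observed orientation differs from the hypothesis, repeat copy B is
reverse-complemented in place, then each primer pair amplifies iff one
primer binds the plus strand upstream of the other on the minus strand
(3′ ends converging) within the maximum product size (default 5,000 bp,
matching short-product junction PCR design). `design_junction_primers`
builds the canonical six-primer layout in which four combinations span
the DR junctions and two span the hypothetical IR junctions; on a DR
genome the first four amplify and the last two do not, and inverting one
repeat copy swaps the pattern.

## Inversion model

`apply_inversion` reverse-complements the spanned block: inside features
get mirrored coordinates and flipped strands, the exon list order is
preserved (which keeps transcription order correct on the new strand),
and applying the same event twice restores the input byte for byte. A
span boundary inside an intact feature is an error, because real block
inversions in this genome class have intergenic breakpoints; an explicit
`allow_split` clips the feature into pseudogene fragments instead.

`infer_inversion` is deliberately restricted to the single-inversion
hypothesis: each architectural transition in the genus is explained by
one block inversion per lineage, and importing a general
sorting-by-reversals solver would add failure modes without adding
relevant power. Comparison is restricted to genes present exactly once in
both maps (repeat-duplicated rRNAs are uninformative for order, and gene
loss belongs to the content survey). All rotations of the second map and
both reading directions are tried; a candidate requires the mismatching
genes to form one contiguous circular block equal to the strand-flipped
reversal of its counterpart. Shortest span wins. When no single inversion
explains the orders, the call honestly reports the minimal breakpoint
block count (computed on the forward reading; flipped-reading block
counts are not comparable) instead of forcing an answer. Breakpoints are
reported as flanking gene names, not base-precise positions: intergenic
breakpoints are not observable from gene order alone.

## Content survey

Pseudogene classification is annotation-first, sequence-second: a
deposited `/pseudo` flag is trusted; otherwise a protein gene is a
pseudogene when its spliced CDS length is not a multiple of three or its
translation under NCBI table 11 (bacterial/plastid) contains an internal
stop. An editable ACG start is *not* evidence of decay and never triggers
pseudogene status. Gene names are normalized through a small shipped
synonym table plus a tRNA rule (anticodon suffixes dropped, one-letter
amino-acid codes upper-cased, `trnfM` preserved) before any matrix or
count is built.

Category counts come in both conventions used for this genome class:
distinct gene names, and per-copy totals where each repeat-duplicated
gene adds its extra copies (the "parenthetical" convention). The shipped
19-plastome compendium satisfies `once + duplicates = per-copy total` on
every row, and the package reports both so either convention can be
compared. GC is computed over the whole circle with N excluded from the
denominator; fractions are reported to 2 decimals and grouped means to 1
decimal, matching the precision of the reference values. Note the
compendium's 16 *Selaginella* totals average 132,957.8 bp; a published
summary gives 132,571 ± 11,612 for the same rows, a discrepancy this
package surfaces rather than reproduces.

The intron survey runs over the 19 canonical intron-containing plastid
genes (13 protein-coding, 6 tRNA; clpP and ycf3 carry two introns each,
all others one). Intron *i* is present iff an annotated copy has at least
i + 1 exons; genes missing or pseudogenized score `gene-missing`, since
their exon structure is not trustworthy.

## Editing survey and confirmation

Start codons classify as normal (ATG), abnormal (ACG — one C-to-U event
yields AUG) or other (e.g. GTG); stops as normal (TAA/TAG/TGA), abnormal
(CAA/CAG/CGA — one event yields a stop) or other. Pseudogenes are
excluded by default because their reading frames are unreliable
(configurable), and repeat-duplicated copies are surveyed once. The
edited C within an abnormal codon is fixed by the chemistry and
hard-coded: codon position 2 for starts, position 1 for stops.

Pileup confirmation takes per-site base counts on the feature's coding
strand (read bases complemented for minus-strand genes — C-to-U editing
is defined on the transcript). A site is confirmed when depth ≥
`min_depth` (default 10) and T/(C+T) ≥ `min_ratio` (default 0.10). The
source data for this survey show edit ratios either near zero or well
above 0.5, so the thresholds are deliberately permissive; both are
configurable and echoed in output headers, and raw counts are always
reported so any stricter rule can be applied post hoc. Uncovered sites
are reported unconfirmed with reason `no coverage`.

The built-in read placer (`simple_map`) is a deliberately simple
unique-31-mer voting mapper, ungapped and circular-aware, sufficient for
reads simulated from the reference itself; ambiguous and unseeded reads
are discarded and counted. Real RNA-seq should come in as SAM/BAM from a
real aligner via `read_alignments` (pysam; text SAM works, no index
needed), which checks reference name and length against the record.

## Pairwise diversity

Two genomes pre-rotated to a comparable origin are aligned by chaining
shared unique 31-mers (longest increasing subsequence on anchor
positions) and closing inter-anchor segments with a global gapped
alignment (match 1, mismatch −2, gap open −5, gap extend −2). Large
repeat copies contain no genome-wide unique k-mers, so oversized
segments are re-anchored with k-mers unique within the segment and
closed recursively; segments above 20 kb that resist anchoring are
reported unaligned and excluded from all tallies. An anchor chain
covering less than half of either sequence raises an explicit
"not collinear" error directing the user to gene-order comparison —
counting point variants across a rearrangement would be meaningless.

A SNP is an aligned column with two distinct unambiguous bases; an InDel
*event* is one maximal contiguous gap run regardless of length (a 7-bp
gap is one event), with gapped bases accumulated separately; columns
involving N are excluded from every count. The event-based InDel unit is
a counting dialect, stated in output headers. Repeat-region columns
count once per genomic position, i.e. the duplicated repeat contributes
twice across the genome, as it does in genome coordinates.

## Synthetic data

The generator builds the circle as LSC | RepA | SSC | RepB, with RepB a
verbatim copy (direct) or reverse complement (inverted) of RepA. rRNA
genes live inside the repeats and are therefore duplicated, as in every
deposited lycophyte plastome; markers psbA/rbcL/rpoB always land in the
LSC; the SSC is made longer than the LSC, the architecture typical of the
genus. Defaults emulate the deposited *Selaginella* envelope: 130 kb
genome, 12 kb repeat in direct orientation, GC target 0.53, 56 protein
genes with 77% ACG starts, 10% abnormal stops, 20% two-exon genes. Gene
bodies are random non-stop codons between the chosen start and stop —
content and editing surveys are annotation- and codon-driven, so real
homolog sequences would add nothing the surveys could detect. Planted
pseudogenes carry an internal TAA at the CDS midpoint while staying
annotated intact, exercising the sequence-based detection path.

Fractions are realized as Bernoulli draws per gene by default, so the
realized count varies with the seed. An `exact_fractions` mode plants
exactly `round(fraction × n)` genes instead, for reproducing a study
condition stated as a realized count (e.g. 43 of 56 starts ACG).

`mutate` plants SNPs and InDels (≤ 50 bp) at positions separated by a
configurable minimum (default 100 bp; ~80 bp is needed to fit the
largest published intraspecific load, 1218 SNPs + 113 InDels, on a
126 kb genome) and remaps feature coordinates through the InDels, so a
frameshifting InDel inside a CDS yields a detectable pseudogene. Read
simulation samples uniformly over each gene's genomic span with a
read-length margin at both ends (so terminal codons get full coverage,
as they do in real transcripts with UTRs); at a planted site each read
carries the edited base with probability equal to the site efficiency,
then independent substitution errors are applied.

What the generator does *not* emulate — and therefore what passing
planted-truth tests do not establish about real data: sequencing-platform
error profiles (no homopolymer or quality-decay model), transcript
abundance variation (uniform per gene), spliced-read alignment (reads are
pre-mRNA-like, never spanning an intron junction), annotation errors, and
homology-detectable gene remnants (pseudogene calling on real genomes
additionally relies on homology search, which is out of scope here).

## Problem sizes and determinism

Every stochastic component takes an explicit seed and a single PCG64
stream per dataset; identical configs give byte-identical FASTA, GenBank
and FASTQ output, and the end-to-end pipeline is byte-deterministic on
fixed inputs. The test suite and the acceptance script run planted-truth
properties at moderate scale as the package's own verification design:
100 seeded genomes (repeats 5–20 kb) for repeat recovery, 100 seeded read
simulations at depth 100 for editing recovery and false-confirmation
rates, and one 126 kb pair at the published 1218/113 variant load.

## Known limitations

- One repeat family only: the detector reports the single longest pair;
  small dispersed repeats are out of scope.
- Single-inversion inference only; two or more overlapping events are
  reported as such, not resolved.
- Primer matching for amplicon prediction is exact; near-match binding
  with mismatched 3′ ends is not modelled.
- The collinear aligner assumes ≥ ~95% identity and a shared gene order;
  it is not a general-purpose genome aligner.
- `mutate` assumes features do not wrap the origin (rotate first); the
  generator never emits wrapping features.
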