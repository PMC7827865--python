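# plastiddr

Comparative analysis of plastid genome (plastome) architecture for
lycophytes and other plants whose plastomes deviate from the textbook
layout. Most land-plant plastomes are quadripartite circles: a long and a
short single-copy region (LSC, SSC) separated by two large **inverted
repeats** (IR_A/IR_B). Most *Selaginella* plastomes instead carry the same
repeat pair in **direct** orientation (DR_A/DR_B), the product of a large
block inversion that swept part of the LSC plus one repeat copy into the
SSC; later lineage-specific inversions flipped DR_B back to IR_B in a few
species. The same genomes show drastic gene and intron loss, >50% GC, and
pervasive C-to-U RNA editing — many genes encode `ACG` where the
transcript needs an `AUG` start, or `CAA`/`CAG`/`CGA` where it needs a
stop, and editing restores the canonical codon post-transcriptionally.

`plastiddr` is a library plus CLI for working with such genomes:

- **structure** — find the large repeat pair of a circular genome by
  unique *k*-mer seeding against the sequence and its reverse complement
  (greedy co-linear merging, mismatch-tolerant ungapped extension),
  classify the orientation (DR vs IR), tile the circle into the
  quadripartite partition, and predict junction PCR amplicons that
  discriminate the two architectures.
- **rearrangement** — apply a block inversion to an annotated genome
  (features mirrored, strands flipped; an involution), and infer the
  single inversion separating two circular gene orders, reporting the
  flanking genes of the breakpoints.
- **content_survey** — species × gene present/pseudogene/missing matrix
  (pseudogene = annotated `/pseudo`, internal stop under translation
  table 11, or broken frame), intron presence over the 19 canonical
  intron-containing plastid genes, per-genome summary statistics (region
  lengths, GC, category counts with and without repeat duplicates), and
  grouped aggregation.
- **editing** — classify the first/last codon of every intact protein
  gene as normal / abnormal (editable by one C-to-U event) / other;
  confirm abnormal codons against mRNA read pileups: the edited C (middle
  base of `ACG`, first base of `CAA`/`CAG`/`CGA`) must show T in reads at
  ratio ≥ `min_ratio` (default 0.10) and depth ≥ `min_depth` (default 10).
  SAM/BAM input via pysam, or FASTQ through a built-in unique-31-mer
  read placer.
- **diversity** — SNP and InDel counting between near-identical genomes
  via unique-31-mer anchor chaining with gapped closing of inter-anchor
  segments; one InDel event = one maximal contiguous gap run.
- **synthetic_data** — seeded generator for every input above with
  recorded ground truth: annotated circles with planted DR/IR repeats,
  ACG starts, abnormal stops, pseudogenes, introns; mutated genome pairs
  with known SNP/InDel positions; edited mRNA-like reads with per-site
  efficiencies and sequencing error.

## Worked example

Simulate a DR-form plastome and analyse it:

```bash
plastiddr simulate --seed 1 --out demo --genome-len 60000 \
    --repeat-len 8000 --n-protein 16 --n-trna 4
plastiddr structure demo/SYN000001.gb
```

```json
{
 "id": "SYN000001",
 "orientation": "direct",
 "identity": 1.0,
 "label_basis": "marker-genes",
 "LSC": 19798,
 "SSC": 24198,
 "RepA": 8002,
 "RepB": 8002
}
```

The two repeat copies (8,002 bp, identity 1.0 — the maximal repeat picked
up two chance-matching flank bases beyond the planted 8,000) are in direct
orientation; the arc holding the marker genes (psbA/rbcL/rpoB) is named
LSC, and here — as in most *Selaginella* — the SSC is the *longer*
single-copy region. `plastiddr run-all *.gb --out run/` writes the full
bundle (structure.json/bed, stats.tsv, matrix.tsv, introns.tsv,
editing.tsv, diversity.tsv, summary.md, MANIFEST.json), e.g.:

```
| id        | species               | orientation | LSC   | SSC   | repeat |
| SYN000001 | Synthetica plastoma 1 | direct      | 19798 | 24198 | 8002   |
| SYN000003 | Synthetica plastoma 3 | inverted    | 19800 | 24200 | 8000   |
```

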