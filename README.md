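# poolmapper

Identification, well deconvolution and annotation of target-enriched
insertion sequences from multidimensional pooled sequencing libraries.

## The problem

Insertional-mutagenesis resources (e.g. transposon-tagged plant lines) need
the genomic insertion site of every line in a library of thousands.
Sequencing each sample separately is wasteful; instead samples are arranged
in a 3-D "cube" of `P` plates × `R` rows × `C` columns and *one pooled,
barcoded amplicon library is sequenced per plate, per row and per column* —
`P·R·C` samples in only `P+R+C` libraries (960 samples in 30 libraries for
a 10×8×12 cube). Each read carries a technical prefix
(`barcode + primer + identifier`) followed by the target site duplication
(TSD) the element created on insertion and then the genomic flank. The TSD
plus flank is unique per insertion, so the TSD-anchored sequence serves as
an *index* that can be traced across pools: a genuine single-well element
shows up at high coverage in exactly three libraries, and the intersection
of those three pools is its well.

`poolmapper` implements the full desk-side pipeline:

1. **preprocess** — stream-filter raw FASTQ/FASTA by barcode (exact) and
   primer/identifier (substitution-tolerant), trim the prefix, slice the
   TSD index (FASTQ→FASTA conversion included).
2. **store** — persist filtered reads in an embedded sqlite store, one
   table per (element end × library), and group them into per-pool
   coverage tables: for index *i* in library *ℓ*,
   `cov(i, ℓ) = n_reads(i, ℓ) / N_ℓ`, ranked `1..K` in descending coverage.
3. **deconvolve** — the core. A pool of a given dimension holds `E` genuine
   elements (`E = R·C` for a plate pool, `P·C` for a row, `P·R` for a
   column), so the top `⌊TH_G1·E⌋` ranking indices are its candidates
   (`TH_G1 = 1.5` by default). An index that is a candidate in exactly one
   pool of each dimension is a **Grade-1** assignment at their
   intersection. **Grade-2** rescues elements that under-amplified in one
   library: two strict dimensions plus a unique pool within the relaxed
   bound `⌊TH_G2·E⌋` (`TH_G2 = 3`). Indices prominent in more than 50% of
   all pools are inferred **endogenous** (host-genome background) and
   excluded; indices hitting several pools of one dimension imply multiple
   wells (premeiotic transpositions) and are reported for investigation.
   Outputs: per-plate HTML well grids, a well-tagged FASTA, TSV tables.
4. **elementmap** — interpret external alignments (BLAST `-outfmt 6` or
   SAM; the aligner itself is external) of the assigned sequences:
   unique/multiple/unmapped locus calls, insertion-point placement,
   gene-context classification against a GFF3 (exon *k* of *n*, intron,
   ±1 kb flanks, intergenic) and 5′/3′ end concordance.
5. **simpool** — a synthetic pooled-read generator with full ground truth
   (toy genome, per-well insertions, lognormal amplification bias,
   misprimed/junk noise, substitution errors, endogenous spike-ins,
   duplicate wells, per-pool attenuation), so the whole pipeline is
   testable without external data.

## Worked example

Simulate a 96-well cube (4×4×6, 14 pooled libraries, 10,000 reads per pool
with default 10% noise and 0.5% sequencing errors), run the pipeline on the
3′ end, then map the assignments with BLAST:

```bash
poolmapper simulate --seed 7 --out-dir example
# 96 insertions over 96 wells, 14 pool libraries under example

poolmapper run --design example/design.yaml --reads-dir example/reads \
    --config example/filter.yaml --end three_prime --out-dir example/decon
# retained 67385/140000 reads; 96 Grade-1 and 0 Grade-2 assignments; report under example/decon

makeblastdb -in example/reference.fasta -dbtype nucl -out example/refdb
blastn -query example/decon/assignments.fasta -db example/refdb -outfmt 6 \
    -out example/hits.tsv
poolmapper map --assignments example/decon/assignments.fasta \
    --aln example/hits.tsv --format blast --gff example/annotation.gff3 \
    --end three_prime --out example/annotated.tsv
# 96 queries: 96 unique loci; table at example/annotated.tsv
```

`retained 67385/140000` is the filter keeping the ~half of each pool's
reads that carry the 3′-end primer (the rest are the 5′-end amplicons and
noise). All 96 wells come back Grade-1; `assignments.tsv` records each
well's index, per-dimension coverage ranks and the representative read, and
`assignments.fasta` headers carry the well coordinates (`>01A01|grade1`).
The annotation table then reads, e.g.:

```
well   end          chrom  insertion_point  locus_status  gene_id    gene_context  paired
01A01  three_prime  chr3   107486           unique        gene_0000  exon(1/2)     False
01A02  three_prime  chr2   184072           unique        gene_0001  intron        False
01A03  three_prime  chr2   133619           unique        gene_0002  within_1kb_upstream  False
```

i.e. the insertion in well 01A01 landed in exon 1 of 2 of `gene_0000` —
the kind of call used to nominate knockout candidates. Running the 5′ end
the same way and feeding both tables to `poolmapper.elementmap.pair_ends`
flags wells whose two flanks anchor to the same locus, strong evidence the
assignment is genuine.

Every stage is also available individually (`poolmapper preprocess`,
`store-load`, `coverage`, `deconvolve`, `map`, `convert`), so pools can be
processed in parallel from a shell and re-run incrementally.

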