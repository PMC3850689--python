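# Methods

## Model and procedure

A sample cube of `P` plates × `R` rows × `C` columns is sequenced as
`P+R+C` pooled amplicon libraries, one per plate/row/column. Each sample
carries one target-enriched insertion; reads from its flanks begin, after
the technical prefix, with the target site duplication (TSD) the element
created. The TSD slice of length `index_length` is the *index* used to
group reads. The deconvolution premise is purely rank-based, not
probabilistic: target-enriched amplicons are sequenced far deeper than
noise, so a genuine element's index ranks near the top of the coverage
table of exactly three pools — its plate, row and column — and the well is
their intersection.

### Filtering (preprocess)

A read is retained iff it starts with the library barcode (matched
exactly — demultiplexing fidelity), followed by the primer within
`max_mismatches_primer` substitutions and the identifier within
`max_mismatches_identifier`. The mismatch model is substitution-only
(Hamming): indels would shift the trim offset and corrupt the TSD slice,
and at amplicon-sequencing error profiles substitutions dominate. `N`
never matches any base. Comparison is case-insensitive; output is
upper-cased. Reads shorter than prefix+index are counted and dropped, never
fatal. Filtering is streaming (constant memory), order-preserving and
deterministic; per-library runs are independent and can be parallelised
externally.

### Coverage (store)

Reads are persisted in an embedded single-file sqlite store, one table per
(element end × library) with fields (index_seq, trimmed_seq, read_id); SQL
is generated internally. Coverage of an index in a library is its read
count normalized by the library total — a per-million scaling would be an
equivalent monotone transform and cannot change ranks or grades. Ranks run
1..K in descending coverage, ties broken by descending raw count then
ascending index sequence: deterministic and platform-independent. The
representative read kept per index is the modal trimmed sequence (ties:
lexicographically smallest), so reports emit a real full-length read.

### Deconvolution

With `E` the expected genuine-element count of a pool (`R·C`, `P·C` or
`P·R`), the Grade-1 candidate set of a pool is its top `⌊TH_G1·E⌋` ranking
indices. `TH_G1` defaults to 1.5 — headroom for rank jitter from
amplification bias — and `⌊·⌋` is used because fractional multipliers make
a non-integer bound otherwise. An index that is a candidate in exactly one
pool of each dimension is assigned Grade-1. Grade-2 requires two strict
dimensions and, in the remaining one, presence in exactly one pool within
`⌊TH_G2·E⌋` (default 3) but beyond the strict bound — the parallel
construction is the minimal consistent reading of a "not-so-good"
dimension. If the weak dimension offers two or more relaxed pools the index
is reported ambiguous and not assigned; intent on that corner case is not
decidable from first principles, and refusing is the conservative choice.

Endogenous inference runs *before* assignment: an index "prominent"
(within the pool's Grade-1 candidate bound; one coherent notion of high
coverage, overridable via `endogenous_min_rank_fraction`) in strictly more
than `endogenous_pool_fraction` (default 50%) of all pools is endogenous
and excluded from candidacy, since host-background elements amplify from
every sample and would otherwise soak up well assignments. The strict
inequality means 15 of 30 pools is *not* endogenous, 16 is.

An index hitting `n_p·n_r·n_c > 1` candidate combinations is a multi-well
element (premeiotic transpositions legitimately occupy several wells); all
implied wells are reported. Beyond 8 implied wells the element is
reclassified suspected-endogenous — a pragmatic guard against borderline
background elements masquerading as many-well candidates. Two indices
assigned to the same well are both kept and flagged ambiguous rather than
arbitrated by rank. Output ordering is deterministic: (plate, row, column,
index).

Note a consequence of running endogenous inference first: on very small
designs (≲12 pools) a two-well duplicate element spans up to 6 pools and
can cross the 50% cutoff, i.e. duplicate detection needs designs where
6 ≤ half the pool count. Real designs (30 pools) are far from this edge.

### Element mapping

Alignment is external (BLAST `-outfmt 6` or SAM); this package only
interprets results. Hits below `min_identity` (default 95%) or shorter
than `min_length` (default 0.8× query length) are discarded; zero
survivors → unmapped, one → unique, and any secondary hit scoring ≥ 90% of
the best → multiple (ambiguity in repetitive regions). These thresholds
are config-exposed operationalisations, not canonical values. The
insertion point is the flank-proximal hit coordinate (hit start on `+`,
hit end on `−`): the flank begins with the TSD, so this approximates the
true site to within the TSD length. Gene context uses the gene feature
span with a ±1 kb window, exons numbered in transcription order; the
nearest qualifying gene wins (ties: lowest coordinate, then gene id). A
unique hit on a chromosome absent from the annotation is classified
intergenic — the signature of a genome/annotation mismatch. Two ends of a
well pair iff both are unique, on the same chromosome, within `max_gap`
(default 2× TSD length, the largest offset the duplicated target site can
introduce between the two flanks' insertion points).

## Simulator

`simpool` emulates the experiment end to end: a uniform-random toy genome
(3 chromosomes × 250 kb by default), one insertion per well of a 4×4×6
cube, both-end flanks sharing the TSD at the junction (the 5′ flank is the
reverse complement of the upstream region, so its index is the TSD's
reverse complement), 10,000 reads per pool of the form
`barcode+primer+identifier+TSD+flank` truncated to 100 bp.

Realism choices and their defaults:

* **Amplification bias**: per-(element, end, pool) abundance ∝
  lognormal(0, σ), σ = 0.5 — the simplest multiplicative model of PCR
  efficiency spread; it produces the rank jitter the TH_G1 headroom
  exists for.
* **Noise**: 10% of reads, split evenly between *misprimed* reads (correct
  technical prefix, drawn from ~25 per-pool off-target genomic loci with
  their own lognormal abundances — mispriming amplifies specific loci, so
  noise indices have real coverage mass and genuinely compete for
  candidate ranks) and *junk* (uniform-random sequence that fails the
  prefix filter), so both filter branches are exercised.
* **Errors**: i.i.d. substitutions at 0.5% per base, applied after read
  composition so the truth ledger's per-category counts are exact.
* **Endogenous elements**: 2 by default, emitted into *every* pool at a 5×
  copy multiplier.
* **Attenuation**: `attenuated_pools` divides a pool's on-target
  (genuine + endogenous) weight by the given factor while noise is
  untouched — a failed target enrichment in that library. This is what
  pushes the pool's elements past the strict bound and into Grade-2
  territory.
* Determinism: each pool draws from an RNG stream keyed by (seed, pool
  position), so outputs are byte-identical under a seed and independent of
  generation order.

Deliberate departures from real data: insertion sites are kept ≥3 kb apart
and their TSDs unique across both read orientations (an 8-mer birthday
collision between two wells — ~7% likely at 96 wells — would conflate two
elements for reasons unrelated to the method); no indel errors, quality
scores constant, no PCR chimeras, gene models are single-transcript toys
tiled so the context classes cycle deterministically. Passing tests
therefore demonstrate the pipeline's logic under controlled rank
perturbations, not robustness to TSD collisions, structural variation or
chimeric reads.

## Problem sizes

The validation runs use the 96-well 4×4×6 cube at 10,000 reads/pool
(140,000 reads per scenario; three scenarios: zero-noise, default-noise,
one plate pool attenuated 20×), grading-oracle equivalence on one hundred
random 3×3×3 instances against an exhaustive (index, well) enumerator,
coverage equivalence against an in-memory group-count on a 10⁵-read
library, and the annotation oracle on 1,000 random gene/point layouts.
These sizes exercise every code path while keeping a full suite run in the
tens of seconds.

## Known limitations

* Only 3-D designs are validated; the data model would extend to more
  dimensions but no logic beyond three is tested.
* No statistical confidence on assignments — the method is rank-threshold
  based by construction.
* "Unique locus" thresholds are heuristic and config-exposed; repetitive
  regions are reported as `multiple`, never resolved.
* The store is single-writer; there is no remote/multi-user DBMS support.
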