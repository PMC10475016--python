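# Methods

## Coordinates and identity

All genomic arithmetic uses one internal convention: 0-based half-open
intervals. VCF positions (1-based) and GFF3 coordinates (1-based
inclusive) are converted once at parse time; an SNV at printed
position *p* occupies `[p-1, p)`. Variant identity is the exact tuple
(chrom, pos, ref, alt). Indels are **not** silently left-normalised —
inputs are assumed normalised upstream, because re-normalising can
merge records the caller meant to keep distinct; an explicit
`left_align` pass against the genome is available and off by default.
Chromosome names match by exact string; a rename table can be supplied
on ingest but nothing is renamed silently.

## Variant identification

A call is retained iff

```
alt / (ref + alt) > min_vaf        (default 0.20, strict)
support            >= min_alt_reads (default 5, inclusive)
```

where `support` counts alt-supporting reads by default
(`depth_rule="alt"`); the alternative reading — total depth at the
locus — is `depth_rule="total"`. VAF uses two-allele AD-style
accounting: depth on other alternate alleles is excluded. Zero-depth
records are rejected with a named reason, never a division error.
Filtering is order-preserving and idempotent, and a log tallies
rejections by reason.

Germline subtraction removes tumour calls whose key occurs in the
matched normal; the normal's read support plays no role. Timepoint
classification then partitions the two filtered somatic sets into
common / additional / lost by key membership; duplicate keys within a
sample collapse to the record with the larger alt count (warned). For
common variants the relapse-sample record is the representative.

## Consequence calls

One gene model per gene: the transcript with the longest total CDS,
ties broken lexicographically by transcript id. Models whose CDS
length is not a multiple of 3 are flagged non-codable, excluded from
consequence calls (with a warning) but still usable for proximity.

An SNV inside a CDS segment is classified by substituting the alt base
into its codon in transcript orientation and translating both codons:
identical amino acid → synonymous; mutant stop → nonsense; reference
stop lost → stop-lost; loss of the initiator ATG → start-lost;
otherwise missense. An indel whose reference footprint overlaps any
CDS segment is frameshift when `(|ref| − |alt|) mod 3 ≠ 0`, else an
in-frame indel; indels spanning a CDS boundary are classed by the
overlapping portion. Everything else is one `non_CDS` class — splice
and UTR sub-classes are deliberately not distinguished. Labels are
HGVS-like (`c.4G>T (p.E2*)`, `c.7del… (p.…fs)`) — readable pointers,
not full HGVS normalisation. The implementation is validated against
an independent oracle that splices, reverse-complements and translates
the entire wildtype and mutant CDS and diffs the proteins, over
hundreds of random multi-exon genes on both strands.

## Transcription regulatory areas

A TRA is a maximal interval where at least `min_regulators` (default
5) *distinct* regulator names are simultaneously bound. The builder
sweeps cluster endpoints per chromosome maintaining a name→active-count
multiset, so duplicate clusters of one factor never double-count;
qualifying segments that touch are merged, making regions maximal,
disjoint and sorted. Each region records the union of regulators
overlapping it anywhere plus the peak distinct depth. Equivalence with
a per-base brute-force oracle (materialise distinct counts for every
base, threshold, take maximal runs) is asserted over 100 random
instances, and total coverage is checked to be non-increasing in the
threshold.

A variant enters a TRA through its **anchor** base — the mutated base
for an SNV, the leftmost reference base for an indel. Involvement is
attributed at that base by default (`attribution="position"`: the
regulators whose clusters cover the anchor), which is the stricter
base-resolution reading; `attribution="region"` attributes the whole
region's regulator union instead. Regions are disjoint by
construction, so no variant can hit two.

Proximity: a gene is within the window (default 20,000 bp, inclusive
at exactly the window) of an alteration iff the number of bases
strictly between the anchor base and the gene span is ≤ the window
(0 inside the span). Distance is to the transcript extent, not the
TSS. The boundary pair — gap 20,000 in, 20,001 out — is pinned by
test against a quadratic brute-force oracle.

## Involvement statistic

For regulator *r* and class *c* ∈ {common, additional} with `N_c`
TRA alterations, the involvement rate is `100 · n_{r,c} / N_c` and the
skew ratio is `additional_rate / common_rate`, computed on unrounded
rates; rates are rounded (1 decimal) only at serialisation, the ratio
to 4 decimals. With planted counts 14/50 vs 47/100 the ratio is
1.6786 — rounding rates first would give 47/28-style drift, which is
why rounding order is fixed. A regulator absent from common
alterations is reported as *additional-exclusive*, a flag rather than
a numeric sentinel, and sorts before every finite ratio; the table is
ordered by ratio descending, ties by additional rate then name. The
skew report flags ratio ≥ 2 (configurable) and all
additional-exclusives, the latter with a low-frequency caveat below
5% involvement. No significance machinery is attached — the statistic
is descriptive; the simulator quantifies its sampling noise instead
(at N=500 per class the estimate stays within the exact 99% binomial
envelope of the planted 0.47/0.28 ratio).

## Expression thresholds and overlaps

Differential expression consumes p-values; the engine that produced
them is upstream and out of scope. `|FC| ≥ 2` is realised on the
ratio scale (FC ≥ 2 or ≤ 0.5, i.e. |log2FC| ≥ 1, thresholds
inclusive) with P < 0.01 strict. Fold change is
`(mean cond + ε)/(mean ctrl + ε)` with pseudocount ε = 0.1; when ≥ 2
replicates per group exist and no p-value column does, a Welch t-test
on `log2(FPKM + ε)` is attached as a convenience. Transcript-shift
genes require one transcript passing the same thresholds **and**
carrying an accepted structure label (defaults: reference containment,
junction match); the label is consumed, never recomputed. Gene-set
overlaps are exact Venn partitions of 2–4 named sets (regions keyed by
the exact set combination, counts summing to the union), serialised
as TSV with memberships.

## Synthetic data

The generators are pure functions of (seed, parameters); reruns are
byte-identical, and every dataset ships a JSON truth sidecar that
tests read rather than re-derive.

* **Reference**: 2 chromosomes × 300 kb of random sequence with 60
  non-overlapping genes (1–3 exons, both strands); every CDS starts
  ATG, ends at a single stop, has no internal stop and length
  divisible by 3. Exon boundaries are codon-aligned for construction
  simplicity; split-codon handling is exercised by the randomised toy
  models in the test suite instead.
* **TFBS clusters**: planted regions carry a 5-regulator core covering
  the interval end to end plus 8 optional regulators laid over `2^8`
  equal zones, zone *j* covered by exactly the optional regulators in
  *j*'s bitmask — so any involvement subset corresponds to real bases.
  Three decoy regions with a 4-regulator core stay below threshold.
  Background clusters (150) are placed clear of planted intervals and
  re-jittered until the builder, run as a post-hoc audit, recovers
  exactly the planted intervals.
* **Variants**: 40 germline (present in all three tables), 60 common
  (32 in-TRA), 90 additional (54 in-TRA), 25 lost. In-TRA positions
  are drawn by sampling each optional regulator's involvement
  Bernoulli per class — MYC at (0.28, 0.47), RCOR1 (0.10, 0.40),
  CHD2 (0.08, 0.30), RXRA/KDM5B additional-only, POLR2A/EP300/CTCF
  symmetric — and placing the variant in the matching zone. Passing
  support is depth U{30..100} with alt ~ Binomial(depth, 0.35)
  conditioned on passing; 10% of each class is converted to boundary
  sub-threshold support (VAF exactly 0.20, or exactly 4 alt reads),
  out-of-TRA calls first so the in-TRA counts survive filtering
  intact. The sidecar records planted and expected post-filter counts.
* **Expression**: 3,000 genes (the 60 reference gene ids included in
  the universe), 74 up / 320 down at log2 effect 2.0 (margin above the
  |FC| ≥ 2 bound at replicate noise sd 0.15) with p forced below the
  cutoff; nulls fluctuate around zero effect with uniform p, so
  recovery of the planted sets is exact. 1,321 shift genes each get
  one accepted-class passing transcript; decoys fail a threshold or
  carry a non-accepted label.

These sizes are the package's default study conditions; they echo the
scale of a single paired-sample comparison, not a population. What
passing tests show is that the machinery is exact on data whose truth
is known by construction. What they do not show: performance on real
mutation spectra (no signatures, no haplotype structure, no mapping
artefacts), calibration of the DE engine (p-values are inputs), or
robustness to annotation-build differences.

## Pipeline and reproducibility

Stage order is fixed: filter → subtract → classify → consequence →
build-TRA → intersect → proximity → involvement → integrate. The run
manifest echoes the configuration and per-stage counts and asserts
internal consistency (filtered ≤ read; the three classes sum to the
key-union). Outputs are byte-reproducible from identical inputs and
config; wall-clock timestamps go into the manifest only on explicit
request for that reason. Configuration comes from one TOML file with
CLI-flag overrides (flags > file > defaults). Exit codes: 0 success,
1 usage, 2 data error.

## Known limitations

No BAM/CRAM or tabix support; no liftover; full GFF3 generality is out
of scope (gene/mRNA/CDS subset only). Structural variants, copy
number and translocations are not classified. HGVS labels are
approximate. The involvement statistic carries no inferential test by
design. The sweep and indexes are built for desk-scale inputs (tested
to ~10^5-interval tracks); a genome-scale ENCODE track works but has
not been profiled.
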