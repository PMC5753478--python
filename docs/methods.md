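# Methods

`circage` implements a circRNA discovery–quantification–aging pipeline for
bulk total RNA-seq, together with a synthetic-data generator that serves as
its test harness. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does not
show about real data.

## Coordinates and data model

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF input (1-based inclusive) and BED output convert at the module
boundary. A circRNA junction is identified by `(chrom, start, end, strand)`
where `start` is an annotated exon genomic start and `end` an annotated exon
genomic end; its strand is the annotated strand of the single host gene
(reads are strand-ambiguous in the simplified alignment model). Alignments
are simplified per-mate block lists (`FragmentAlignment`) rather than SAM
records — the pipeline consumes only junction-overlap information.

## Back-splice detection

Detection is anchor-based. For each read (both orientations), the terminal
`anchor_length` = 20 nt anchors are placed in the genome by exact k-mer
lookup; a placement is used only if unique. A head-to-tail pair (tail anchor
genomically before the head anchor, span ≤ 25 kb) is extended inward by
scanning candidate breakpoints: the donor coordinate must be an annotated
exon end and the implied acceptor an annotated exon start on a common
strand. Total mismatches must not exceed `max_mismatches` (6), and the 8 nt
on each side of the breakpoint must align with at most one mismatch per
side — without this window rule a read from an unannotated junction a few
nt away can be snapped onto the nearest annotated edge with a handful of
mismatches. Ties break by most matched bases, then smallest span. Reads
overlapping the junction by less than the anchor length on either side are
unrecoverable by construction (an anchor would straddle the junction), which
is why the generator's recall guarantee is stated for fragments with
anchor-length overlap on both sides.

The filter cascade then:

1. collapses PCR duplicates — supporting fragments from one library whose
   placed reads have identical coordinates count once. The duplicate key is
   the block structure of the placed junction reads (plus the mate when
   placed), not the plain outer interval: every junction-crossing read of a
   given junction shares the same outer interval (the junction itself), so
   an outer-coordinate key would collapse all support to one;
2. removes junctions whose span overlaps exons of more than one gene, or of
   none, and assigns the survivor to its single parental gene;
3. keeps junctions with ≥ `min_catalog_reads_total` = 12 deduplicated reads
   summed over all libraries and assigns serial ids in coordinate order.

## Quantification

Counting is template-based and independent of discovery. Each catalog entry
gets a 200-nt junction template: the last 100 nt of the annotation-spliced
circle joined to its first 100 nt, back-splice point at the midpoint;
circles shorter than the template wrap. Reads are placed on templates by
seeded exact k-mers (so reads may overhang the template ends), and a read
counts iff it crosses the midpoint with ≥ `min_junction_overlap` = 8 nt on
each side, passes the same mismatch rules as detection, and its best
placement is unique (score ties between templates are assigned to neither).
Fragments are deduplicated per library by the template coordinates of their
junction-crossing mates. The generator logs exactly this statistic
(`junction_unique`), so error-free quantification is tested for exact
equality. One consequence worth knowing: on short circles at deep coverage
the number of distinct fragment placements saturates, so deduplicated counts
— and hence fold changes — compress. This mirrors duplicate removal on real
data and is why statistical calibration uses the count-level generator
(below) rather than read-level simulation.

TPM is `count × 1e6 / library_size` with the library size equal to total
sequenced fragments, not junction-read totals. The per-time-point detection
rule sums deduplicated reads over the replicates of a time-point and
thresholds at `min_timepoint_reads` = 6.

## Aging statistics

Pairwise comparisons between time-points use fold changes of mean TPM (a
pseudocount equal to the smallest nonzero TPM in the comparison is added to
both means when either is zero) and two-sided unpaired t-tests, Welch by
default — with n = 3 heteroskedastic TPM replicates the pooled-variance
assumption is the riskier one; a pooled mode is available. BH correction is
applied within each pairwise comparison. A circRNA is called up when
FC > 1.5, P < 0.05 and q < 0.2 (down symmetrically); calls are monotone in
both thresholds. Degenerate rows (zero variance in both groups with equal
means) get p = 1 and a flag.

The global test pools per-circRNA TPM values by time-point:
tie-corrected Kruskal–Wallis, then Nemenyi pairwise post-hoc via the
studentized-range distribution (infinite df) on tie-corrected mean-rank
differences. The RCM enrichment test uses Dunn's z-tests with Bonferroni
adjustment instead, matching the different post-hoc convention of that
analysis. Both post-hocs are implemented in `rank_tests` from the standard
formulas (no post-hoc package is a dependency).

Age-specific circRNAs pass the 6-read rule at exactly one time-point; the
default is strict (zero reads elsewhere), with a lenient mode (below
threshold elsewhere) behind a flag, since "specifically expressed" is
ambiguous between the two readings. PCA QC projects libraries on the first
two components of the centered, unscaled TPM matrix (log transform
optional).

## Host-gene independence

Linear (forward-orientation) reads are counted at the circRNA's two boundary
coordinates: a fragment crosses a boundary if a mate covers it contiguously
with ≥ 8 nt on each side or uses it as the donor/acceptor of a forward
splice with ≥ 8 aligned nt on each side; back-splice fragments are excluded;
the two boundary counts are averaged (half up). Replicate-level pairs
(circ, circ + linear) are modelled as beta-binomial draws with a shared
overdispersion; the test is a likelihood-ratio of one common proportion
(H0) against per-time-point proportions (H1), p from χ² with T − 1 df, BH
across tested circRNAs, eligibility requiring ≥ 6 circular reads per
compared time-point. The default call threshold is P < 0.05 with FDR < 0.05;
an FDR < 0.2 mode exists because both conventions are in circulation for
this analysis.

Numerics: overdispersion is parametrized as φ = 1/(1 + θ) ∈ [0, 0.9] and
fitted by profile likelihood — for each φ the group proportions are
independent bounded 1-D optimizations, and φ itself is located on a grid
dense near zero and refined by a bounded scalar search. The φ = 0 boundary
is the exact binomial likelihood with closed-form proportion MLEs, so for
non-overdispersed data the test reduces to the classical binomial LRT; the
dense-near-zero grid matters because the profile optimum often sits just off
the boundary and missing it biases the LRT. An early joint quasi-Newton
implementation mis-converged enough to inflate the null rejection rate to
~0.09; the profile form is calibrated (~0.034 at α = 0.05 under the
Poisson-count null, where conditioning on totals makes the circ counts
exactly binomial) and agrees with an independent dense-grid oracle to
~1e-10. Note the test is mildly conservative at n = 3 replicates per group
because chance between-group spread can be absorbed into the free H0
overdispersion. The LRT statistic is clipped at 0; p-values are clipped into
(0, 1].

## Genomic features and RCM search

Region classes come from the features overlapped by the circRNA's exons on
the host gene's reference transcript (the longest; a union-of-exons mode
exists for exon membership): CDS, 5'UTR+CDS, 3'UTR+CDS, 5'UTR, 3'UTR, or
other (including non-coding hosts and spans touching both UTRs). Exon counts
and the 1-based first-exon rank (transcript orientation, reported only for
multi-exon circRNAs) use the same reference transcript.

RCM search is ungapped seed-and-extend between the strand-oriented upstream
intron and the reverse complement of the downstream intron: exact
`word_size` = 7 seeds, extension at +1/−2 with X-drop 6, hits kept at score
≥ 10, deduplicated by diagonal and final interval, coordinates mapped back
to the downstream intron's native orientation. These constants are the
package's convention for a deterministic, oracle-checkable approximation of
short-word nucleotide search; gapped alignment is out of scope. The
enrichment statistic is the per-locus hit count (max length and total score
are reported alongside), compared across circ loci and exon-2/exon-8
control loci of non-circRNA genes sampled with a fixed seed to match the
circ-locus count.

## Synthetic-data generator

The generator emulates the target study design: 12 libraries = 4 time-points
× 3 replicates of paired-end 125-nt reads; a mixture of linear mRNA
fragments (Poisson per gene per library, default mean 100, flat across age)
and circRNA fragments (Poisson with mean `base_circ_mean` = 50 × the
time-point's age multiplier, default (1, 1.2, 5, 6)); fragments N(250, 30)
nt; substitution errors i.i.d. per base; genes laid out non-overlapping on
one chromosome with i.i.d. uniform intergenic/intronic sequence, alternating
strands, 4–9 exons of 150–350 nt, introns 120–400 nt; a CDS from
mid-first-exon to mid-last-exon so terminal exons carry UTRs. CircRNA loci
start at transcript exon rank 2 and never reach the terminal exon, so both
flanking introns exist; 30-nt RCMs are planted into the flanking introns of
80% of circ loci by default. Circular fragments are drawn from the doubled
circle sequence, giving uniform coverage across the back-splice point.
Exons are kept ≥ 150 nt ≥ read length so a junction-crossing read never
also spans a forward splice, which keeps anchor placement exact.

The truth table records, per locus and library, the expected mean, emitted
fragments, junction-spanning fragments (≥ 8 nt on both sides), and the
deduplicated count under exactly the quantification key — the oracle for the
exactness tests. Everything is deterministic given `rng_seed` (sub-seeds
seed+1..3 separate locus choice, RCM planting and read emission).

A count-level generator (`simulate_counts`) draws the same Poisson counts
without emitting reads, against a fixed nominal library size of 1e6
fragments (in real libraries junction reads are a negligible share of the
total, so library size is external to the circRNA counts). It is used for
statistical calibration and power checks, where read-level simulation would
add only runtime and the dedup-saturation confound.

What passing these tests does not show: real libraries have non-uniform
coverage, indels and quality-correlated errors, multi-mapping from repeats
and paralogs, unannotated splice sites, rolling-circle artifacts, and
incomplete annotations — none of which the generator models. The validation
demonstrates correctness of the algorithms under their stated assumptions,
not field performance on a real genome.

## Problem sizes used in validation

Detection accuracy is checked on ~2.2 × 10⁵ fragment pairs (20 genes, 10
circRNA loci, per-gene linear mean 850, 1% error) and error-free runs at
default depth; type-I calibration uses 10,000 null circRNAs per test;
parameter recovery uses 100 circRNAs at base mean 30; RCM enrichment uses a
60-gene genome with 20 circ loci so both control groups are well populated.
All are the package's own validation sizes, chosen to give stable estimates
of quantities whose true values were measured at larger n during
development.

## Known limitations

- Detection requires annotated splice sites on both ends by design; no
  de-novo GT/AG search.
- Deduplicated junction counts saturate on short circles at deep coverage
  (see Quantification).
- The ratio test's χ² asymptotics are approximate at 3 replicates per
  group; it runs mildly conservative there.
- Ambiguous junction reads are discarded, not rescued by EM.
- The internal exon/intron structure of multi-exon circRNAs is taken from
  the annotation; back-splice reads cannot reveal internal retention or
  skipping.
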