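# Methods

This note records the models, conventions and numerical choices behind
genomekit, the assumptions they rest on, and what the synthetic-data
generators do and do not emulate.

## Coordinates and formats

All record types share one internal convention: 0-based, half-open
`[start, end)` intervals. One-based formats (VCF POS, SAM POS, WIG
start, GTF start) are converted in their parsers and restored in their
serializers; no other code performs coordinate arithmetic on file
conventions. Consequences worth knowing:

- Adjacent intervals (`[0,10)`, `[10,20)`) never overlap.
- Zero-length intervals (e.g. the insertion point of a pure insertion)
  overlap nothing; callers who want neighborhood semantics must pad
  explicitly.
- A VCF record spans `[POS−1, POS−1+len(REF))`; a SAM record's end is
  its POS plus the reference-consuming CIGAR length (M, D, N, =, X).

Readers are generators: memory is bounded by one record, verified by a
test comparing traced allocations at 2×10^4 vs 10^5 records. Headers
(`##`/`#` for VCF, `@` for SAM, track lines) are captured before
iteration and re-emitted verbatim on write. Gzip input is detected by
magic bytes (a misnamed gzip file is still decompressed; a `.gz` name
over plain bytes is an error, since the extension promised compression);
gzip output is selected by a `.gz` suffix.

Round-trips are byte-faithful for the fixture corpus with these
deliberate canonicalizations: whitespace-separated BED is re-emitted
tab-separated, floats print as `%g`, and variableStep WIG is densified
to a step-1 track on read (fixedStep output splits blocks around
missing-value runs; missing is an explicit sentinel, never 0).

Malformed records fail fast with file, line number and offending text —
no silent skipping. Soft-masked (lowercase) bases are preserved on
round-trip and compare equal to uppercase in all algorithmic contexts.

Binary BAM/CRAM codecs are out of scope; the SAM text codec is native
and the record contract is the seam where a binary reader could be
attached.

## Interval engine

The index is a per-chromosome interval tree (the `intervaltree`
package) keyed by start with max-end augmentation; query results are
returned in genome order with input order breaking ties, so results are
independent of insertion order. Overlap ignores strand by default (a
same-strand restriction is available in the single-cell counter where
it matters). Correctness is anchored to a brute-force nested-loop
oracle on random instances (10^4 intervals × 500 queries).

`genome_sort` is an external merge sort: lines are chunked (default
10^5 per chunk), sorted, spilled to temporary files and k-way merged,
so memory is bounded by the chunk size. The total order is
(chromosome rank, start, end, serialized line) — including the line
text makes the order fully deterministic even for records that tie on
coordinates. Chromosome rank comes from an explicit chrom.sizes order
when given (unknown chromosomes are then an error) and is lexicographic
otherwise. Barcode mode keys on the `CB:` token of the record name
instead.

## Liftover

Chains are validated on parse: target strand `+`, and block sums
`Σsize + Σdt = tEnd − tStart`, `Σsize + Σdq = qEnd − qStart`. Negative-
strand query coordinates are strand-local per the UCSC convention;
single positions map through `q_forward = qSize − q_local − 1`.

An interval's mapped fraction under a candidate chain is the share of
its bases inside aligned blocks. Status resolution:

- exactly one chain at or above `minMatch` (default 0.95, the common
  liftOver convention) → `lifted`;
- several usable chains → the one whose score strictly dominates, else
  `ambiguous` (determinism over guessing);
- none usable but some base maps → `partial`; no base → `unmapped`.

The lifted interval spans the minimum to maximum mapped query base, so
internal unaligned stretches widen rather than split the output;
`strict` mode refuses any interval with mapped fraction < 1 instead.
VCF records are re-checked against the new reference when one is
supplied (`ref_mismatch` on failure, `length_change` when the mapping
is not length-preserving). SAM records are lifted only when the whole
alignment maps contiguously on the same strand; anything else would
need CIGAR surgery and is rejected as `cigar_split`.

Chain inversion (swap target/query, normalize the new target to `+` by
reversing blocks and flipping both coordinate pairs) gives the
round-trip guarantee tested on simulated assembly pairs: lift followed
by inverse lift is the identity on fully-mapped intervals.

## Overlap enrichment

The null model is independent uniform placement: each A element keeps
its length and lands uniformly over the valid start positions of the
search space (whole chromosomes by default; a BED search space
restricts placement, e.g. to non-gap regions), with B fixed. This is
the standard element-shuffling null, stated explicitly because results
are only interpretable relative to it. Overlap is element-wise — an A
element hits or it does not.

The hit probability for a length-ℓ element is computed exactly by
dilating each merged B interval left by ℓ−1 and summing clipped
coverage over valid starts. The count statistic is Poisson-binomial;
its tail is computed by direct convolution of the per-element
probabilities (O(n²), exact to ~1e−15 against full 2^20 enumeration at
n = 20), by a continuity-corrected normal approximation
(mean Σp\_i, variance Σp\_i(1−p\_i)), or by permutation with
`p = (1 + #{k* ≥ k}) / (n_perms + 1)` so an estimated p is never 0.
The three routes cross-validate on a toy genome (1 chromosome, 10 kb,
20 A, 5 B, 20 000 permutations) within Monte-Carlo error.

## Population genetics

**Convention.** The selection parameter is α = 2Ns throughout and is
printed in all outputs.

**Density and likelihood.** The stationary density `f(x; α)` (see
README) is discretized on a uniform midpoint grid of G = 1000 points,
`x_i = (i + ½)/G`, and normalized there; `expm1` keeps the ratio stable
to |α| = 100. The sampling distribution of a derived-allele count j out
of n chromosomes is the grid-integrated binomial mixture renormalized
over the segregating classes 1..n−1 — exactly the process the simulator
uses (draw x from the grid density, draw Binomial(n, x), reject
non-segregating draws), so simulation and inference share one model by
construction. G is configurable; 1000 points make the neutral spectrum
match 1/j to ~0.1% while keeping a likelihood evaluation at ~10 µs
after the binomial matrix is cached per (n, G).

**MCMC.** Random-walk Metropolis on α with a Gaussian proposal
(default sd 0.5), flat prior on a bounded interval (default ±50);
out-of-bounds proposals are rejected and counted. Defaults of 5000
iterations with 1000 burn-in mix well at desk scale (acceptance
0.3–0.5); the validation experiments use 2000/500 with 10^4 variants of
n = 20 chromosomes, where nominal 95% credible intervals cover the true
α in ≥ 18 of 20 replicates.

**Spectra.** Polarized spectra assume ALT is the derived allele; a fold
operation merges bins j and n−j for unpolarized data. Only biallelic
SNVs with fully-called genotypes contribute; everything else is counted
as skipped so totals always reconcile.

**Somatic calling.** Fisher's exact test (one-sided, alt-enrichment in
the experimental sample) was chosen over asymptotic likelihood-ratio
tests for exactness at the small counts typical of desk-scale depth;
it matches exhaustive hypergeometric enumeration to 1e−9 relative.
Defaults: `min_alt_reads` 2, `max_normal_af` 0.0, `max_p` 1e−3. The
validation experiments use two operating points: the specificity guard
runs identical tumor/normal pileups with `max_normal_af` 1.0 (so the
statistical test itself, not the contamination filter, is what holds
the line) and demands zero calls at p ≤ 1e−6 over 10^5 columns; the
sensitivity screen at 20% VAF and depth 50 uses p ≤ 0.05 with a 5%
normal-AF allowance, the conventional screening significance level —
at depth 50 an exact test simply cannot reach p ≤ 1e−3 until ~10 alt
reads, so a screen at that threshold would trade most of its recall
for specificity the downstream filter already provides.

**Haplotypes.** Variant alleles are substituted into the reference
slice right-to-left so earlier coordinates stay valid; unphased
heterozygotes are an error unless explicitly overridden. Identical
haplotypes merge with counts; output is sorted by descending count then
sequence for determinism.

**Alignment to VCF.** Columns where the reference base and at least one
other sequence are non-gap and differ (case-folded) become merged-ALT
SNV records; columns containing any gap are counted and reported but
never emitted — indel emission is deliberately deferred because
left-alignment semantics in a multiple alignment are ambiguous.

## Single-cell counting

Defaults follow 10x 3' v3 chemistry (16 nt barcode + 12 nt UMI; v2 via
flags). Whitelist handling: exact match accepted, a unique
Hamming-distance-1 neighbor corrected, ambiguous or distant barcodes
dropped and counted. Gene assignment requires overlap with exons of
exactly one gene — ambiguous and intergenic reads are counted and
discarded; antisense reads count by default with a `--stranded` option,
since chemistry varies. UMI deduplication is exact string identity (no
Hamming-1 UMI merging): deterministic and order-independent, at the
cost of slightly over-counting molecules whose UMIs carry sequencing
errors — a known divergence from pipelines that collapse near-identical
UMIs. The audit trail (assigned + ambiguous + intergenic + dropped =
primary mapped; matrix total + duplicate UMIs = assigned) always
reconciles. Input normalization, when a per-gene input/control total is
supplied, is `count / (input + 1)` — the pseudocount keeps genes absent
from the input usable.

## Coverage and track arithmetic

Depth counts CIGAR M, =, X and D as covering (a deletion spans its
columns) and N, I, S, H as not — standard pileup-depth semantics,
stated because conventions differ across tools. Only primary mapped
reads count. The exact integer identity Σdepth = Σreference-consumed
bases is asserted, not approximated. Track arithmetic propagates
missing values (missing op anything = missing; x/0 = missing);
smoothing is a centered moving average over the non-missing neighbors
in an odd window, truncated at track edges, leaving all-missing windows
missing.

## Simulators and what passing tests mean

The generators are first-class modules whose outputs always pass their
own format's parser, are deterministic under a fixed seed, and carry
their ground truth:

- **Reads**: uniform starts and strands, constant base quality,
  independent per-base substitution errors uniform over the three
  alternatives, `<L>M` CIGARs; paired mode draws the insert from a
  truncated normal and emits FR proper pairs. No indel errors, no
  quality-dependent error profile, no PCR duplicates — so tests passing
  on these reads demonstrate bookkeeping and statistical correctness,
  not robustness to real error structure.
- **Assembly pairs**: random deletions, insertions and inversions
  (sizes uniform in 5–50 bp at desk scale, configurable) applied per
  chromosome; colinear runs become one `+` chain, each inversion its
  own `−` chain, with the base-level target→query map retained. Real
  assembly differences (segmental duplications, translocations between
  chromosomes) are not modeled.
- **Barcoded reads**: R1 is barcode+UMI, R2 exonic sequence of the
  designated gene; the aligned counterpart places reads within single
  exons so the expected count matrix equals the design exactly. Doublets,
  ambient RNA and barcode-sharing artifacts are not modeled.

Validation experiment sizes (10^4 intervals, 10^5 pileup columns,
5 × 10^4 variants, 20 MCMC replicates, 2 × 10^4 permutations) are desk
scale: large enough for the statistical bands to be meaningful, small
enough to run routinely.

## Known limitations

- SAM tags are opaque strings; typed tag access is out of scope.
- VCF symbolic/breakend alleles are carried as text, not interpreted.
- The enrichment null ignores GC content and distance matching;
  conclusions are relative to uniform placement only.
- The selection likelihood assumes a stationary population at
  equilibrium — no demography.
- liftover does not compose chains (no multi-hop) and lifts BEDPE feet
  independently, not as linked pairs.
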