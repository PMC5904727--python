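# Methods

## Problem setting

Claims that dietary plant miRNAs ("xenomiRs") enter mammalian
circulation rest on small RNA-seq count tables in which plant-annotated
sequences receive mapped reads in host samples.  Two artifact routes
explain most such signals: low-level contamination and sequencing error
produce sporadic counts in a minority of samples, and genuine host
sequences that also occur in plant references (or that have contaminated
plant databases) produce consistent, sometimes abundant counts.
`xenomir` operationalizes the screening steps that separate these
explanations: count thresholding, host-sequence matching, a triage
cascade, and a read-level subtraction filter.

## Count screening model

The unit of analysis is a candidate × sample matrix of raw mapped read
counts (integers ≥ 0; a candidate absent from a sample's table is a 0,
not missing).

**Replicate merging.** When each library is sequenced more than once,
runs are *summed* per library (the runs exist to increase depth;
averaging is deliberately not offered).  Libraries with fewer than the
modal number of runs are dropped as unreliable replicates, which is how
a 192-library study becomes 190 merged columns when two libraries have a
single usable run.

**rpm arithmetic.** With mean sequencing depth *R* reads/sample and
mapped fraction *f*, a cutoff of *r* rpm (reads per million *mapped*
reads) corresponds to *r·R·f*/10⁶ raw counts, and a raw count *c*
corresponds to *c*/(*R·f*)·10⁶ rpm.  Both computations read *f* from
`ScreenConfig.mapping_fraction` — one field, two conventional values:

- 0.5 ("about half of reads map") for the coarse translation of the
  32 rpm cutoff into ≈ 200 raw reads;
- 0.475 for estimated-median-rpm values.  The source material uses the
  midpoint of the original study's reported mapping-percentage range
  without printing the range; 0.475 is back-derived from the published
  pair (median 1072.5 counts ↔ 180.6 rpm) and verified against every
  other published rpm cell to 1 decimal.  It is a config value, never a
  hard-coded constant.

**Inclusion screen.** A candidate passes when it has ≥ `min_reads`
(default 3) in at least ⌈`min_sample_fraction`·n⌉ samples (default
0.10; ceiling is required so that 10% of 23 samples means 3 samples)
and its mature sequence is discoverable (membership in the supplied
annotation set).  Output order: samples-at-threshold desc, mean desc,
id.  The screen is monotone in both thresholds.

**Background screen.** Median raw count strictly greater than
`background_median_reads` (default 200).  Strict inequality reflects the
wording "above a … cutoff"; a candidate exactly at the cutoff is
background.  Medians over an even number of samples are the mean of the
two central values, hence half-integers like 1072.5 are expected and
preserved.

## Host-match classification

All matching is ungapped (Hamming); indels are a documented
non-goal — mature miRNA candidates are ~20 nt and the questions asked
("is this sequence present in the host?") are about (near-)identity,
not homology.  Sequences are normalized on load: case-folded, U→T,
ambiguity codes rejected (categories are defined on exact base
identity, so N-wildcards would blur them).

Three primitives, each brute force by design (the reference behaviour
any accelerated index must reproduce bit-identically):

- `exact_search` — all full-length 0-mismatch placements, plus strand
  first, then minus; minus-strand hits are reported in forward-strand
  coordinates with strand `-`, which is how an "antisense" match is
  expressed without a second coordinate system;
- `longest_perfect_stretch` — longest common substring via the
  O(nm) dynamic programme, vectorized over the reference; `PARTIAL`
  when ≥ `partial_min_stretch` (default 15 nt).  Multiple disjoint
  stretches are not summed;
- `best_windowed_match` — minimum Hamming distance over all
  candidate-length windows on both strands; 0 → `EXACT_FULL`,
  1..`near_max_mismatches` (default 1) → `NEAR`.

`classify_host_match` combines them across references with precedence
`EXACT_FULL > NEAR > PARTIAL > NONE`: a full-length hit with one
substitution is stronger evidence of host origin than a shared 15-nt
fragment.  Ties resolve toward longer matches, fewer mismatches, then
smaller coordinates, so results are deterministic.

## Triage cascade

Exactly one verdict per candidate, evaluated in fixed order:

1. host `EXACT_FULL` **and** biotype `UNMAPPED_IN_CLAIMED_SPECIES`
   → `DATABASE_CONTAMINANT` (a "plant" database entry that does not map
   to its claimed species but is verbatim host sequence);
2. host `EXACT_FULL` or `NEAR` → `HOST_SEQUENCE`;
3. biotype in {rRNA fragment, tRNA fragment, mitochondrial,
   microsatellite} → `LIKELY_NONMIRNA_FRAGMENT`;
4. median ≤ background → `BELOW_BACKGROUND`;
5. in current miRBase, host `NONE`, above background
   → `PLAUSIBLE_XENOMIR`;
6. otherwise `UNRESOLVED`.

Host evidence precedes biotype precedes abundance; the order is not
configurable — one canonical cascade keeps verdicts comparable across
datasets.  `PARTIAL` matches never decide a verdict; they are recorded
in the evidence list only, since a shared fragment is suggestive rather
than conclusive.  A safety property holds by construction and is tested
by exhaustive enumeration of the discrete input space: no candidate with
a full-length exact host match can ever be labelled
`PLAUSIBLE_XENOMIR`.

One consequence worth noting: a candidate that is an annotated miRNA
with no host match but a below-background median (the MIR894 pattern)
triages to `BELOW_BACKGROUND`, because the abundance rule fires before
the plausible/unresolved tail.

## Stringent read filter

`host_subtract` removes a read iff its best full-length placement on
*any* host or extra subtraction reference (both strands — sequencing
orientation is unknown) has ≤ `host_max_mismatches` mismatches
(default 2, the permissive end of the recommended "one or two").
`foreign_assign` then assigns the survivors to every foreign reference
containing them verbatim; multi-reference hits are reported ambiguous,
never resolved, and anything else is unassigned.  Subtraction strictly
precedes assignment, so (retained, removed) partition the input and no
read is both host-removed and foreign-assigned.  Reads shorter than
15 nt are rejected at load — below that length perfect matches are too
promiscuous to be informative (the same 15-nt scale as the partial-match
threshold).  Additional mammalian/microbial contaminant sets are passed
as extra subtraction FASTAs with the same budget; no curated list is
shipped.

## Synthetic data

The generator emulates the statistical structure the screens assume;
one integer seed fixes every draw end to end.

- **Counts.** Background candidates draw library totals
  Poisson(`background_rate`, default 0.2 — most samples 0, a minority
  1–3 reads); host-derived candidates draw
  Poisson(`host_abundance_mean`, default 1100, matching the observed
  abundant-candidate scale over ~190 libraries).  Totals are split
  uniformly-multinomially across each library's runs, so merging
  recovers them exactly.  Batch effects are a per-study multiplier on
  the background rate.  Poisson (not negative binomial) is a documented
  simplification; overdispersion beyond the batch multiplier is not
  modelled.
- **Study layouts.** `simulate_two_study_design` produces the reference
  layout: 192 plasma libraries × 2 runs (2 libraries with a single run,
  dropped at merge → 190) plus a single-run mixed study of 17 cell and
  6 plasma samples, jointly 198 plasma libraries.
- **References.** Planted host-side regions realize each candidate's
  configured level: verbatim copy (`exact`, alternately planted
  antisense), full-length copy with exactly one substitution (`near1`),
  or a window sharing exactly the candidate's first 15 nt with *every*
  subsequent position deliberately substituted (`partial15`) — the
  forced substitutions keep a planted fragment from drifting into an
  accidental near-match, which matters because several real candidate
  sequences share 14–19 nt with each other.  Foreign references contain
  all candidates verbatim.
- **Reads.** Host reads are reference windows with 0–2 injected
  substitutions (always within the subtraction budget); foreign reads
  are verbatim foreign windows, rejection-sampled so none also matches a
  host reference within budget; noise reads are random, rejection-sampled
  away from both sets.  Ground-truth filter categories are therefore
  exact by construction, and the tests require exact recovery.

What passing on synthetic data does *not* show: robustness to
overdispersed counts, adapter contamination, quality-correlated errors,
ligation bias, or indel-bearing reads — none of which the generator
emulates.

The packaged fixture (`xenomir.fixtures`) pins the 15 recurrent
candidate sequences with their published per-study count summaries and
annotation biotypes, planted into deterministic synthetic host
references at their documented match levels.  The host references are
labelled synthetic stand-ins: they reproduce the published *category
pattern* (exact / partial / 1-mismatch / none, one antisense), not the
real human transcript coordinates.

## Numerical and interface choices

- Integers throughout the count path; medians may be half-integers.
  Display rounding (1 decimal for means and rpm) happens only at the
  TSV boundary; internal computation is full precision.
- The sample-fraction ceiling uses a 10⁻⁹ epsilon so that binary
  floating-point noise cannot push an exact boundary (0.10 × 10 = 1)
  over the ceiling.
- TSV everywhere, UTF-8, Unix newlines; outputs staged and atomically
  renamed; every output directory carries a sha256 manifest so reruns
  are verifiable byte for byte.
- Config files are YAML with sections `screen` / `match` / `filter` /
  `sim` mirroring the dataclass fields exactly; unknown sections or keys
  are hard errors (a silently ignored threshold typo would change
  results).
- Problem sizes in the test suite: matcher oracle sweeps use 200 random
  instances with candidates ≤ 30 nt and references ≤ 2 kb; Monte-Carlo
  count checks use 100 replicates of the 190-library layout; end-to-end
  recovery uses 20 seeds; the read-filter ground-truth check uses 1000
  reads.  These sizes make the distributional claims testable at desk
  scale while keeping the suite fast.

## Known limitations

- Ungapped matching only; an indel-bearing host copy of a candidate
  would be under-called (`PARTIAL` at best).
- The background model is a stand-in: the true count distribution of
  contaminant reads in real studies is unknown and likely heavier-tailed
  than Poisson.
- Annotation is a static input table; no live database queries.
- Host references are user-supplied FASTA at desk scale; genome-scale
  subtraction (full human genome) needs a real aligner and is out of
  scope.
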