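# Methods

`repeatscape` characterizes the repetitive complement ("repeatome") of plant
genome assemblies: homology-based repeat masking against a classified
consensus library, microsatellite (SSR) cataloging, de novo structural
discovery of LTR retrotransposons with target-site-duplication (TSD), primer
binding site (PBS), polypurine tract (PPT) and coding-capacity annotation,
family assignment by the 80-80 rule, genome copy-number estimation, and
molecular dating of elements from the divergence of their two LTRs.  A
synthetic genome generator with a machine-readable truth table defines the
conditions under which every stage is validated.

All internal coordinates are 0-based half-open; GFF3 output converts to
1-based inclusive.

## The synthetic genome generator

The generator emulates the statistical structure the analysis assumes, not
any particular genome:

* **Background** — i.i.d. nucleotides with a GC dial (default 0.46, a typical
  value for a Triticeae chromosome arm).  Higher-order composition is a
  non-goal: none of the downstream detectors conditions on dinucleotide
  structure.
* **LTR retrotransposons** — 5'LTR + internal + byte-identical 3'LTR at build
  time.  LTRs carry the canonical 5'-TG…CA-3' termini.  The internal region
  starts with an 18-nt PBS exactly complementary to the 3' end of a
  designated tRNA and ends with a 15-nt purine run (PPT) immediately before
  the 3'LTR.  The *autonomous* kind embeds a single long ORF encoding the
  GAG-AP-INT-RT-RH domain set; the *TRIM* kind has a non-coding internal in
  which stop codons are planted so no reading frame on either strand runs
  longer than 90 codons.
* **Other repeats** — TIR DNA transposons (13-bp terminal inverted repeats),
  satellite arrays (exact monomer tandems), perfect SSR tracts, and
  low-complexity runs over 1-2-letter alphabets.
* **Aging** — an element of age `A` years has each of its two LTRs (and its
  internal region) mutated independently, each site substituted with
  probability `m = r·A` uniformly to one of the three alternative bases,
  with `r = 1.36e-8` substitutions/site/year.  The expected LTR-pair
  divergence is therefore `2m(1-m) + (2/3)m²` — the small-age limit is the
  `2rA` that the dating stage inverts, and the quadratic correction is below
  half a percent (relative) for ages up to ~1 Myr and ~3% at 3 Myr, well
  inside the dating tolerance.  Substitutions only by default; indel-free
  divergence is deliberate, because LTR dating by `T = K/2r` assumes point
  mutations.
* **Insertion mechanics** — a fresh random TSD of the requested length (0 or
  4-6 bp) is duplicated on both flanks; nested insertions splice
  `TSD+guest+TSD` into the host element, the truth table keeps the host as
  one logical record with a `nested_in` back-pointer on the guest, and all
  coordinates (including LTR sub-intervals) are shifted so that slicing the
  final genome at any truth interval reproduces the stored feature sequence
  exactly.  The tRNA set and protein-domain library used for planting are
  synthetic, generated with fixed seeds, and written alongside the genome so
  that detection runs against exactly the planted words.

Positions in `plant_insertions` refer to the original background (nested
positions to the host element); positions in `plant_ssrs` /
`plant_low_complexity` refer to the genome as passed in, and existing truth
records are shifted in place.

## Homology masking

The masker aligns every library entry (both strands) against the target with
exact 11-mer seeds expanded into **gap-free** maximal-scoring diagonal
segments (match +1, mismatch −1, N never matches), then resolves overlaps and
rolls the survivors up into per-category counts, masked lengths and
percentages.

Gap-free alignment is a deliberate choice, not a shortcut: under the
package's substitution-only divergence model every true homology segment
lies on a single diagonal, where the maximal-scoring segment *is* the optimal
local alignment.  This makes the seeded scan provably equivalent to an
exhaustive scan of all diagonals with the same thresholds —
`mask_sequence_oracle` implements that quadratic scan and the equivalence is
asserted on small inputs.  The equivalence assumes the inputs are not
internally periodic (the seeded scan skips a diagonal whose band is ≥98%
covered by already-accepted segments of the same entry, which only triggers
inside tandem arrays, where the oracle's extra segments are phase-shifted
duplicates of the same coverage).  Indel-tolerant comparisons are used where
they matter (library redundancy, family rules, dating), via edit-distance
alignment.

Defaults `min_score=225`, `min_identity=0.70` are conventional masker-like
cut-offs; both are exposed.  Overlaps are resolved deterministically: higher
score wins the contested bases, ties broken by identity, then length, then
entry id; a loser keeps only its longest remaining stretch, so slivers do not
inflate element counts.  Low-complexity sequence is flagged separately as
merged 64-bp windows with mononucleotide Shannon entropy ≤ 1 bit, and SSR
loci from the SSR stage join the summary as the "Simple repeat" category.
Library redundancy removal clusters greedily longest-first, joining a
shorter entry to a representative when a glocal (infix) alignment of the
shorter inside the longer reaches ≥95% identity — coverage of the shorter is
1.0 by construction, the CD-HIT-style convention used for all
identity/coverage rules here.

## SSR catalog

Perfect tandem tracts with unit 1-6 nt, reported maximal and under the
smallest explaining unit (a tract whose motif is itself a tandem of a
shorter unit belongs to that unit).  Motifs are canonicalized to the
lexicographically smallest string among all rotations of the motif and of
its reverse complement, so (GA)n and (TC)n collapse.  Default minimum copy
numbers: mono ≥ 10, di ≥ 6, tri/tetra/penta/hexa ≥ 5 — common SSR-survey
practice; imperfect/compound SSRs are out of scope.  Classes are
compositional: AT-rich (> 50% A/T), GC-rich (> 50% G/C), AT/GC-balanced
(exactly 50%; only even unit sizes can reach it).  A strict switch restricts
the balanced class to di- and tetranucleotides; under it, a balanced hexamer
is binned GC-rich — an arbitrary but fixed tie resolution, recorded here
because no compositional argument favors either side.  Frequencies are
reported as "one SSR per N kb" (total length / count / 1000).  A brute-force
per-position extension scan (`find_ssrs_oracle`) validates the vectorized
caller exactly.

## Structural LTR discovery

Candidate LTR pairs come from forward-strand self-comparison: exact 13-mer
seeds shared by two positions whose distance lies in the detector box
(min/max LTR length 100/2000, min/max internal distance 1000/15000 — the
minimums are standard LTR_FINDER-style settings, the maximums bracket
observed plant elements with headroom) nominate a diagonal; the
maximal-scoring gap-free segment there (match +1, mismatch −2; the stiffer
mismatch penalty keeps random-flank score excursions short, so statistical
boundaries stay within a few bp of the planted ones) is a putative LTR pair
if it satisfies the box and the minimum LTR-pair similarity (0.80).
Segments whose "LTR" k-mers recur three or more times inside the element are
rejected as tandem-array artifacts.  Overlapping candidates are resolved by
highest similarity × total LTR length, ties to the earlier, shorter
candidate.

The pair search is orientation-blind — a two-LTR element presents its LTRs
as direct repeats on either strand, so a forward self-scan finds
minus-strand elements at the same coordinates and rescanning the reverse
complement would only duplicate every candidate.  Orientation is assigned
afterwards from PBS/PPT support on the two possible readings (ties default
to plus).

**Boundary refinement and TSD detection.**  The statistical segment boundary
wanders a few bases around the true LTR terminus (terminal mismatches trim
it, chance flank matches extend it), so boundaries are refined on structural
signals, in the way dedicated structural finders do:

1. LTR termini snap to 5'-TG…CA-3' dinucleotide anchors, accepted only when
   *both* LTR copies show the motif at the same diagonal offset (a false
   anchor is a 1/256-per-offset event); nearest anchor wins.
2. The PBS abuts the 5'LTR and the PPT abuts the 3'LTR in a canonically
   primed element, so a detected PBS pins the element *end* (through the
   pair diagonal) and a detected PPT pins the element *start*; these become
   additional point anchors.
3. TSD detection tries all anchor pairs — motif anchors (quality 2), PBS/PPT
   pins (quality 1), and, only for an end with no motif anchor exactly at
   its statistical boundary, a ±4 bp window (quality 0) — and reports the
   longest exact 4-6 bp flank duplication at the pair with the best combined
   anchor quality, then longest, then smallest shift.  The winning anchor
   pair becomes the element boundary.

On an element whose termini are intact the anchor set collapses to the
single true boundary pair and the chance of calling a TSD on random flanks
is ~0.5%; the windowed fallback (needed because terminal motifs themselves
mutate with age) raises that null rate somewhat on degraded elements — the
price of keeping exact-TSD recovery high at ages up to 3 Myr.

PBS: best reverse-complement exact match (≥12 nt) between the 3' end of any
tRNA and the region within 20 bp downstream of the 5'LTR (the search starts
6 bp inside the LTR to tolerate boundary overshoot); ties go to the
lexicographically smallest tRNA id.  PPT: best 15-nt window within 30 bp
upstream of the 3'LTR with purine fraction ≥ 13/15, ties to the window
closest to the LTR.  Coding capacity: six-frame translation of the internal
region searched with 4-mer-seeded, gap-free amino-acid alignments against
the domain library; the element is autonomous when the hits jointly cover
≥ 80% of the library's total length, otherwise non-autonomous and binned by
element length (TRIM ≤ 4 kb < unknown < LARD > 5.5 kb; the thresholds are
configuration, since published TRIM families stretch the size conventions).
Copia vs Gypsy is inferred from INT/RT order in the best-supported frame
only — no phylogeny.  Head-to-tail runs of same-family candidates (gap ≤ 30
bp, LTR identity ≥ 0.8) are flagged as tandem arrays; within a perfect
tandem the element phase is ambiguous by a few bases because every flank
window recurs at the array period.

## Family rules, copy number, membership

Two elements are one family when they are ≥ 80% identical over ≥ 80% of
their internal/coding regions, or of their LTRs, or both; identity is
matches over alignment columns of the shorter region aligned glocally inside
the longer (coverage of the shorter = 1.0).  Decisions are reflexive and
symmetric but not assumed transitive; families are connected components
under single linkage.  Candidate redundancy uses the same machinery at
95/95, greedy longest-first.  Novelty filtering excludes a candidate when
any library entry passes the family rule against it.  Copy number counts
non-overlapping genomic hits (both strands, seeded diagonal scan) with
identity ≥ 0.80 and hit length ≥ 0.80 of the element.  Where the original
analyses relied on manual inspection, an explicit margin rule substitutes: a
genomic hit is a family member when it matches the probed family exclusively
or with identity at least 10 percentage points above any other family (the
margin is configuration; all such decisions are logged).  All thresholds are
inclusive, with a 1e-9 float guard.

## Dating

`T = K/(2r)` with `r = 1.36e-8` substitutions/site/year.  `K` is the
p-distance of the globally aligned LTR pair — mismatches over gap-free
columns — either raw (default) or Jukes-Cantor corrected
(`K = -(3/4)·ln(1 - 4p/3)`, undefined at p ≥ 0.75).  Raw p is the default
because at the divergences where LTR dating is informative the JC correction
is second-order, and the model used is always recorded in the output.
Equal-length LTR pairs are compared positionally: under substitution-only
divergence the gapless alignment is the correct global alignment, whereas an
edit-distance aligner may explain two adjacent mismatches as an equal-cost
indel pair and deflate the distance.  Unequal lengths fall back to
edit-distance global alignment with gap columns excluded.

## Pipeline and evaluation

`run_pipeline` fixes the stage order to the discovery funnel — mask → SSR →
structural scan → dedup (95/95) → novelty filter (80/80) → annotate/classify
→ copy number → dating — writes every table plus a JSON run log of all
parameters (no timestamps, so reruns are byte-identical), and, when a truth
table is supplied, scores predictions: a prediction matches a truth record of
the same class when the intervals reciprocally overlap ≥ 80% and both
boundaries are within ±10 bp, with ties resolved by maximum bipartite
matching (Hopcroft-Karp).  Precision/recall per class, boundary-error and
age-error distributions, TSD exact-match rate and an autonomous/TRIM
confusion table are reported.

## Validation suites and problem sizes

`repeatscape.benchmarks` regenerates every validation scenario from a seed:
the divergence law (200 replicates, 500-bp LTRs, age 1 Myr; mean p-distance
within 3 binomial SE of 2rA), masking recovery on a 2-Mb genome with ~60%
planted repeat content (total masked % within 2 points of truth, exact
copies to ±10 bp), seeded-vs-exhaustive masking equivalence (20 small
cases), the SSR brute-force oracle (10 × 100 kb) and exhaustive
canonicalization (units ≤ 4), LTR recovery (40 single-copy elements, LTRs
100-1100 bp, internals 1-10 kb, ages ≤ 3 Myr, ≥ 90% recovered to ±10 bp,
TSD exact ≥ 95%) and false positives (2 Mb repeat-free, ≤ 1/Mb), dating
recovery (median estimate within 20% per age at 0.5/1/2/3 Myr × 100
replicates), two-family partition recovery (20+20 members, 85% within / 65%
between), threshold-edge arithmetic, and end-to-end determinism.  These
sizes are the package's standard validation conditions; `tests/` asserts
them and `scripts/acceptance.py` re-measures and reports them.

What passing says — and does not say — about real data: the generator has no
indels, no sequencing or assembly error, no collapsed tandem repeats, no
solo LTRs, no truncated or heavily decayed elements, and single-copy
families in the recovery suites.  Performance on real chromosome-arm
assemblies, where all of those occur, will be lower, and absolute repeat
fractions or SSR frequencies measured here do not transfer.

## Known limitations

* Gap-free masking under-recovers homology across real indels; the library
  dedup/family stages, which use edit-distance alignment, do not share this
  limit.
* TSD reporting inside perfect tandem arrays reflects array periodicity, not
  integration-site duplication.
* Strand assignment relies on PBS/PPT detectability; an old element with
  degraded signals defaults to plus.
* The membership margin (10 points) quantifies a qualitative published
  practice; results near the margin are sensitive to it.
* JC dating saturates at p ≥ 0.75; both models understate ages where
  back-substitutions matter (> ~10 Myr at this rate).
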