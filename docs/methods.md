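# Methods

This note documents the models and numerical choices behind
`paraprimer`, what the synthetic-data generator does and does not
emulate, and the decisions taken where the procedure left room.

## Local search and its statistics

`local_search.search` is a seed-and-extend nucleotide aligner: 12-mers
shared between query and genome (both strands) seed diagonal bands
(± 10), each band is extended by banded affine-gap Smith–Waterman with
blastn-like scoring (match +1, mismatch −2, gap open −5, gap extend
−2), and significance is reported as an e-value through a
Karlin–Altschul-style surrogate: bits = (λ·S − ln K)/ln 2 with λ = 1.28,
K = 0.46, and E = m·n·2^(−bits) with n counting both genome strands.
These constants are an internal calibration chosen so that a 24 bp
exact hit sits just below the 10⁻⁵ design cutoff while a 20 bp hit does
not; absolute e-values are *not* comparable to any particular BLAST
build, and nothing downstream depends on more than thresholds and
orderings. All scoring constants live in `config.py`.

One consequence worth knowing: under this scoring each SNP between a
hit and the best hit costs 3 raw score points ≈ a factor e^(1.28·3) ≈ 46
in e-value, so the "discard hits more than 10¹⁰ worse than the region
best" rule tolerates roughly six mismatches. Sibling paralogs beyond
that envelope produce no category-1 prediction — the behaviour is the
stated filter, not a bug, but it means category-1 recovery depends on
flank length × divergence.

The band (± 10) bounds detectable indel offsets; the FST and primer
use-cases are substitution-dominated, and the test oracle (unbanded DP
on reported substrings) confirms exactness within that regime.

## Categorised FST predictions

The predicted insertion position is the subject coordinate aligned to
the hit's T-DNA-proximal query terminus — FSTs read from the junction
into the genome, so that terminus is the low query offset (which maps
to the *high* subject coordinate on minus-strand hits). Region
segmentation uses ≥ 30 bp query overlap (transitive closure), borrowed
from the grouping rule since no separate threshold is stated.
Category-1 capping (3 per region) and the 10¹⁰ e-value filter apply
only to category-1 selection; the single best hit is never filtered.
Predictions closer than 1000 bp collapse to the better e-value, and the
same collapse is applied across a line's FSTs before grouping (two
predictions 600 bp apart cannot be distinct insertions by the stated
distance rule, whichever FST produced them).

## Paralog groups

Merging is to a fixpoint under the all-pairs condition (same FST
region, or flank identity > 0.79 strictly), which makes the result
independent of merge order; when several merges are admissible the pair
with the highest minimum cross-pair identity merges first, affecting
only intermediate states. Flank identity is matches / alignment
columns of a global alignment (Biopython `PairwiseAligner`, same
+1/−2/−5/−2 scoring) of the 400 bp flanks on the FST-proximal side of
each prediction — the side the evidence covers; a both-sides variant
was considered and rejected as it would claim symmetry the FST does not
attest. Flanks truncate at chromosome ends. Groups need ≥ 2 members.

## Primer arithmetic

* Tm = 81.5 − 11.6 + 0.41·%GC − 600/len (the −11.6 term is a fixed salt
  correction; no Na⁺ parameter is exposed). Valid from 12 nt.
* Quality flags: GC clamp = 1–3 G/C in the last 5; runs — a homopolymer
  of exactly 5 passes, 6 fails (`max_run = 5`; the procedure's two
  descriptions disagree between "more than 5 fails" and "less than 5
  passes", and the point-scheme figure carries the former); GC content
  in [40, 60]; hairpin — the reverse complement of the last 5 bases may
  not occur anywhere in the primer (the stricter of the two stated
  scopes; a first-5-only check would be a config relaxation).
* Elongation grows a primer 5'-ward from a fixed 3' base, lengths
  18–30, choosing the length with Tm closest to target and rejecting
  the position if the best is > 3.0 °C off. The 18/30/3.0 values are
  package choices (unstated in the source procedure): 18–30 nt is the
  practical PCR primer range and ± 3 °C is where a primer stops being
  usable at the requested annealing temperature. Regions containing N
  and elongations that would leave the chromosome yield no candidate.
* Points: 8/4/2/1 for the four flags plus 1 per discriminating
  mismatch; retention needs ≥ 15.

## Standard design method

Phase 1 runs over the hit-free subsegment found during method selection
with ≥ 80 bp windows (30 bp overlap); phase 2 over the whole zone with
≥ 110 bp windows. Within a window, candidate 3' ends are enumerated
exhaustively, each elongated at the stepped temperature (0, −0.4, +0.4,
… ± 1.2 °C, closest-first — the stated range, with order a package
choice), and all four flags are required. The first unique
(3'-12-mer count = 1) candidate ends the search (best ΔTm, then
leftmost, within its window/step); otherwise the candidate with the
fewest 12-mer hits over the whole run is returned. Because uniqueness
is a property of the 3'-end position alone, exhaustive 3'-end
enumeration makes the method complete at desk scale: if any admissible
unique placement exists, a unique primer is returned (asserted against
an enumeration oracle in the tests).

## Windowed progressive MSA and the paralog method

Hits ≥ 50 bp at cutoff 10⁻⁵ (self-hits masked) are elongated,
strand-aware, to the zone's length and clamped at chromosome ends;
truncated rows are N-padded so they stay in register, and N columns
count as mismatches (absent sequence cannot anneal either). Alignment
is windowed (~220 bp, 30 bp overlap, a trailing stub folds into the
previous window): pairwise identities → UPGMA guide tree (scipy average
linkage) → profile–profile global DP with sum-of-pairs scoring
(match +1, mismatch −1, base-vs-gap −2, gap–gap 0). Window overlaps are
reconciled by keeping the earlier window's columns — the simplest rule
that preserves "every reference base in exactly one column", which the
tests assert. A gap in a paralog row counts as a mismatch.

Candidate 3' ends are reference columns ordered by descending mismatch
count, ties toward the zone centre (keeps amplimers near the requested
distance band) then leftmost; when fewer than 20 discriminating columns
exist, zero-mismatch columns are appended so near-identical paralogs
degrade to standard-like behaviour instead of failing. Mismatch points
credit the per-column counts over the primer's 3'-terminal 5 reference
positions (`mismatch_window = 5`, matching the clamp window; a value of
1 reproduces a terminal-only reading). Enumeration caps at 200 columns.
Candidates below 15 points are discarded; the first unique candidate in
column order wins, else the fewest-hits candidate.

`confirm_locus` ranks candidate loci by local-alignment raw score of a
sequenced amplicon (same +1/−2/−5/−2 scoring), so each covered SNP
separates the true locus from its sibling by 3 points; equal top scores
are "ambiguous", no ≥ 50-column alignment is "unconfirmed".

## Designer

Zones are left = [t − max_dist, t − min_dist) and right =
(t + min_dist, t + max_dist] (1-based target t), forward primer on the
plus strand of the left zone, reverse on the minus strand of the right
zone; defaults 300–800 bp per side, bounds 100–1500 with ≥ 100 bp range
per side, target Tm default 60.5 °C within [50, 72]. Product size is
the amplimer span on the reference, forward 5' end to reverse 5' end
inclusive. Additional pairs re-run the design with prior primers
excluded. Genotyping output pairs (forward, reverse) as the wild-type
assay — amplicon only when no insertion interrupts the amplimer — and,
given a user-supplied T-DNA border primer sequence, (forward, border)
and (border, reverse) junction assays; border primers are never
designed. Gene-ID targeting resolves through an optional GFF3 to the
gene midpoint.

## Synthetic data: the stated world

`generate_genome` plants paralog families as copies of an ancestral
segment in i.i.d. uniform background; `divergence` is defined as the
expected *pairwise* per-base divergence between members (each copy
mutates at divergence/2 from the ancestor), so `divergence = 0.05`
realises ~95% pairwise identity — the quantity the grouping rule and
flank-identity checks consume. Members sit ≥ 1000 bp apart so the
distance rules are exercised. Mutation is substitution-only by default:
the discriminating signal the designer exploits is SNPs, and indels
would complicate truth bookkeeping without adding coverage.
`simulate_insertions` draws uniform positions away from chromosome ends
and keeps one line's insertions ≥ 2 kb apart — on a real-genome scale
two independent integrations essentially never fall within 1 kb, and
on toy genomes uniform draws would otherwise collide with the
same-insertion merge rule. FSTs are assembled flank sequences (the
granularity the mapping operates on) with i.i.d. substitution errors;
composite FSTs concatenate two flanks of one line, the shorter
(stronger-signal) flank first at a 40/60 split. No read-level artefacts
(quality values, adapters, chimeric junk) are simulated, so a green
test establishes algorithmic correctness on clean assembled FSTs, not
robustness to raw sequencing noise.

## Determinism and performance

All randomness flows through `numpy.random.default_rng(seed)`; searches
and designs are deterministic for fixed inputs, with explicit
tie-breaking (e-value, score, coordinates) everywhere a "best" is
chosen. The DP inner loops are numba-jitted when numba is available
and fall back to identical pure-Python code otherwise. The 12-mer
index stores exact plus-strand counts keyed by the genome fingerprint
(names, lengths, CRC) and is rebuilt automatically when stale; 3'-end
queries are duplex-aware (k-mer + reverse complement) because a
mispriming site exists on both strands of the template — a plus-strand-
only count would be the natural config variant.

## Known limitations

* E-values are internally consistent but not portable to BLAST outputs.
* The banded extension misses alignments with indel offsets beyond
  ± 10 from the seed diagonal.
* Category-1 recovery is bounded by the 10¹⁰ e-value factor (~6
  mismatches under this scoring); highly diverged siblings surface only
  through the grouping flank-identity route.
* The MSA is progressive without iterative refinement; pathological
  window boundaries could split a mismatch cluster, mitigated by the
  30 bp overlap.
* Primer pairs are designed per side; no joint pair optimisation
  (dimer ΔG, product-size preferences) is attempted.
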