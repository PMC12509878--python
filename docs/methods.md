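# Methods

## The mapping model

`ncmap` maps reads produced by nucleotide-conversion chemistries. A
conversion scheme is an ordered base pair (from → to): C→T for bisulfite
data, T→C for SLAM-seq, any other ordered pair for other chemistries.
Applying the scheme to both reference and reads projects the problem into
a three-letter alphabet in which a true chemical conversion is invisible
to the aligner, while sequencing errors and variants still cost edits.

Conversion does not commute with reverse complementation, so the
reference is indexed twice: once as convert(ref) and once as
convert(revcomp(ref)). A read is likewise queried in two converted
variants (read and its reverse complement), giving four query streams
whose combination determines the mapping strand. Mapping strand alone
does not determine how conversions appear in forward-reference
coordinates: the second mate of a fragment from the forward strand maps
to the reverse strand yet still shows the scheme pair (e.g. reference C
over read T), whereas a first mate from the reverse strand shows the
complementary pair (reference G over read A). The pipeline therefore
tracks, per mapping, the strand the chemistry acted on (`conv_strand`),
inferred from whichever chemistry-consistent alignment orientation fits
better; conversion counting and the deviation statistics use that strand.

### Index

- Window length `w` = 64 bp, k-mer length `k` = 16, sketch size `s` = 16.
  Windows overlap by `k`−1 bp (stride `w`−`k`+1 = 49), so every k-mer of
  the reference belongs to exactly one window; a final window shorter
  than `w` is kept while it still holds a k-mer.
- Per window, the bottom-`s` MinHash sketch retains the `s` smallest
  *distinct* h₁ values over its k-mers (standard bottom-s sketching;
  k-mers containing N are skipped). Sketch overlap estimates the k-mer
  Jaccard similarity between read and reference windows.
- h₁ and h₂ are splitmix64-style 64-bit mixers derived from a single
  `hash_seed` (default 42). Features are stored and compared in h₂ key
  space, giving one canonical key space for insertion and lookup.
- Features occurring at more than `max_locations_per_feature` = 256
  reference locations are treated as over-represented (repeat-derived)
  and contribute no hits at query time; set to `None` to disable.

### Candidate selection

Hits from all window sketches of a query variant are merged into a single
(target, window)-sorted stream. For each anchor hit, the placement
spanning at most as many windows as the read itself is scored by the
number of hits it contains; placements with at least `t` = 4 hits
qualify. Overlapping qualifying placements are merged keeping the
highest-scoring one (ties: leftmost, then shortest); the per-read
candidate list is deduplicated across query streams (same target and
strand, overlapping spans → best hit score wins) and capped at 16
candidates. `t` trades sensitivity for speed and is exposed as
`--hit-threshold`; it must stay well below `s`.

For paired input, mate candidates on the same target with opposite
strands whose combined span fits within `max_insert` = 1000 bp accumulate
their hit scores; each mate's candidate list is re-ranked by the best
combined score before alignment.

### Alignment

Each candidate region (tight window span padded by one read length on
both sides, clipped to the target) is aligned semi-globally: unit edit
costs, region end-gaps free, query consumed entirely. The dynamic
programming is delegated to edlib; the module owns the contract — among
equal-distance placements the leftmost is reported (exact infixes via a
string-search fast path, otherwise the leftmost edlib location is
re-aligned globally to obtain the CIGAR). Both chemistry-consistent
orientations of every candidate are aligned and the lower-distance one
kept. The normalised score is 1 − edit_distance / read_length; mappings
scoring below `min_score` = 0.8 (≈ at most 20% edits) are dropped, which
also bounds the edlib search (`k` = ⌊0.2·read_length⌋). Alignments from
reverse-complement frames are mirrored so records always describe the
forward reference strand.

### MSA statistics and filter

Alignments are grouped by (target, window-of-start): reads whose mapping
starts fall in the same stride-49 reference window share one region. Per
region the original-alphabet reference subsequence and up to 16 read rows
(highest score first; ties by read id) form an MSA; insertion columns are
shared blocks sized by the longest insertion at that position.

- Column statistics: coverage, base percentages, most common nucleotide
  M (ties resolved toward the reference base, then alphabetically),
  whether M agrees with the reference, and a consensus where M's relative
  frequency is ≥ `consensus_threshold` = 0.8.
- Read statistics: alignment score; percentage of the read's non-gap
  columns deviating from the reference and from the consensus.
  Differences matching the expected conversion on the mapping's
  `conv_strand` are *not* deviations — counting them would erase the very
  signal that separates conversions from errors. A flag
  (`conversions_are_deviations`) restores the naive behaviour.
- Global statistics: read count, min/mean/max alignment score.

The nine-dimensional feature vector per mapping (score, %dev-ref,
%dev-consensus, n_reads, min/mean/max score, fraction of columns where M
agrees with the reference, fraction with defined consensus — the order is
recorded in the model file) feeds a random forest: 100 trees, depth 12,
Gini impurity, bootstrap resampling, √d feature subsampling (scikit-learn
behind the `ForestModel` surface). The ensemble probability is the mean
of per-tree class probabilities; a mapping is kept when the positive
probability is ≥ 0.5 (the boundary keeps). A read alone in its region
bypasses the forest and is filtered by `min_score` only, as is every read
when the filter is disabled. Reads beyond the 16-row MSA cap fall back to
the score rule. Because the features summarise the whole region, a
mapping's fate legitimately depends on its co-mapped reads.

Training labels a mapping positive when its span overlaps the read's true
origin by at least 90% of the read length on the correct target and
strand; only multi-read regions contribute instances (singletons never
reach the forest).

## The simulator

`simulate_reads` emulates the two standard benchmark regimes:
paired-end bisulfite reads (100 bp, 50% conversion per cytosine of the
originating strand, 0.2% per-base substitution error, insert ~
Normal(300, 25) truncated at the read length) and single-end SLAM-seq
reads (2% T→C, fragments drawn from the 3′-terminal 250 bp of each
transcript). Conversions are applied to the fragment in its sequenced
orientation — both mates derive from the same converted strand, so mate 2
carries complementary-pair conversions, exercising the `conv_strand`
machinery. Errors are substitution-only (uniform among the three other
bases), applied after conversion; no indels, quality profiles, PCR
duplicates or methylation-context (CpG/CHG/CHH) structure are modelled.
Every read carries a truth record (origin span, strand, planted
conversion and error counts), and identical seeds give byte-identical
output.

`random_genome` produces the synthetic references: i.i.d. sequence at GC
0.41 (human-like) with 5% of the sequence covered by repeat families —
segments of 300–2000 bp copied to 2–4 locations with per-copy divergence
drawn uniformly from 0–5%, mimicking repeat families of mixed age.
Repeats are what make mapping hard: they produce the multi-mapped reads
and false-positive mappings the filter stage exists to prune. What
passing tests on this generator demonstrate is correctness of the
machinery (windowing, sketching, candidate logic, 3N alignment,
conversion accounting, filter plumbing) — not performance on a real
genome, whose repeat landscape is both vastly larger and differently
structured (see Limitations).

## Evaluation

A reported location is correct when it overlaps the true origin by at
least 90% of the read length on the correct target and strand. A
multi-mapped read counts as correctly aligned if any location is correct;
unique metrics consider reads with exactly one reported location; all
rates are percentages of simulated reads (each mate counted separately).
The false-positive count is mapping-level: kept mappings that are not
correct.

## The replicate filter experiment

`scripts/acceptance.py` (and the corresponding acceptance test) runs
five replicates of: a fresh 2 Mbp synthetic genome, 25 000 simulated
pairs (≈ 5× coverage, mirroring a realistic whole-genome run), one
mapping pass, then two finalisations of the identical alignment set —
score-rule only versus forest filter (trained once on an independent
10 000-pair simulation) — and reports the mean percentage reduction in
false-positive kept mappings. These sizes are the package's chosen desk
scale; the experiment is deterministic given its seed.

The *magnitude* of the reduction is a property of the reference's repeat
landscape, not of the pipeline. On this generator's repeat model, most
false positives sit on diverged repeat copies whose elevated
deviation-from-reference/consensus statistics the forest separates
easily, so the measured reduction is large (most removable FPs are
removed). On a real mammalian genome the bulk of false positives come
from near-identical duplications that are statistically indistinguishable
from true mappings, leaving only a few percent of FPs removable. The
directional claim — enabling the filter strictly reduces false positives
at essentially unchanged sensitivity — is the portable result; the
percentage is not comparable across repeat landscapes.

## Numerical and determinism choices

- Coordinates are 0-based half-open internally; 1-based only in SAM.
- All tie-breaks are deterministic (candidates: score desc, target,
  position, strand; MSA membership: score desc, read id; primary
  mapping: filter probability, then score, then position). Reruns with
  the same inputs are byte-identical, and results are independent of the
  read batch size because region grouping happens only after all reads
  are aligned.
- Degenerate inputs: reads shorter than `k` are reported unmapped;
  reference records shorter than `k` are skipped at indexing; all-gap
  MSA columns have no most-common nucleotide and no consensus; an empty
  candidate or alignment set yields an unmapped record, never an error.
- Index files round-trip bit-exactly (.npz with a JSON header); model
  files embed the feature ordering, hyperparameters, seed and threshold.

## Limitations

- Single-process implementation; the design is batch-parallelisable but
  no threading is provided.
- No spliced or affine-gap alignment; transcriptome mapping treats each
  transcript as an unspliced target.
- No base-quality awareness, adapter trimming, duplicate marking, or
  per-cytosine methylation quantification.
- The synthetic repeat model under-represents near-identical segmental
  duplications; filter-efficacy percentages measured on it overstate
  what a real mammalian genome allows (discussed above).
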