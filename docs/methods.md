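# Methods

## Similarity metric

The scorer is pinned to the indel-family ratio, not classical
Levenshtein: `score(a, b) = 100·2·LCS(a,b)/(|a|+|b|)`, equivalently
`100·(1 − d_indel/(|a|+|b|))` where substitutions cost a deletion plus
an insertion. The probe-vs-read score is the maximum of this ratio over
*every* contiguous substring of the read (the "partial ratio"). This
exhaustive-substring maximum is the contract; the production
implementation (`probemine._kernels.partial_ratio_kernel`) reuses one
dynamic-programming row per window start and prunes window lengths
using the sound bound `score ≤ 200·m/(m+w)` (LCS ≤ probe length m), so
it provably returns the same value as enumeration. A deliberately naive
per-window reference scorer (`partial_ratio_bruteforce`) is kept in the
package and the two are compared exactly — on an exhaustive corpus of
all probes ≤ 6 bp over {A,C,G} against all reads ≤ 10 bp, and on
random pairs up to 25×150 bp — in the test suite. Fast partial-ratio
implementations in general string-matching libraries restrict the
candidate window set and can differ at edge windows; exact equality
with enumeration is the contract here, which is why the scorer is
written in-repo (as compiled numba kernels) rather than delegated.

Useful anchors of the metric for 20-mer probes (typical PCR primer
length): an interior single substitution scores exactly 95.0, two
interior substitutions 90.0, a single indel 100·38/39 ≈ 97.44. An *edge*
substitution scores ≈97.4 instead of 95.0, because a one-base-shorter
window trims the mismatch — a property worth knowing when interpreting
near-threshold scores. These anchors motivate the default screening
threshold of 100 and the recommendation to stay at 95 or above when
mismatch tolerance is wanted.

Scores are kept as floats and never rounded before the inclusive `≥
threshold` comparison. When the two strands tie, "+" is reported. Reads
are uppercased; `N` (or any non-ACGT character) in a read matches
nothing, which is the conservative behavior for ambiguous base calls.

## Probes

Probe panels are plain FASTA; the full header line after `>` (trimmed)
is the probe name, since published panels use descriptive multi-token
names. Sequences are uppercased; `U` is normalized to `T` (RNA-derived
primers) and inosine `I` to `N` (it base-pairs indiscriminately; one
bundled coronavirus primer carries it). Degenerate probes are expanded
into all combinations over {A,C,G,T} at parse time and cached, in a
fixed order (per-position alternatives A<C<G<T, rightmost fastest) so
outputs are deterministic. Expansion is refused above a configurable
cap (default 4,096 per probe) because degeneracy is combinatorial — a
refusal with an explicit override beats a silent memory blowup. The
bundled panels' worst probe expands to 96 sequences.

The probe length ladder (`build_length_ladder`) fixes the anchor's 5′
end and grows 3′-ward in `step`-base increments — the construction used
to study detection efficiency versus probe length. The bundled 105-bp
anchor around probe SK30 yields the 101-probe, 5–105 bp ladder.

## Sampling

The extraction ratio is an integer percentage r in [1, 100]. The target
count is `min(N, max(ceil(N·r/100), floor))` with floor 5,000 for
FASTQ and 1 for FASTA. Two decisions here were genuinely open: the
ceiling (guarantees ≥ 1 record at tiny N), and applying the floor
*before* capping at N (a 4,000-read file yields all 4,000 reads at any
ratio — never an error). Indices are drawn uniformly without
replacement and kept sorted, so extraction preserves original record
order; the seed is surfaced in the API and CLI (per-file seeds are
derived by hashing the file name with the run seed, so results do not
depend on input order). FASTQ extraction is double-pass — count, plan,
then copy raw 4-line blocks verbatim to a gzip temporary — and fails
loudly if the file changed between passes. FASTA files are sampled in
memory with no floor. Paired-end mates are treated as independent
files.

## Engine

Sampled records are scored in batches (default 500 records) against
the whole panel; batches can be distributed over a process pool whose
initializer hands each worker the panel once. Per-probe counts are
merged by elementwise addition, so results are bit-identical for any
worker count or batch size — asserted as a test invariant, not assumed.
A read matched by k probes contributes one count to each; a read
matching one probe on both strands counts once. Reads shorter than a
probe are excluded from that probe's scoring but remain in
`total_selected`, the single per-file denominator used for every
percentage; per-probe excluded counts are additionally reported, as an
extension. Unreadable or malformed files become failed entries with an
error note and zero counts; they never abort a run.

## Reporting

Per-file `<stem>_results.txt` (selected total, per-probe counts and
percentages, then per-read hit lines in the fixed column order
read_id / probe / score / strand), aggregated `total_results.txt`
(file / probe / matched / total / percent, tab-delimited, one header
row), and a `summary_result_<YYYYMMDD_HHMMSS>.txt` with the
configuration echo and elapsed time; the timestamp is injectable so
reruns can be byte-stable. Percentages are printed with four decimals:
real screens detect down to 0.01% and below, and two decimals would
round those to zero. Matched reads are exported one FASTA entry per
(read, probe) hit with header `read_id|probe|score|strand`. Plots —
the probes×files percentage heatmap (diverging blue–red colormap) and
per-file / per-probe bar charts, all 300-dpi PNG via the file backend —
are derived from the same table and carry no information of their own.

## Downsampling reliability

Observations pair a matched count at extraction x with the 100%
reference count for the same (probe, file); pairs with zero reference
are dropped (the detected proportion is undefined) and all remaining
observations are pooled unweighted into one ordinary least-squares fit
of y = 100·c_x/c_100 on x. Back-calculation inverts the fitted line;
relative error is 100·|estimate − actual|/actual. The error-decay
model `err(m) = A·e^(−B·log10 m)` is fitted by least squares after
log-linearization (ln err on log10 m), matching the exponential form
the relationship empirically takes, and inverted as
`m = 10^(ln(A/err)/B)`, rounded to the nearest integer. Inversion is
refused when the requested tolerance exceeds A (the model never
predicts that much error at m ≥ 1). These thresholds characterize one
dataset and panel; they are decision aids, not universal cutoffs, and
100% extraction remains the default when target abundance is unknown.

## Synthetic fixtures

The generator emulates exactly the features the matcher sees: read
length, base composition, planted probe occurrences with exact
substitution/insertion/deletion loads, and strand. Background reads are
drawn uniformly over {A,C,G,T} and rejection-sampled until the
*reference* scorer (not the production one) puts them strictly below
the fixture's threshold for every panel probe on both strands; planted
reads are redrawn until their in-read score equals the planted copy's
isolated score (flanking bases can otherwise enlarge the best window
and inflate the score) and they stay below threshold for all other
probes. The manifest therefore states exact expected counts for any
screening threshold at or above the certification threshold, and tests
assert equality, not approximation. Fixtures carry flat quality strings
("I") and none of the error profiles, quality structure, coverage
biases, or duplication of real sequencing data — passing tests
demonstrate correctness of the screening logic, not performance on any
real platform's error characteristics.

## Problem sizes and numerical choices

Test fixtures use hundreds of reads of 60–70 bp against panels of two
20-mers, the exhaustive oracle corpus uses the full {A,C,G} space up to
6-bp probes and 10-bp reads (~9.6×10⁷ pairs via a shared-prefix
enumeration oracle that is itself cross-checked against the naive
per-window scorer), the subsampling-floor check uses a real 200,000-read
file, and the downsampling round trip uses hypergeometric draws from
100,000-read files at abundances 30–10,000. These sizes make every
assertion exact or tight while keeping the suite fast. Error-decay
recovery tests use multiplicative lognormal noise at σ = 0.1 on the
log-error scale. All randomness is seeded; hypothesis property tests
run derandomized.

## Known limitations

No mapping coordinates, CIGAR strings, or quality-aware scoring — hits
say a probe-like subsequence is present, not where it maps. The partial
ratio is permissive for very short probes (a 5-bp probe matches
constantly); the ladder exists precisely to study that trade-off.
Counting is per read, so two occurrences in one read count once.
Subsampling is per-file and unstratified. The GUI-style interactive
workflow is out of scope; the CLI and library are the interfaces.
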