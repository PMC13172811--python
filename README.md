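# probemine

Probe-based fuzzy screening of raw FASTQ/FASTA sequencing reads.

`probemine` answers a simple question that comes up constantly in
diagnostic and surveillance work: *do these raw sequencing files contain
my target sequences?* — where the targets are short user-defined
nucleotide probes (published PCR primers, qPCR probes, custom
sequences, including IUPAC-degenerate ones). It screens reads directly,
with no alignment, reference genome, or database construction, and
reports per-probe matched-read counts and percentages per file. It is a
pre-alignment triage tool: positive hits are preliminary signals to be
confirmed by alignment-based follow-up, for which the matched reads are
exported as FASTA.

## The method

The similarity between a probe *p* and a read *r* is the **partial
ratio** under the indel metric:

```
score(p, r) = max over contiguous substrings w of r of
              100 · 2 · LCS(p, w) / (|p| + |w|)
```

where LCS is the longest-common-subsequence length. This equals
`100 · (1 − d(p, w)/(|p|+|w|))` with *d* the insertion/deletion edit
distance (a substitution costs one deletion plus one insertion), so an
exact occurrence of the probe anywhere in the read scores 100, one
substitution in a 20-mer scores 95.0, and one indel scores ≈97.4.
Every read is scored on both strands (the reverse complement of the
read is compared too) and, for degenerate probes, against every IUPAC
expansion; a read is a **match** when its best score is ≥ the
user-chosen threshold (inclusive). Reads shorter than a probe are
excluded from that probe's matching but stay in the reported
denominator. In practice a threshold of 95 or higher keeps the screen
specific while tolerating single-base variation.

Large FASTQ files can be screened on a uniform random subsample
(integer extraction percentage 1–100, with a 5,000-read floor,
double-pass so files are never held in memory). The `downsample`
module quantifies when that is safe: it calibrates detected proportion
against extraction fraction by linear regression (y = a·x + b),
back-calculates 100%-equivalent counts as `100·c/(a·x+b)`, fits the
relative-error decay `err(m) = A·e^(−B·log10 m)` against full-data
abundance *m*, and inverts it to the matched-read abundance needed for
a chosen error tolerance.

Everything is tested against an exhaustive-substring oracle and against
synthetic fixtures whose content is certified read-by-read, so counts
can be asserted exactly.

## Worked example

Generate a ground-truthed fixture — 30 reads of probe-free background
plus 4 planted copies of a beta-actin primer — then screen it:

```
$ cat fixture.json
{"n_reads": 30, "read_len": 60, "threshold": 100, "format": "fastq",
 "seed": 8, "panel": {"actin": "AGAGATGGCCACGGCTGCTT"},
 "plants": [{"probe": "actin", "copies": 4}]}

$ probemine fixture --config fixture.json --out fx/
INFO wrote fixture.fastq and manifest.json (4 planted copies)

$ printf '>actin\nAGAGATGGCCACGGCTGCTT\n' > panel.fasta
$ probemine screen --probes panel.fasta --input fx/fixture.fastq \
    --threshold 100 --out out/
INFO screening 1 file(s) against 1 probe(s)
INFO done in 0.1 s; outputs in out/

$ cat out/total_results.txt
file	probe	matched	total	percent
fixture.fastq	actin	4	30	13.3333
```

The screen recovers exactly the 4 planted copies among 30 selected
reads (13.3333%). `out/` also contains `fixture_results.txt` with the
per-read hits (read id, probe, score, strand), the matched reads as
`fixture_matched_reads.fasta`, a timestamped run summary, and — unless
`--no-plots` is given — a probes×files percentage heatmap plus
per-file and per-probe bar charts at 300 dpi.

Three probe panels used in published screening studies ship with the
package (`probemine.data.load_panel`): `hiv` (33 probes), `coronavirus`
(119 probes) and `kras` (21 probes), plus the 105-bp anchor for the
5–105 bp probe length ladder (`probemine ladder`).

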