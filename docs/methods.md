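# Methods

## Model and scope

The package treats cultivar identification as a pipeline over **dominant
presence/absence markers**.  A genotype matrix `G ∈ {0,1}^{C×M}` records,
for each of `C` cultivars and `M` markers, whether the marker's PCR fragment
amplifies.  Markers come from two sources: published InDel fragments
(genotyped externally and supplied as TSV) and retrotransposon insertion
sites discovered by transposon-display sequencing, which the package both
simulates and analyses.  Identification uses the conjunction rule only: a
marker set `S` identifies target `t` iff `G[t,m] = 1` for all `m ∈ S` and no
other cultivar has all of `S`.  Absence of a fragment is never used as
evidence *for* a cultivar, because on a dominant assay a missing band is
indistinguishable from a failed amplification; the *rbcL* positive control
exists precisely to separate "absent" from "PCR failed".

## Simulated transposon display

`simulate_landscape` draws the ground truth: flanking sequences are sampled
uniformly over ACGT and rejection-sampled so that every pair differs at ≥ 5
positions over the first 50 bases — more than twice the clustering mismatch
allowance, so the true partition is unambiguous.  A configurable fraction of
sites is made cultivar-specific (present in exactly one cultivar); the rest
are shared by ≥ 2 cultivars drawn uniformly.  `generate_reads` emits, per
present site and cultivar, exactly `depth` template reads of the form
`tag + flank (+ adapter remnant)`, truncated to 150 bp, then:

- substitutes bases independently at `error_rate`;
- replicates each template `U{1..3}` times (PCR duplicates);
- assigns each read a constant per-base quality from a two-point mixture
  (QV 38 with probability 0.95, else QV 20), enough to exercise a mean-QV
  filter without modelling per-cycle decay;
- optionally adds a fraction of off-target background reads (random
  sequence behind the same tag).  The default is 0: background levels are
  not a measured quantity, and the noisy analysis driver sets 1 % explicitly.

Read 1 only is simulated: the analysed object is the trimmed 50-mer flank,
to which a second read adds nothing.  Barcoding/demultiplexing is modelled
as one FASTQ per cultivar.  Fragment-size selection and fragmentase cut-site
structure are not modelled; indel sequencing errors are excluded (the
clusterer is substitution-only by design).

Defaults that mirror the emulated assay: 150 bp reads, QV ≥ 30 filter,
50 bp fixed trim, duplicate-collapse threshold 10, absence threshold 0.1 %,
clustering seed 8 / mismatch 2.  Flank length (100 bp), tag (30 bp) and
adapter (33 bp) are package choices sized so that a default read contains
tag + full flank + a trimmable adapter remnant.

## Preprocessing

Order is fixed: tag strip → adapter trim → quality filter → 50 bp trim →
duplicate collapse.

- **Tag strip**: reads must begin with the element-end tag (≤ 1 mismatch);
  others are dropped as off-target.  This step makes the downstream 50-mer
  a pure genomic flank prefix.
- **Adapter trim**: truncate at the leftmost adapter match; a match of
  length `L = min(|adapter|, bases to read end)` is accepted when exact over
  the full adapter or when `L ≥ 8` with ≤ 1 mismatch.  The mismatch
  allowance keeps trimming robust to simulated sequencing errors without a
  full alignment; the `L ≥ 8` floor stops chance 3'-end matches.
- **Quality filter**: retain reads with *mean* QV ≥ 30.  Mean-of-read is one
  of several defensible readings of a QV ≥ 30 filter; it is deterministic,
  matches the simulator's constant-QV reads exactly, and is the documented
  choice here.
- **Fixed trim**: keep the 50 bp prefix, discard shorter reads.
- **Collapse**: identical 50-mers with multiplicity ≥ 10 are reduced to
  multiplicity 1 (heavy duplication is treated as PCR amplification, not
  evidence); multiplicities below 10 are preserved as-is, since only the
  ≥ 10 case is part of the emulated protocol.  Collapse is idempotent and
  never changes the set of distinct sequences.

## Clustering

A deterministic greedy seeded-Hamming clusterer replaces external
self-alignment tooling: distinct 50-mers are processed in descending total
multiplicity (lexicographic tie-break); a sequence joins the earliest
cluster whose representative shares ≥ 1 exact 8-mer and lies within Hamming
distance 2, else founds a new cluster with itself as representative.  The
(8, 2) defaults carry over the tile-size / one-off intent of BLAT-style
clustering; score and repeat-masking parameters have no analog under pure
Hamming matching and are absorbed into these two knobs.  Representative =
highest-multiplicity member, a package convention.  Reads are clustered in
a single orientation: transposon-display read 1 always leaves the element
in the same direction, so reverse-complement matching is unnecessary.  An
8-mer inverted index makes the scan near-linear for well-separated sites;
the test suite checks the indexed implementation against a naive quadratic
restatement of the same rule.

## Genotyping

`call_presence` sets `G[c,s] = 0` iff `count(c,s) / total(c) < threshold`
(default 0.001), else 1 — a count exactly at 0.1 % is *present* under the
strict-inequality reading.  Fractions are computed on post-collapse
multiplicities within one cultivar's library for one retrotransposon
family, the only self-consistent base given that collapse precedes
clustering.  Cultivars with zero reads get an all-zero row plus a logged
warning.  Raising the threshold can only turn presences into absences
(monotonicity; property-tested).

Desk-scale caveat: the 0.1 % rule presumes totals in the millions, where
noise clusters fall far below threshold.  In small simulations (totals of
tens after collapse) any singleton exceeds 0.1 %, so noisy runs recover all
true site profiles but also call extra background clusters; exact
truth-matrix equality is asserted only for noise-free runs.  Passing tests
therefore demonstrate pipeline correctness, not noise robustness at
production scale.

## Marker-set search

`minimal_and_set` enumerates candidate subsets by increasing size `k` =
1..`max_k` (default 4: published sets have ≤ 3 members and the 4-line strip
bounds practice) over the target-present, non-control markers, in
lexicographic member order — ties resolve to the lexicographically smallest
set, a tie-break chosen here since minimum-marker tools do not publish
theirs.  Cost is `Σ C(M,k)`, trivial for panels of tens of markers; the
greedy fallback (`greedy_and_set`) handles large panels and never returns a
smaller set than the exact minimum.  When no unique set exists within
`max_k`, the best-covering set is returned flagged `unique=False`.  The
candidate pool can be restricted (e.g. to the fragments actually primed
into a kit), which is how the published three-marker 'Kanpei' combination
is reproduced even though the full 13-marker panel admits a 2-set.

## Kit simulation

`design_kit` places the positive control on line 1 and members on lines
2..4 in descending amplicon size (an invented but fixed convention — strip
line order is a manufacturing choice), enforcing ≤ 4 lines and pairwise
amplicon-size separation ≥ 30 bp (default; the gel non-overlap requirement
is qualitative, and 30 bp is comfortably resolvable on 2 % agarose).
Amplification is deterministic given genotype: `predict_bands` lights the
control line plus each member line with `G[sample, m] = 1`; primer
concentration balancing and hybridisation chemistry are out of scope.
`diagnose` partitions all `2^lines` patterns exhaustively: no control →
`invalid`; control + all members → `target`; otherwise `non_target`.

## Numerical / degenerate-input choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical (landscape, config) ⇒ byte-identical
  FASTQ, truth TSV and pipeline outputs (manifest with SHA-256 checksums).
- Empty FASTQ input produces an empty matrix and a successful exit.
- A genotype TSV cell outside {0, 1, ○, ×, o, x} fails with its row/column
  coordinates; duplicate marker rows must agree exactly to be merged.
- The packaged reference panel stores the assay's ○/× symbols verbatim;
  one marker shared by two kits appears twice and is deduplicated on load.
  Amplicon sizes are keyed by (kit target, marker) because re-primed
  fragments differ in size between kits.

## Problem sizes

The shipped analyses run at desk scale: simulations of 5–26 cultivars,
12–100 sites, depth 12–50 (seconds to ~half a minute on one core), and the
26 × 14 reference panel for all marker-set and kit computations.  Site and
read totals of a production sequencing run are orders of magnitude larger
and are not reproduced here.
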