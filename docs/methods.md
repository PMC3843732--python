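# Methods

## Scope and data model

The pipeline consumes whole-plastome or per-marker multiple sequence
alignments (aligned FASTA) and annotated genomes (GenBank flat files). It
does not compute alignments and does not model plastome circularity:
regions wrapping the origin are rejected, which is safe because candidate
markers sit inside the single-copy and IR blocks. Internally every interval
is 0-based half-open; GenBank's 1-based inclusive convention is converted
at the I/O boundary only, and human-facing TSV reports print 1-based
inclusive coordinates. IUPAC ambiguity codes are carried through unexpanded
so that one place — column classification — decides their meaning.

## Site classification

A column is **variable** iff it contains at least two distinct unambiguous
nucleotides (A/C/G/T), each in at least one sequence. Gaps and ambiguity
codes are missing data: they neither create nor destroy a variable call.
This is the conservative convention of common variability software; its
practical consequence is that a column whose only heterogeneity is `A`
vs `N` is invariant, and gap-only heterogeneity is left entirely to indel
coding. A column is **parsimony-informative** iff at least two unambiguous
states each occur in at least two sequences; the statistic is refused
(rather than returned as 0) for fewer than four sequences, where it is
undefined.

**Total characters** of a marker is its alignment column count, gap
columns included — published marker lengths in screening tables are
alignment lengths. Percentages are `100·count/total` rounded **half-up** to
one decimal (`decimal.Decimal`, not banker's rounding) to match how
screening tables print, e.g. 56/884 → 6.3.

## Simple indel coding

Gap runs are maximal per-row runs of `-`. Every distinct non-terminal
(start, end) interval becomes one binary character, ordered by (start,
end): a row with exactly that run scores 1 (present); a row whose own gap
strictly contains the interval — or whose terminal gap covers it — scores
`?` (the event is unobservable there); any other row scores 0. Terminal
runs found no characters and are treated as missing data, since
leading/trailing gaps usually reflect sequencing extent, not indel events.
Only *variable* characters (both 0 and 1 observed among non-`?` rows)
enter the combined variable+indels tally: an indel shared by all
sequences carries no signal. Complex or modified-complex coding is out of
scope.

## Sliding-window scan

Windows are measured in alignment columns including gap columns, so each
window spans exactly `window` (default 1,000) columns and all values are
comparable; the per-window value is its variable-column count (implemented
as a cumulative sum over the per-column variable mask, so every value is
reproducible by recounting the window slice). An `ungapped_window` mode
instead spans a fixed number of non-gap positions of a designated reference
row, for sensitivity analysis when gap density varies strongly. The
trailing truncated window is dropped unless explicitly kept. Ties in
top-window selection break toward the lower offset. Windows overlapping or
separated by at most the step merge into candidate regions, named from the
reference annotation: a region mostly (≥ 50%) inside one gene takes that
gene's name, otherwise "leftGene-rightGene" from the nearest flanking
genes. Regions longer than 1.4× a cap (default 1,300 columns) split into
⌈length/cap⌉ near-equal consecutive parts ("name part i") so their counts
stay comparable to ~1 kb markers; the 1.4 slack avoids splitting regions
only marginally over the cap into lopsided halves.

## Ka/Ks (Nei–Gojobori with Jukes–Cantor correction)

Coding fractions of candidate markers are checked for selection with the
unweighted pathway method. Per codon, each position contributes the
fraction of its possible single-base changes that are synonymous; changes
creating stop codons are **eliminated** from numerator and denominator (the
original convention), which matches a mutational process in which lethal
changes never fix — charging them as nonsynonymous instead systematically
deflates Ka against such data. Site counts average the two sequences, so
S + N = 3 × codons always. Observed differences per codon are averaged
over all minimal mutational pathways with equal weight; pathways through a
stop codon are excluded unless every pathway is blocked. Proportions are
corrected with d = −(3/4)·ln(1 − (4/3)p), undefined (error) at p ≥ 3/4 —
note that very short fragments can hit this legitimately (a lone TTT→TTC
codon pair has ps = 0.75 exactly). ω = Ka/Ks is undefined (None) when
Ks = 0. Classification uses a declared neutral band of 0.9–1.1 and returns
"undetermined" for undefined ratios or fewer than 5 observed differences.
Multi-sequence regions are summarised by the mean over pairwise ratios with
defined Ks. Likelihood codon models and branch/site tests are out of scope.

**Aggregating replicate pairs.** For calibration checks the package pools
counts (ΣNd, ΣSd, ΣN, ΣS → one corrected ratio, `pooled_kaks`) instead of
averaging per-pair ratios: with ~4–6 synonymous differences per pair the
per-pair ratio is strongly right-skewed (occasional Sd = 1 pairs give
ratios above 4) and its mean overshoots the true ω by 10–40%, whereas the
pooled estimate is empirically unbiased. The jackknife over replicates
supplies its standard error.

## Inverted-repeat check

Copy B is reverse-complemented and compared position-wise against copy A —
no realignment, because the check validates *identity* under concerted
evolution, not homology. Unequal lengths can never report identical;
mismatches are still located over the shorter prefix, and an `end_trim`
of up to 5 bp tolerates slightly different annotated IR boundaries.
Mismatch positions are 1-based in copy-A orientation. IR boundary detection
from raw sequence is out of scope; annotated boundaries are consumed.

## Ranking and cross-clade comparison

Markers rank by the absolute number of variable characters including coded
indels — the quantity that determines information gained per base
sequenced — descending, with a deterministic tie-break chain: variable
sites, then combined percentage, then name. Published screening tables
contain ties whose printed order follows no stated rule, so exact tie
order is not a reproduction target; untied ranks are. Cross-clade
comparison reports per-marker rank differences and the top-3/top-6 overlap
sets; nuclear comparison markers (ITS, *waxy*) are rendered but never
ranked against plastid loci. On the packaged *Solanum* counts the top-6
overlap is {ycf1 part 1, ycf1 part 3, rpl32-trnL}. The printed "Average"
rows of such tables are not reproducible from the printed per-row values
under any obvious denominator and are excluded from reports.

## Synthetic data

The generator trades realism for exact truth. Mutations are placed
star-wise: each variant column gets an alternative base in a random
non-empty *proper* subset of taxa, at distinct columns, so in this
homoplasy-free regime the planted counts are exactly recoverable and any
discrepancy is a pipeline bug. Indels are planted as shared-boundary,
non-terminal gap intervals, pairwise separated by at least one column (so
runs cannot fuse) and disjoint from variable columns; each is exactly one
variable coded character. A nested mode plants a gap strictly inside a
longer gap of another taxon to exercise `?` scoring (one nested event
yields two characters, inner and outer). IR blocks come in mutation-free
reverse-complement pairs, emulating concerted evolution.

Codon pairs for selection tests are generated by acceptance–rejection:
proposals are uniform single-base changes, stop-creating proposals are
discarded, and nonsynonymous proposals are accepted with relative
probability ω — the same selection model the estimator assumes. Multiple
hits per codon (including reversals) are allowed; they are what the
Jukes–Cantor correction undoes. Realized event counts are returned as
truth, so Sd + Nd equals the requested substitution number exactly.

The default plastome-trio architecture is a scaled-down (~25 kb)
quadripartite genome: quiet genes and spacers (0.004 variable sites per
column, typical congeneric background), four hot spacers and a hot ycf1
CDS (0.045 per column, ~45 variable sites per kb — the level that makes a
region stand out in a three-genome screen), and two 3 kb IR copies. Three
taxa mirror the three-genome screening design; 12 taxa are used for
clade-level marker alignments, mirroring a typical clade sample. The
stand-in "rpl32" gene block is deliberately oversized (1.4 kb) so the two
flanking hot spacers resolve as separate candidate regions at the default
window/step; real gene lengths are not emulated. What passing recovery
tests shows is that the measurement machinery is exact under known truth —
not that real alignments are homoplasy-free, nor that real indels always
share boundaries; on real data, variable counts are exact by definition
while indel-character counts depend on the alignment's gap placement.

## Problem sizes and determinism

Tests and the acceptance script run the trio screen at ~25 kb × 3 genomes,
clade alignments at ≤ 1,300 columns × 12 taxa, and ω-recovery at 100
replicate pairs of 200 codons with 20 substitutions per pair — sizes at
which every stage completes in seconds while each statistic retains enough
events to be meaningful. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; identical spec and
seed give byte-identical alignments and genomes.

## Known limitations

- Star-topology simulation has no shared tree structure; rate variation,
  inversions and length polymorphism of real plastomes are not emulated.
- Simple indel coding only; overlapping-but-unequal gaps in messy real
  regions may be counted differently than by eye, so combined tallies on
  real alignments can differ by a site or two from manual counts.
- The window scan counts variable sites, not nucleotide diversity; windows
  are alignment columns, so heavily gapped windows cover less sequence.
- Pairwise Ka/Ks only; no tree-aware or likelihood estimates.
- The phrase-level convention for "gap-aware" window sizing (columns vs
  non-gap reference positions) is a declared choice; both are available.
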