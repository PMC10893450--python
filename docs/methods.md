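# Methods

This note records the models behind `wgdscan`, the parameters that
matter, the numerical choices, and what the simulation-based validation
does and does not establish.

## Ks estimation (NG86)

Paralog and ortholog pairs are aligned at the protein level
(`Bio.Align.PairwiseAligner`, global mode, BLOSUM62, gap open −10,
extend −0.5; the aligner's first optimal alignment is taken, which makes
tie-breaking deterministic) and the alignment is back-translated onto
codons. Synonymous and nonsynonymous sites are counted per codon by
enumerating the three single-base alternatives at each position;
alternatives creating stop codons are excluded and the position's
fractions renormalised over the stop-free alternatives, so each sense
codon still contributes three sites. Site totals are averaged over the
two sequences. Differences in multi-hit codons are averaged over all
substitution orders, discarding orders that pass through a stop codon;
the rare column in which *every* order is blocked is excluded from both
site and difference totals. Proportions are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 or a zero site count
yields an explicitly flagged undefined estimate (Ks and Ka are flagged
independently), never a silent drop.

NG86 was chosen over ML codon models because it is deterministic,
dependency-free and accurate enough for peak-position work; on the
simulator's own output the mean estimate is within ~1% of truth at
Ks ≤ 1.2 and within ~4% at 1.5, with saturation growing above that
(tests quantify this). Estimates from other counting or ML methods may
shift peak positions slightly.

## Redundancy weighting and the retention filter

Within one family and species, m genes yield m(m−1)/2 pairs but only
m−1 duplication events. The family's genes are single-linkage clustered
on pairwise Ks (`scipy.cluster.hierarchy.linkage`); each of the m−1
merge nodes distributes weight 1 equally over the gene pairs it joins,
so every event contributes total weight 1 to the distribution. If any
pairwise Ks in a family is undefined the family falls back to an equal
split of m−1 events over its defined pairs.

Ks values are retained on the **closed** interval [0.1, 5] (both
boundary values kept); counts dropped below, above, and as undefined
are recorded per distribution.

Ortholog pairs are reciprocal best hits. The built-in scorer counts
shared amino-acid 4-mers between translated sequences — adequate for
the simulator's indel-free data — and any externally computed score
table (e.g. from BLASTP) can be supplied instead; ties break
lexicographically by gene id.

## Mixture model and peak calling

Univariate Gaussian mixtures are fitted by EM directly on raw Ks values
(a `--log-transform` switch exists but is off by default), with each
observation contributing its redundancy weight to the responsibilities.
Component variances are unequal and floored at 1e−4 (a degenerate
all-equal input therefore converges to the floor instead of failing);
means are initialised k-means++-style from a seeded generator, the best
of `n_restarts` runs by log-likelihood is kept per k, and the same seed
reproduces the same fit. Model choice minimises
BIC = −2·log L + p·ln(n_eff) with p = 3k − 1 and n_eff the summed
weights; ties go to fewer components. Components with weight ≥ 0.1
(default) are reported as peaks.

Peak placement compares a peak's mean to the dominant component of a
BIC-selected fit to an interspecific distribution, with a coincidence
tolerance of 0.1 Ks units by default (the biological statement
"coincided" is qualitative; the tolerance makes it operational): a WGD
peak larger than the divergence mode predates the speciation
(`before_divergence`).

## Reconciliation and WGD calling

Gene trees are mapped onto the rooted binary species tree by standard
LCA reconciliation; a gene-tree node is a duplication iff it maps to
the same species-tree node as at least one child. A duplication at a
node with child lineages A and B is typed (AB)(AB) iff each duplicate
subtree contains at least one species from A and one from B;
duplications mapping to species-tree tips cannot show this pattern and
are typed "other". Note that a duplication whose second copy survives
in only one species maps, under LCA parsimony, to that species' tip —
not to the deeper node where it may actually have occurred; this is the
standard, deliberate behaviour of the mapping.

Duplications at gene-tree nodes with support below 50 (default,
configurable) are discarded; nodes without support values are kept.
Non-binary nodes are resolved deterministically (left-ladder over
children ordered by smallest descendant leaf) and the number of such
resolutions is logged.

WGD calls use two joint thresholds with strict inequalities —
(1) GD > 450, GD ratio > 4.5%, (AB)(AB) > 50%; (2) GD > 1000,
ratio > 5%, (AB)(AB) > 20% — designed for transcriptome-scale family
counts. In `scaled` mode the two count thresholds are multiplied by
n_families/10000 so the same logic applies to small simulated datasets;
the ratio and (AB)(AB) thresholds are scale-free and unchanged.
Duplications mapping to the species-tree root are reported with a
warning but never auto-flagged, since a root pile-up is more often a
sampling artefact than evidence.

The bundled gene-tree builder is neighbor joining on protein
p-distances with lexicographic tie-breaking, rooted by minimal
duplication count (ties: implied losses, then newick string). It is
plumbing for desk-scale validation, not a replacement for ML tree
inference; NJ supplies no support values, so by default all its
duplications count.

## Dating and rate correction

date [Mya] = Ks/(2r)/10⁶ with r in synonymous substitutions per site
per year; the default reference rate is 11.04 × 10⁻⁹. Window
comparisons use closed intervals and zero tolerance by default; larger
Mya means earlier.

The correction chain rescales a target lineage onto the reference scale
through a bridge species that (a) shares a datable duplication peak
with the reference and (b) is an outgroup to both reference and target,
so that both interspecific ortholog peaks date the same split. The
reference's own coefficient is fixed at 1 — the only value under which
aligning the bridge peak onto the reference anchor is self-consistent.
The between-species coefficient is the arithmetic mean of the two
lineage coefficients; this mean (rather than a harmonic one) introduces
a small systematic error when rates differ strongly, of order 3% at a
1.4-fold rate contrast in the worked geometry, which is well inside the
scatter of estimated peak positions. Chain inputs default to
BIC-selected dominant components but printed peak values can be passed
directly. A derived target coefficient ≤ 0 raises an error (the rate
geometry is then inconsistent).

## Selection screen and gene-set statistics

A duplicate pair is positively selected iff Ka/Ks is strictly greater
than 1; undefined ratios (zero or saturated Ks) are counted separately
and never flagged. Enrichment is the hypergeometric upper tail
P(X ≥ k) per term over a configurable universe (default: all annotated
genes), Benjamini–Hochberg corrected; terms with fewer than 3 universe
genes are skipped; no GO-hierarchy propagation is performed — the
annotation map is taken as given. Genus-level gene-fraction comparisons
use Welch's t-test by default (Student's optional); both genera need at
least two species, and the zero-variance degenerate case is resolved
explicitly (equal means → t = 0, p = 1; different means → p = 0).

## The simulator

Each family starts as one random stop-free ancestral gene (length
Poisson around 200 codons by default, minimum 10) evolving down an
ultrametric rooted species tree whose branch lengths are
reference-scale Ks per lineage. Substitution is per-site with equal
base-exchange rates; proposals creating stops are rejected and redrawn,
nonsynonymous proposals are accepted with probability ω (default 0.2,
firm purifying selection), and the attempt count per branch is
calibrated from the branch's starting sequence so the expected accepted
synonymous substitutions per synonymous site equal the branch's Ks.
Rate heterogeneity is modelled by per-tip multipliers scaling terminal
branches; internal branches evolve at the reference rate.

A WGD episode at node v with pair age a duplicates every extant copy at
reference depth a/2 on the branch above v (episodes older than the
root act on a stem lineage); each new copy survives with the episode's
retention probability. Small-scale duplications and losses arrive as
Poisson processes per copy per effective-Ks unit (defaults 0.05 and
0.02 — a visible exponential-like background that does not drown the
planted burst). Extinct families are regenerated with bounded retries.
The truth table labels every within-family tip pair with its origin
(episode id, `ssd`, or `speciation`) and its exact model Ks (sum of
effective branch lengths on both paths from the pair's gene-tree MRCA).
The same seed yields byte-identical datasets.

What the simulator does **not** model: indels (alignments on simulated
data are trivially gap-free, so the aligner's gap handling is exercised
only by dedicated unit tests), codon-usage bias, among-site rate
variation, hybridisation/allopolyploid subgenome exchange, and
assembly/isoform artefacts of real transcriptomes. Passing end-to-end
tests therefore demonstrates the correctness of the inference chain
under its own model assumptions, not robustness to every property of
real data.

## Validation scales

The whole-pipeline recovery check plants one episode (pair age Ks 1.1,
retention 0.8) at an internal node of a four-taxon tree, simulates 500
families per replicate, and requires — in at least 90% of 20 seeds —
both a mixture component with mean in [1.0, 1.2] and a WGD call at
exactly the planted node under scaled thresholds. Reconciliation is
verified against a brute-force oracle exhaustively for every rooted
gene-tree shape and species assignment up to 5 leaves over a 4-taxon
species tree (≈110k trees; full enumeration to 8 leaves is
combinatorially out of reach) plus 300 seeded random trees of 6–8
leaves. NG86 is verified against exhaustive pathway enumeration on
random ≤5-codon alignments to 1e−9.
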