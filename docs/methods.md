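# Methods

This note documents the models, statistics and design choices behind
`dapregulon`, in the order the pipeline runs them.

## Coordinate and background models

All coordinates are 0-based half-open; GFF3's 1-based inclusive convention
is converted once at the parsing boundary. Operons are called by the
standard prokaryotic heuristic: consecutive same-strand genes whose
intergenic gap is at most `max_gap` (default 150 bp) share an operon. The
candidate regulatory ("non-coding") window of an operon spans up to 400 bp
upstream of the head gene's translational start through 40 bp into its CDS,
truncated so it never reaches into a neighboring gene's CDS; a head gene
shorter than 40 bp truncates the overhang with a warning. For divergently
transcribed operon pairs the two windows may overlap; each window carries
its own operon id, and a feature in the shared stretch maps to both targets
because it falls inside both windows. By default only operon heads get
windows; `include_internal=True` also emits windows upstream of internal
genes. Origin-wrapping features on circular genomes are not modeled.

The background is an order-*m* Markov model (default *m* = 2) estimated
from (m+1)-mer counts on **both** strands with pseudocount 1 per k-mer,
which makes the model reverse-complement symmetric. Scores condition on the
scanned sequence's own context; the first *m* positions fall back to the
marginal composition.

## Peak calling

Coverage is accumulated per base from fragment BED intervals; duplicate
fragments are retained by default (the screening convention for in-vitro
selection data, where duplicates carry signal). The caller computes

    fold(i) = (smoothed TF depth + α) / (s · smoothed control depth + α)

with a 50 bp moving average, pseudo-depth α = 1 and library-size scale
s = n_TF / n_control. Bases with fold ≥ `min_fold` (default 1, i.e. any
enrichment above the scaled control) form candidate runs, merged across
gaps ≤ 100 bp.

Each run is then tested at the fragment-count level: with X TF fragment
starts and C control starts in the run, the exact conditional test of two
Poisson rates treats X as Binomial(X + C, n_TF/(n_TF + n_control)) under
the null. This was chosen over a fixed-λ Poisson test deliberately: a
fixed λ ignores the control's own sampling noise, and empirically lets two
independent same-rate libraries produce q < 0.05 peaks, while the
conditional test keeps them null. C is taken conservatively as the larger
of the in-run control count and the integral of a 1 kb-windowed local
control rate (absorbing mappability artifacts), plus α — so calling a
track against itself can never reach significance at any FDR ≤ 0.5.
Benjamini–Hochberg across runs gives Q-values; peaks with q ≤ `fdr`
(default 0.05) are returned, apex at the maximum smoothed fold.

Near-duplicate peak windows are purged greedily in input order: a sequence
is dropped when its best ungapped alignment to any retained sequence (any
offset, either strand) reaches `max_identity` (default 0.8) over a window
of ≥ 100 bp — removing repeated peaks and transposon-scale repeats while
keeping motif-scale similarity.

## Motif discovery

Discovery is ZOOPS (zero-or-one occurrence per sequence) EM over both
strands. The E-step computes posterior site probabilities from the
PSSM-vs-background likelihood ratio of every window; the M-step
re-estimates expected counts, the site prior γ, and column frequencies
regularized by a pseudocount of 0.1·nsites distributed by background
composition. The objective (total log likelihood ratio of the ZOOPS
mixture over pure background) is non-decreasing across iterations;
convergence is a relative change < 1e-6 or 200 iterations.

Starting points are seed words: because peak windows are apex-centered and
binding sites concentrate at the apex, words overlapping the central ±30 bp
of each sequence are the prime candidates, followed by w-mers repeated
anywhere and random draws. Candidates are ranked by a vectorized
best-window Hamming similarity prescreen, screened by one EM sweep, and
the best few run to convergence.

Widths are swept over {6, 8, …, 24} by default (the range where bacterial
TF operators fall; the full 3–60 range is available by configuration).
Widths compete on the objective's **excess over its shuffle-null mean**
(four per-sequence letter-shuffle refits), since the raw objective grows
mechanically with width; a z-score was rejected because a 4-shuffle
standard-deviation estimate is too noisy to divide by. The winning motif
is trimmed of uninformative *edge* columns (relative entropy < 0.3 bits),
which removes background-level flanks the sweep can attach without
touching interior spacer columns of gapped dyads.

The E-value is p·(number of widths tried), where p is a normal-tail
probability of the observed objective against a null estimated from 100
composition-preserving per-sequence shuffle refits. This calibration is
tool-internal: E-values are comparable within this package, not to other
motif discoverers. Dyad annotation reports the best inverted or direct
arm pair of the consensus (ties toward inverted, then longer arms, then
leftmost); motif comparison reports the best mean column-wise Pearson
correlation over offsets and orientations, scaled by the fraction of the
shorter motif covered so that chance 4-column agreements cannot outrank
full-length alignments. Motifs round-trip through MEME minimal format.

## Match p-values and scanning

A word scores `S(w) = Σ_i log2 f_i(w_i)/b(w_i | context)` in bits. The
match p-value is the exact probability that a random background word
scores ≥ S(w), by dynamic programming over the column score distribution:

- widths ≤ 9: the DP enumerates the exact (merged) float support — no
  discretization — and agrees with brute-force 4^w enumeration to
  ≤ 1e-9 (the partial sums are accumulated left-to-right in both);
- wider motifs: column scores are discretized on an ε = 1e-4 bit grid,
  bounding the score error by w·ε ≈ 1e-3 bits, far below threshold
  resolution.

For order-m backgrounds (m > 0) scores use sequence-context denominators
while p-values are computed under the order-0 marginal composition — a
deliberate, conservative approximation (an exact order-m DP is a noted
extension). Windows containing N are skipped. Scanning reports every
position × strand with p below threshold, overlapping sites retained (no
greedy masking — closely spaced operator arrays are real), sites sorted by
position with '+' first.

Thresholds follow the two-tier convention: p < 1e-4 in peak windows,
p < 1e-5 genome-wide, with per-TF overrides. The two-word worked example
shows why overrides exist: a motif built from equal counts of `ATAGTCC`
and `ATAGTCT` gives both words the identical top score with exact
p = 2·4⁻⁷ ≈ 1.22×10⁻⁴ — above 1e-4, at-or-below 2e-4 — so the default
rejects the motif's own words and a 2e-4 override accepts both.
`calibrate_threshold_null` supports threshold choice by rescanning with
column-permuted motifs (default) or shuffled sequences. Degenerate-word
search (e.g. `GTAAnnTTAC`, mismatches counted at non-n positions only)
covers TFs whose PSSM fails to capture known sites;
self-reverse-complementary patterns are reported once per duplex
occurrence. EMSA probe design takes the lowest-p site plus 10 bp of peak
context per flank, and a same-length context window with no match at
p ≤ 1e-3 as the negative.

## Regulon assembly and network

A peak joins a regulon only if its apex lies in a regulatory window AND
its 500 bp window contains a site at the peak threshold (the qualifying
site may sit anywhere in the window; no apex-distance cap is imposed).
Targets are whole operons expanded to member genes; a feature in a shared
divergent stretch targets both operons. A genome-scan site inside a
retained peak window is attributed to the peak-derived evidence column,
not double-counted, keeping the per-source site accounting disjoint. The
word-rule path admits exact pattern instances anywhere in regulatory
windows plus ≤1-mismatch instances only inside retained non-coding peaks.
Site-architecture reports flag the "two pairs of inverted repeats"
geometry (spacing vector short–long–short with equal shorts within 3 bp)
as a report, not a filter — enforcing it is a per-TF judgment call.

Conservation is simplified phylogenetic footprinting: ortholog upstream
sequences (same 400/40 convention) are an input table; an edge is flagged
conserved when the motif matches the focal gene's upstream region and
those of ≥ `min_genomes` − 1 other genomes (defaults p < 1e-4, 3 genomes
including focal; no phylogenetic weighting). The merged network types
target genes that encode assayed TFs as TF nodes, detects autoregulation,
TF→TF hierarchy and shared targets, reports binding-site interval
overlaps between TFs (≥ 1 bp), and exports SIF/GraphML/TSV.

## Synthetic data

The generator emulates the study design this pipeline targets. Defaults
(one choice, fixed): a 500 kb genome sampled from a deterministic
AT-rich order-2 background (GC 0.39 with a mild same-base repeat boost for
short-range autocorrelation); 200 two-gene operons of 900 bp genes,
300 bp intergenic stretches, strand alternating in blocks of four so most
windows are private while every '−'→'+' block boundary yields a divergent
pair; one TF with 20 sites sampled from a 14 bp consensus PSSM at
column concentration 0.95 (≈ 23 bits of information), planted ≥ 60 bp from
window edges so the fragment-pileup apex stays inside the window, and —
by default — at positions owned by exactly one operon, so the planted
regulon is unambiguous; fragment libraries of ~200 ± 30 bp fragments
(minimum 50 bp, normal lengths clipped) at 30× background coverage, with
TF-sample fragments concentrated over planted sites to 10-fold expected
coverage and a uniform control. Everything is a pure function of
(seed, parameters); the JSON manifest regenerates byte-identical files.

What the generator does **not** emulate: read-level error and quality,
PCR/GC bias, mappability structure, binding-footprint shape, competing
TFs, and real operator-architecture diversity. Passing recovery tests
therefore demonstrates the pipeline's correctness under its own model
assumptions, not performance on real sequencing data.

One consequence worth stating: scanning all regulatory windows (~60 kb at
this scale) at p < 1e-5 on two strands is *expected* to yield on the order
of one chance background match per dataset. Such a site enters the
assembled regulon by construction — exactly as scan-only sites do in real
reconstructions — so recovery tests assert that every planted edge is
found, that every peak-supported edge is planted, and that any scan-only
extra re-verifies as a genuine sub-threshold match away from planted
sites, rather than demanding a literally empty difference that the null
rate makes seed-dependent.

## Problem sizes and numerical choices

The shipped tests run the full study at 500 kb / 20 sites (about a minute)
and module tests at 60–120 kb; these sizes were chosen so the planted
signal matches the study conditions while the suite stays desk-scale.
Numerical guards: EM soft counts are renormalized per column at machine
precision; p-value lookups use a 1e-9 score tolerance so a word's own
score maps onto its own atom; survival functions are accumulated from the
tail; BH is taken from statsmodels. Known limitations: single-contig
genomes (multi-contig input is concatenated by the caller), Markov orders
> 5 unsupported, no activation-vs-repression sign inference, no
expression integration, and E-values are not comparable across tools.
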