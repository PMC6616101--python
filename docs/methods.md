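# Methods

This note documents the models, parameter choices and numerical
conventions behind `polyasig`, and what the synthetic benchmark does and
does not establish about real data.

## Coordinates and site definition

A cleavage site's position is the genomic coordinate of the last
templated nucleotide, relative coordinate −1; the poly(A) tail begins at
+1 and relative coordinate 0 does not exist. The YA cleavage
dinucleotide occupies (−2, −1). Flanks cover −300..−1 upstream and
+1..+100 downstream on the sense strand, reverse-complemented for
minus-strand sites and transcribed to RNA. Internally all genomic
intervals are 1-based inclusive (GFF3 convention); BED input/output is
converted at the file boundary. Motif positions everywhere refer to the
3′-most base of the word, so AAUAAA "at −23" occupies −28..−23; this is
the convention under which the canonical signal sits at −23 ± 4.

## Site clustering and internal-priming filters

Cleavage events on one chromosome and strand are chained
single-linkage: adjacent events at most `max_gap = 24` nt apart join one
cluster. The representative is the member with the largest pooled read
count; ties go to the most downstream member in the transcription
direction (3′-seq peaks skew 3′). Clustering is therefore independent of
input order, which the tests assert against a brute-force oracle.

Three artifact rules are checked on the +1..+10 downstream window, in
order: ≥6 adenines anywhere; a leading AAAA/AGAA/AAGA/AAAG tetramer;
a run of more than five consecutive adenines. The run rule is logically
subsumed by the ≥6-A rule inside a 10-nt window (a 6-run is six
adenines), so with this check order `fail_runA` can never be the
reported status; all three rules are retained and reported per rule
because the rule set, not its overlap structure, is the published
procedure. Sites with fewer than 10 nt of downstream contig are kept and
edge-flagged rather than judged on a truncated window.

## Region annotation

Precedence across overlapping same-strand transcripts is
3′ UTR > CDS > 5′ UTR > intron, favouring mature-mRNA assignments.
Sites outside every same-strand transcript but within `extension` nt
downstream of an annotated 3′ end are "extended 3′ UTR" (Ex_3UTR) of the
nearest gene, mirroring the observation that a large fraction of
downstream sites fall within a few hundred nt of annotated ends; the
default extension is 1,000 nt (configurable) since about half of such
sites lie within 500 nt. The upstream mirror gives Ex_5UTR; Ex_3UTR is
tried first. Antisense overlap counts as intergenic — assignment is
strictly strand-specific. Per-gene APA statistics define proximal =
5′ UTR + CDS + intron and distal = 3′ UTR + Ex_3UTR, and gene categories
by site count: 0 non, 1 rare, 2–4 moderate, >4 abundant. Correlations
between APA frequency and gene structure are Pearson r with two-sided
p-values (scipy); zero-variance columns yield NaN rather than a value.

## Usage classes

Read shares are pooled over all samples and all passing sites of the
gene (a 3′ UTR-only denominator is available by subsetting the input
table). The strong threshold is strictly greater than 0.70: a 70/30
gene is universal/universal, a 71/29 gene strong/weak; the tests
enumerate the whole boundary. Control pseudo-sites are genomic AAUAAA
occurrences with no real site within 50 nt of the hexamer; the
pseudo-cleavage position is placed so the hexamer end sits at −23,
matching the observed position of the real signal, because the data do
not define where a nonfunctional hexamer's "site" would be.

## Markov-background k-mer statistics

The background for a region is a first-order Markov chain fitted to that
region's own sequences (dinucleotides counted within sequences only).
The expected per-position frequency of a word is the chain probability
written as the product of its k−1 dinucleotide frequencies over its k−2
interior mononucleotide frequencies; the acceptance suite verifies this
against brute-force enumeration of all 4⁶ hexamers to <1e−12.

The count variance used in z_oe is the exact variance of the number of
(overlapping) occurrences in a stationary first-order chain, summed over
sequences:

* the binomial diagonal T·f_e·(1−f_e);
* positive covariance at each self-overlap period d of the word,
  2(T−d)·f_e·(f_e^{(d)} − f_e), where f_e^{(d)} is the conditional
  probability of the trailing d bases given the overlap;
* negative covariance −2(T−d)·f_e² at non-period distances d < k
  (incompatible overlaps cannot co-occur);
* a geometric tail for distances d ≥ k, computed from powers of the
  transition matrix, which vanishes for iid backgrounds.

The last two terms go beyond a period-only correction; without them the
predicted SD misses the Monte-Carlo oracle at the tested precision
(10,000 simulated sequences, agreement required within 3× the oracle's
own standard error). The formula assumes marginal stationarity, which
holds exactly for models built from a transition matrix via
`MarkovModel.from_transition` and to O(1/L) for fitted models.

Binomial p-values are upper tails P(X ≥ O_o), X ~ Binomial(T, f_e),
computed by scipy in linear or log space. The two-proportion statistic
z_sw between strong and weak sets uses pooled p = (O_s+O_w)/(N_s+N_w)
and proportions in the numerator — the only scale on which the pooled
probability is coherent; a raw-count numerator variant is retained
behind a flag for comparison with older reports. Both statistics are
calibrated on null simulations in the acceptance suite (z_oe moments,
z_sw type-I rate at |z| > 1.96).

## Greedy signal selection

Each round counts all hexamers in the current sequence set restricted
to the selection window, walks candidates in descending frequency (ties
lexicographic, for determinism), and accepts the first whose binomial
p-value beats `p_cut = 1e−5` and whose positional SD is at most
`sd_cut = 7` nt. Accepted hexamers remove every sequence containing
them (whole-sequence removal is the primary mode; position masking is
available), and the loop ends when no candidate passes. Two details
matter:

* Positional statistics always come from the original, uncut dataset —
  removing sequences inflates the apparent dispersion of the remaining
  signals, so dispersion is judged before any removal.
* The dispersion window is the selection window widened by
  `sd_margin = 15` nt per side. Measured only inside a 22-nt window, no
  word can exceed SD 7 (the uniform bound is ≈6.4), so scattered decoys
  would never be rejected; measured over the full −300..+100 flank,
  even a perfectly planted signal fails, because its few background
  occurrences across 400 nt dominate the variance. The widened window
  separates the two regimes: planted-at-−23 signals keep SD ≈ 4.5,
  uniformly scattered words exceed 14.

## Element schemas

Signal windows per genomic class are fixed published constants
(configurable), e.g. the 3′ UTR model USE −100..−35, PE −34..−13,
CEL −12..−3, CER +1..+33, DSE +34..+100; the proximal-class models
shift these boundaries and CDS collapses the cleavage-proximal windows
into one CE. Selected hexamers (region z_oe above the empirical 99th
percentile, plus z_sw ≥ 1.96 when strong/weak sets of at least
`min_strong_weak = 30` flanks each are available) are clustered with a
shift-penalized mismatch distance — minimum over shifts |s| ≤ 3 of
(mismatches in the overlap + 0.5·|s|) — under average linkage cut at
2.6. Groups are aligned at each member's distance-minimizing shift
against the group medoid (ties: smaller |shift|, then smaller shift;
medoid ties lexicographic), a deliberate replacement for a progressive
multiple aligner: for fixed-length hexamers the shift alignment is
exact, deterministic and dependency-free. Consensus is the per-column
majority base with IUPAC codes on ties; PFMs are written as JASPAR
text. Note the empirical-quantile screen always flags the top tail of
each window, so on signal-free backgrounds the reported elements are
noise by construction — the z/p columns, not the presence of rows,
carry the evidence.

## Stage-specificity entropy

Counts are scaled to counts-per-million within each stage before
entropy, so sequencing depth does not masquerade as specificity; H and
modeH are then scale-free. The one-step Tukey biweight uses c = 5 and
eps = 1e−4 (the usual one-step convention); the absolute eps floor
makes modeH scale-invariant only up to O(eps/MAD), which the tests
bound at 1e−4 relative. A perfectly constant profile has an all-zero
residual vector; its modeH is defined as log₂(n) (maximal uniformity)
and flagged. Specific sites are the intersection of the lowest-`pct`
tails of both H and modeH rankings, constitutive the intersection of
the highest tails, with the realized cutoffs reported; sites under 5
total reads are never labelled. The low-entropy = specific direction
follows the outlier-detection (ROKU) convention; the per-stage summary
header notes that some published summaries print the thresholds with
the opposite orientation, and both the direction and thresholds are
configurable.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the benchmark conditions: genes of
3–10 kb with 0–7 introns, 50 genes per chromosome with 2-kb intergenic
spacers; 1–3 3′ UTR sites per gene plus optional intron/CDS/5′ UTR and
extended-3′ UTR sites, at least 50 nt apart; AAUAAA (50%) and AUUAAA
(20%) planted at −23 ± 4 for 3′ UTR sites with a UGUUUU CER element,
and region-specific signals for proximal sites; a YA dinucleotide at
(−2,−1) for 80% of sites; 10% of sites rewritten into internal-priming
artifacts (one removal rule chosen uniformly); negative-binomial counts
(dispersion 0.2) from three archetypes — stage-specific (mean 200 in
one of nine stages over a 0.3 background), constitutive (mean 50
everywhere), and background sites expressed in 2–6 random stages at
mean 30, in proportions 20/20/60. Planted motif writes claim their
genomic footprint in a registry so no later write (motif, YA, artifact
window) can silently overwrite an earlier one; the truth table
therefore describes the emitted sequence exactly. Downstream windows of
clean sites are rejection-sampled to satisfy none of the removal rules,
which is what makes the filter test a closed loop (recall = precision
= 1 by construction).

Deliberate simplifications: background sequence is iid uniform (no
isochores, repeats or composition gradients), one transcript per gene,
no sequencing reads or alignment noise, stage-level counts without
replicates (the entropy analysis operates on nine stage columns, and no
replicate-merging rule is modelled). Passing tests therefore establish
correctness of the statistics and plumbing under a known model — e.g.
that the variance correction is exact for Markov backgrounds — not that
real 3′-seq artifacts are all caught, nor that real signal landscapes
match the planted grammar.

## Problem sizes and numerical conventions

The test and acceptance runs use 150–1,250 genes (≈600–5,100 sites),
2,000 flanks for signal recovery, 10,000 sequences for the variance
oracle, and 10,000 sites for specificity recovery — sizes at which every
Monte-Carlo tolerance above is comfortably resolved while the whole
suite stays fast. All randomness flows through numpy `default_rng`
seeds; identical configuration and seed reproduce every output file
byte for byte, and the pipeline manifest records parameters, input
checksums and per-stage record counts. Degenerate inputs follow one
rule: reject loudly (empty sequence sets, zero-variance SD, pct outside
(0,50), relative coordinate 0) or flag explicitly (contig-edge flanks,
zero-read genes, all-zero profiles), never guess silently.
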