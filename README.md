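# polyasig

Genome-wide analysis of polyadenylation signals from 3′-end sequencing
data, built for the *Xenopus tropicalis* developmental poly(A) site
landscape but applicable to any genome with a cleavage-site table.

Messenger RNAs are cleaved and polyadenylated at sites directed by *cis*
elements around the cleavage site (CS): the canonical AAUAAA and its
variants in the positioning element (PE, roughly −34 to −13 nt), U-rich
upstream elements, and U/GU-rich downstream elements. Genes with several
sites undergo alternative polyadenylation (APA), which is strongly
regulated across development. `polyasig` takes a genome (FASTA), gene
models (GFF3) and cleavage events with per-stage read counts (BED +
count matrix) and produces, stage by stage:

1. **Poly(A) site clusters** — single-linkage chaining of cleavage events
   within 24 nt; internal-priming artifacts are removed when the 10-nt
   window downstream of the representative position is A-rich (≥6 A,
   a leading AAAA/AGAA/AAGA/AAAG tetramer, or a >5-nt A run).
2. **Region annotation** — each site is assigned one of
   3′ UTR / extended 3′ UTR / 5′ UTR / extended 5′ UTR / CDS / intron /
   intergenic, with per-gene APA frequency statistics and Pearson
   correlations against gene structure.
3. **Usage classes** — strong (>70% of the gene's reads), weak,
   universal, unique, plus matched AAUAAA control positions.
4. **Signal discovery** — for a k-mer *w* in a region with sequence
   lengths *l_i*, the expected frequency under a first-order Markov
   background is

   f_e(w) = ∏ f_o(w_i w_{i+1}) / ∏ f_o(w_i)   (interior bases in the denominator),

   the expected count is O_e = f_e · T with T = Σ(l_i − k + 1), and
   z_oe = (O_o − O_e)/SD uses a standard deviation corrected for word
   self-overlap (periodic words such as AAAAAA have super-binomial count
   variance). Significance combines an upper-tail binomial probability
   with a positional-dispersion filter (SD ≤ 7 nt), inside a greedy
   loop that removes sequences covered by each selected hexamer before
   counting the next. Strong-vs-weak differential use is a
   two-proportion z statistic.
5. **Element schemas** — per genomic class, flanks are segmented into
   the published signal windows (USE/PE/CEL/CER/DSE and variants),
   significant hexamers are clustered by a shift-penalized mismatch
   distance (average linkage, cutoff 2.6) and aligned into consensus
   elements with JASPAR-style position frequency matrices.
6. **Stage specificity** — each site's 9-stage profile is scored with
   Shannon entropy H and the outlier-adjusted entropy modeH (entropy of
   |x − T_bw|, T_bw the one-step Tukey biweight); joint low tails are
   stage-specific sites, joint high tails constitutive sites.

A synthetic-data generator (`polyasig.simulate`) plants all of the above
— gene models, signal motifs at configurable offsets, YA cleavage
dinucleotides, internal-priming artifacts, stage-expression archetypes —
with a full truth table, so every stage is tested closed-loop.

## Worked example

The `analysis/` scripts run the whole study on a synthetic dataset:

```sh
python analysis/01_simulate_dataset.py --seed 1   # genome + events
python analysis/02_filter_sites.py                # PACs + artifact filter
python analysis/03_annotate_regions.py            # regions + correlations
python analysis/04_classify_usage.py              # usage classes + controls
python analysis/05_signal_schema.py               # signal discovery
python analysis/06_stage_entropy.py               # stage specificity
```

With seed 1 (300 genes, 1,144 planted sites), step 02 prints

```
2254 events -> 1144 poly(A) site clusters
106 clusters removed as internal-priming candidates (9.3%)
```

— exactly the 106 artifact sites the generator planted at rate 0.1 —
and step 05 recovers the planted PE grammar from sequence alone:

```
greedy PE selection (3' UTR sites):
  AAUAAA  O=281 E=26.6 p=5.1e-181 pos=-23.0±4.6 coverage=51.1%
  AUUAAA  O=47  E=6.8  p=6.3e-24  pos=-23.6±6.4 coverage=17.7%
```

AAUAAA was planted in 50% of 3′ UTR sites at offset −23 ± 4 and AUUAAA
in 20%: the observed counts (O) dwarf the Markov-background expectation
(E), the recovered mean position and spread match the planted values,
and the coverage column reproduces the insertion probabilities. Step 06
then reports the realized entropy cutoffs and the per-stage specific-site
counts and APA ratios.

## Command line

The same stages are exposed as a CLI for use outside the analysis
scripts: `polyasig simulate|filter|annotate|classify|scan|entropy|run`
(see `polyasig --help`); `polyasig run --config pipeline.yaml` executes
the full pipeline with a reproducibility manifest.
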