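# Methods

## The conversion-efficiency statistic

In *Arabidopsis*, 24-nt heterochromatic siRNAs arise from 30–40 nt Pol IV
transcripts (P4RNAs): RDR2 copies the transcript into a duplex, DCL3 dices
it, and the guide strand loads into AGO4 or AGO6 to direct DNA methylation.
Comparing AGO-bound siRNA composition directly with total small RNAs is
confounded, because the precursor pool is itself strongly biased toward 5′ A.
The conversion efficiency removes the precursor-abundance confound by
conditioning on the precursor:

    CE(p) = (AGO-bound siRNA reads whose 5′ end coincides with p) / (precursor reads of p)

for each precursor species `p`. CE reflects the combined dicing-plus-loading
efficiency of that precursor sequence. Species are then sorted ascending by
CE and split into `n_bins` equal-size bins (default 4); comparing the
nucleotide composition of the top and bottom bins reveals which sequence
features promote conversion, independent of how abundant each precursor is.

### Catalog construction

Precursor reads are adapter-trimmed (exact match of an adapter prefix of at
least `min_overlap = 8` nt to the read's 3′ end; trimmed reads shorter than
15 nt are discarded), mapped exactly (ungapped, zero mismatches, sense
strand) to the Pol IV cluster intervals, required to lie fully inside a
cluster, and combined by shared 5′ end: reads anchored at the same
(cluster, position, strand) become one species whose representative sequence
is the longest member (ties broken lexicographically — the longest keeps
maximal 3′ context for positional analysis) and whose read count is the sum.
Species are retained only if strictly longer than 30 nt **and** supported by
strictly more than 50 reads. Both inequalities are strict; the boundary
cases (30 nt, any count) and (any length, 50 reads) are excluded.

Exact matching is a deliberate, conservative divergence from short-read
aligners run with default mismatch tolerance: it is fully reproducible, but
real-library replication may retain slightly fewer reads than a
mismatch-tolerant mapping would.

### siRNA counting

An AGO-bound read counts toward a precursor species iff it is an exact
prefix of the species' sequence (5′ ends exactly aligned, sense strand). A
read that is a prefix of `k` species contributes its full count to each of
the `k`; a fractional option (`1/k` per species) exists for sensitivity
analysis but is off by default. siRNA length is not restricted when
counting; a length window (e.g. 23–25 nt) is available as an option.

### Binning and tie-breaks

Records are sorted by `(CE, species id)` — the id tie-break makes the
partition deterministic — and split into contiguous bins whose sizes differ
by at most one, any remainder going to the lowest-numbered bins so that the
top ("highest CE") bin stays maximally pure. Bin 1 is the lowest-CE bin.

### Composition tables

Per bin, frequencies of A/U/C/G at g1 (the guide 5′ nucleotide) and, for
species with a fixed g1, the frequency of "weak" (A/U) versus "strong"
(C/G) nucleotides at g2. g2 identity proxies the thermodynamic stability of
the duplex's 5′-terminal base pair. Frequencies are tallied per distinct
species, unweighted by read counts — each species is one observation;
read-weighted tallies are available as an option. Bins emptied by a g1
filter are reported with n = 0 and NaN frequencies and are excluded from
trend summaries rather than raising. The trend summary is the signed
difference `freq(highest populated bin) − freq(lowest populated bin)`.

## The generative simulator

The simulator exists so that the whole pipeline can be tested for parameter
*recovery*: it plants known biases and the analysis must find them.

* **Transcription.** One precursor per locus; length uniform on [31, 40] nt
  (default — this straddles the >30 nt filter so the filter is exercised);
  first nucleotide drawn from `plus_one_weights`, default
  A 0.5 / G 0.3 / C 0.1 / U 0.1, reflecting the purine (A-dominant)
  preference of Pol IV start sites and the observed ~60 % 5′-A share among
  24-nt siRNAs; remaining positions i.i.d. from `body_composition`, default
  uniform, which puts the g2 weak-class baseline at 0.5 so stability-trend
  recovery is tested against a symmetric null.
* **Abundance.** Locus means are log-normal (log-mean 0, log-sd 1.2);
  counts are negative-binomial (dispersion 0.3) around the means and then
  rescaled to exactly `precursor_depth` total reads by a multinomial draw.
  These defaults make the >50-read filter discard a nontrivial minority of
  loci (roughly half at the default depth per locus), so filtering is never
  a no-op in tests.
* **Dicing.** Guides are the 5′-anchored prefixes of the precursor at each
  length with positive length weight (19–25 nt by default), so guide g1
  always equals the precursor +1 nucleotide. The passenger strand is not
  represented; g2 identity on the guide serves as the terminal-pair
  stability proxy. An optional `dicing_bias` multiplier keyed on the
  precursor +1 nucleotide can be enabled to study biogenesis-versus-loading
  confounding (for anchored guides it is mathematically equivalent to an
  extra 5′-weight factor, which is why it is off by default).
* **Loading.** `sirna_depth` reads are drawn multinomially over guides with
  weight = source abundance × 5′-nucleotide weight × (g2 multiplier if g2
  is A/U) × length weight. Three 5′-weight presets are shipped: AGO4-like
  (A 1.0 / U 0.5 / C 0.2 / G 0.3 — the measured in vitro relative loading
  efficiencies), AGO6-like (A 1.0, others 0.05 — a strict-5′A caricature;
  no quantitative AGO6 weights have been measured), and neutral (all 1.0).
  Default length weights peak at 24 nt with most mass on 23–25 nt.
* **Seeding.** One top-level seed per parameter record; every stage draws
  from an independent substream spawned deterministically from it, so the
  same configuration is byte-identical on disk across runs.

What the simulator does **not** emulate: sequencing error, quality scores,
antisense/RDR2-strand reads (including the extra 3′ nucleotide on the RDR2
strand), genomic positional structure beyond one cluster per locus, and
cross-locus sequence similarity (multi-mapping is possible but vanishingly
rare for random 31–40-mers). Passing recovery tests therefore demonstrates
that the analysis correctly extracts loading biases from idealised count
data at realistic depths — not that it is robust to alignment artefacts or
error-containing reads.

### The neutral-loading null bound

Under loading that ignores sequence identity, bin membership is independent
of g1, so the bin4 − bin1 g1-A frequency difference is a difference of two
proportions estimated from disjoint groups of sizes n1 and n4. Its sampling
bound is taken as `3 · sqrt(p(1−p)(1/n1 + 1/n4))` with `p` the catalog-wide
g1-A fraction — a 3-standard-error binomial envelope computed per simulated
dataset.

## In vitro quantification

Gel band intensities enter as a `condition, replicate, intensity` table
(densitometry itself is out of scope). Two normalisations: (i) per
replicate, divide every condition by a reference condition (e.g. the 5′ A
duplex) — invariant to uniform rescaling of a replicate, reference
normalised value exactly 1; (ii) per replicate, divide by the replicate
total so fractions sum to 1 (length-distribution view). Summaries are mean
and sample SD (ddof = 1), matching mean ± SD over technical replicates.
Declared condition pairs are compared with two-sided paired t-tests;
Benjamini–Hochberg step-up adjustment (monotone-enforced, capped at 1) runs
across all non-degenerate comparisons. Comparisons with zero-variance
paired differences are flagged degenerate, reported without a p-value, and
excluded from the adjustment with a warning. Published adjusted p-values
from this kind of experiment depend on unpublished replicate intensities;
the procedure, not any specific p-value, is the contract here.

## Problem sizes for the desk-scale checks

Parameter-recovery runs use 2000 loci, 5×10⁵ precursor reads and 10⁵
AGO-bound reads, 10 seeds per condition (3 seeds per weight level for the
monotonicity check at w_A ∈ {0.25, 1, 4}); oracle-equivalence checks use
1000 random instances of ≤ 50 species, and the Benjamini–Hochberg check
1000 random p-vectors. The full acceptance run completes in about half a
minute on one CPU.

## Known limitations

* Exact-match mapping and sense-strand-only counting may undercount
  relative to a mismatch-tolerant, both-strand pipeline on real libraries.
* CE is the raw ratio with no cross-library depth normalisation, so CE
  values are comparable within one precursor/siRNA library pair, not across
  pairs.
* Multi-mapping siRNAs are double-counted by design (full count to each
  matching species); the fractional option changes totals but not the
  default behaviour.
* The composition analysis is descriptive (as is the figure it mirrors); no
  significance test is attached to composition trends.
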