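# sirnasort

Conversion-efficiency analysis of Pol IV precursor RNAs (P4RNAs) into
AGO4/6-bound heterochromatic siRNAs, for researchers studying small-RNA
sorting and RNA-directed DNA methylation (RdDM) in plants.

In *Arabidopsis*, 24-nt siRNAs that direct DNA methylation are processed
from 30–40 nt Pol IV transcripts and loaded into AGO4-clade Argonautes,
which prefer 24-nt guides with a 5′ adenine. Because the precursor pool is
itself ~60 % 5′ A, comparing AGO-bound and total small RNAs directly says
little about the loading step. This package implements the precursor-
conditioned alternative: for every distinct precursor species *p*,

```
CE(p) = (AGO-bound siRNA reads 5′-anchored on p) / (precursor reads of p)
```

the **conversion efficiency** — the per-sequence rate at which a precursor
becomes AGO-loaded siRNA. Species are split into equal-size ascending-CE
bins (quartiles by default), and the g1 (5′ nucleotide) and g2
(weak A/U vs strong C/G, a 5′ terminal base-pair stability proxy)
composition of each bin is compared: features enriched in the top bin
promote dicing/loading.

The package provides:

* `seqio` — FASTA/FASTQ/BED I/O, exact 3′-adapter trimming, exact
  sense-strand mapping, 5′-anchored hit filtering;
* `catalog` — P4RNA species construction (combine reads sharing a 5′ end;
  strict >30 nt length and >50 read filters);
* `ce` — anchored siRNA counting, CE computation, deterministic ascending
  binning;
* `composition` — per-bin g1 composition, g1-conditioned g2 stability
  classes, and trend summaries (bin 4 − bin 1);
* `simulate` — a generative model of biogenesis (Pol IV +1 purine bias,
  heavy-tailed locus abundance, 5′-anchored 19–25 nt dicing) and AGO
  loading (5′-identity × g2-stability × length weights) for
  parameter-recovery testing, with AGO4-like, AGO6-like and neutral
  presets;
* `quant` — in vitro RISC-assembly gel quantification: reference and
  total normalisation, replicate summaries, paired t-tests with
  Benjamini–Hochberg FDR correction;
* a `sirnasort` CLI with `simulate`, `catalog`, `ce`, `composition`,
  `quant` and `all` subcommands.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a strict-5′A loader and recover the planted bias through the full
catalog → CE → composition pipeline:

```python
from sirnasort import (BiogenesisParams, LoadingParams, AGO6_LIKE_5P_WEIGHTS,
                       make_dataset, analyze, ReferenceSet)

bio = BiogenesisParams(n_loci=500, precursor_depth=100_000, seed=42)
load = LoadingParams(five_prime_weights=AGO6_LIKE_5P_WEIGHTS,
                     sirna_depth=25_000, seed=42)
ds = make_dataset(bio, load)
res = analyze(ds.precursors, ds.sirnas, ReferenceSet(ds.clusters))

print("species pre/post filter:",
      res.counts["species_pre_filter"], "/", res.counts["species_post_filter"])
for b, comp in sorted(res.composition_g1.bins.items()):
    print(f"bin {b} (n={comp.n}): " +
          " ".join(f"{nt}={comp.freqs[nt]:.2f}" for nt in "AUCG"))
print("g1-A trend (bin4 - bin1):", round(res.trends["g1_A"], 3))
```

Output:

```
species pre/post filter: 403 / 174
bin 1 (n=44): A=0.00 U=0.14 C=0.14 G=0.73
bin 2 (n=44): A=0.00 U=0.20 C=0.30 G=0.50
bin 3 (n=43): A=0.88 U=0.00 C=0.05 G=0.07
bin 4 (n=43): A=1.00 U=0.00 C=0.00 G=0.00
g1-A trend (bin4 - bin1): 1.0
```

Of 403 collapsed precursor species, 174 pass the strict length/abundance
filters. Because the simulated Argonaute loads 5′ A guides ~20× more
efficiently than others, A-starting precursors convert best: the lowest-CE
quartile contains no 5′ A species (it is dominated by G, the most common
non-A start), the top quartile is 100 % 5′ A, and the trend summary
(bin 4 − bin 1 A frequency) is +1.0. With the neutral preset the same
pipeline yields trends within binomial sampling noise of zero.

The same run from the shell:

```
sirnasort simulate --outdir sim --seed 42 --n-loci 500 \
    --precursor-depth 100000 --sirna-depth 25000 --preset ago6
sirnasort all --precursors sim/precursors.fasta --sirnas sim/sirnas.fasta \
    --clusters-bed sim/clusters.bed --genome sim/genome.fasta --outdir run
```

which writes `catalog.tsv`, `ce_table.tsv`, `composition_g1.tsv`,
`stability_g1_A.tsv` and a `report.json` with counts at every stage.

For real libraries, pass adapter-contaminated FASTQ plus a cluster BED and
genome FASTA to `sirnasort catalog --adapter TGGAATTCTCGGGTGCCAAGG ...`,
then feed the catalog TSV and the AGO-immunoprecipitated reads to
`sirnasort ce` and `sirnasort composition`.

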