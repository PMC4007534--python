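# endoshrink

Comparative analysis of ortholog **length variability** between obligate
insect endosymbionts (OIE) — host-restricted bacteria with extremely reduced
genomes (≲1 Mb) — and their free-living or facultatively host-associated
relatives (nonOIE). Genome reduction is usually described in terms of gene
loss; this package quantifies a subtler signature: for orthologs shared by
both lifestyles, OIE proteins are not uniformly shorter but more *variable*
in length, with the extra variation carried by indels that concentrate at
the protein terminuses, while the very largest proteins (secondary
metabolism, toxins, surface functions) are missing from OIE proteomes
altogether.

It is written for comparative genomicists who already have the standard
upstream artifacts — proteome FASTAs, an OrthoMCL-style groups file, a
Pfam-style domain table, multiple sequence alignments — and want the
downstream statistics to be reproducible and testable. A synthetic-data
generator produces complete, internally consistent input bundles with known
ground truth, so the entire pipeline runs and is validated without any
download.

## What it computes

For each curated orthologous protein set (identical ordered domain
architecture across members; total-length sample SD < 30 aa, which removes
gene-fusion artifacts; ≥2 members per lifestyle), member lengths are split
into domain and linker totals (linker = total − Σ domain lengths) and three
dispersion statistics are computed per lifestyle group:

* **Range** excluding box-plot outliers: points outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by R's default type-7 rule;
* **SD**, the sample standard deviation (n − 1);
* **IQR** = Q3 − Q1.

Each set is classified per metric (no variability / variable in both /
nonOIE more variable / OIE more variable), and the per-set statistics are
compared between lifestyles with a Welch t-test and a Mann–Whitney test
(exact for small tie-free samples, otherwise the continuity- and
tie-corrected normal approximation, matching R's `wilcox.test`). Alignment
gap positions are profiled in ten equal column sections plus an 11th
remainder section, averaged over triplicate shuffled-order alignments.
Finally a maximum-length census derives the clade cutoff (longest OIE
protein), extracts every strictly longer nonOIE "large protein",
categorizes them core vs secondary/unknown, and checks each for a shortened
OIE ortholog (Smith–Waterman, BLOSUM62, gap open 11 / extend 1; found iff
identity > 65% over > 80% of the OIE protein's length).

## Worked example

Run the numbered analysis drivers from the repository root (each is a thin
script over the `endoshrink` library; data land in `scratch/simdata/`,
tables in `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_curate_decompose.py
python analysis/03_variability.py
python analysis/04_gap_profile.py
python analysis/05_census.py
```

`03_variability.py` prints, for the default synthetic panel (50 ortholog
sets over 6 OIE + 6 nonOIE species, OIE length-jitter SD 10 aa vs nonOIE
2 aa):

```
classification over 50 curated sets (total length):
  range: nonOIE_more_variable 2 (4.0%), OIE_more_variable 48 (96.0%)
     sd: OIE_more_variable 50 (100.0%)
    iqr: OIE_more_variable 50 (100.0%)
per-set dispersion, OIE vs nonOIE:
  range: nonOIE avg 4.16, OIE avg 20.66, t-test p 4.96e-17, Mann-Whitney p 7.01e-17
```

i.e. nearly every set is more length-variable on the OIE side, and the
per-set dispersion difference is overwhelmingly significant — the planted
variance contrast, recovered. `04_gap_profile.py` reports that the terminal
alignment sections out-gap the central ones in 48/50 sets (mean terminal gap
fraction 0.90), and `05_census.py` finds all 14 large proteins in nonOIE
proteomes only (cutoff 1,420 aa), with OIE orthologs detected exactly for
the 2 planted core pairs and the secondary-process proteins significantly
longer than the core ones.

The same pipeline is available as a CLI for external data:

```bash
endoshrink run-all --data-dir data/ --simulate --seed 7 --out-dir results/
endoshrink curate --data-dir data/ --sd-max 30 --out-dir results/
```

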