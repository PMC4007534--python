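# Methods

## The comparison

Two groups of bacterial species are contrasted by lifestyle: obligate insect
endosymbionts (OIE; vertically inherited, host-restricted, genomes roughly
0.2–1 Mb) and everything else in the panel (nonOIE; free-living or
non-obligately host-associated, genomes > 1 Mb). The unit of analysis is the
orthologous protein set — at most one protein per species — and the question
is how the *dispersion* of member lengths differs between the two lifestyle
groups, where in the protein the responsible indels fall, and whether the
upper tail of the proteome length distribution survives genome reduction.

## Curation

Raw ortholog clusters pass three filters before any statistic is computed.

1. **Architecture identity.** A protein's domain architecture is the ordered
   list of domain accessions along the sequence (accessions, not free-text
   names, which drift across database releases). Hits above the e-value
   ceiling (default 1.0, the annotation default) are dropped; a hit entirely
   contained in a larger hit is absorbed by the larger one (the larger
   domain's interval is what counts toward domain length); any *partial*
   overlap between surviving hits disqualifies the protein, and with it the
   group. All members must share one architecture.
2. **Length-SD ceiling.** Groups whose member total lengths have sample
   standard deviation ≥ 30 aa are excluded. Spreads that large in this
   setting are almost always gene fusions in one lineage rather than
   genuine length variation, so the single SD rule subsumes fusion removal.
   The SD is computed over *all* members (not per lifestyle) with the n − 1
   denominator, and the inequality is strict (< 30).
3. **Composition.** ≥ 2 members per lifestyle (configurable), so per-group
   dispersion is defined on both sides. Groups with two proteins from one
   species (inparalogs) are excluded, as are sets in which no member has any
   domain (the analysis is domain-centric; a flag re-admits them).

Every exclusion is logged with a machine-readable reason
(`architecture_mismatch`, `overlap_excluded_member`, `sd_too_large`,
`missing_lifestyle_group`, `inparalogs`, `domain_free`). Retained sets are
emitted sorted by group id, so output order is independent of input order.

## Length decomposition

Domain coordinates are 1-based inclusive; a domain's length is
end − start + 1. Per protein, domain length is the sum over the surviving
(nesting-resolved, non-overlapping) intervals and linker length is
total − domain. Conservation `total = domain + linker` is exact and asserted
pipeline-wide. Overlap resolution happens once, in curation; decomposition
treats overlapping input as a contract violation and raises.

## Dispersion statistics and classification

Per set, per lifestyle, over the chosen length (total, domain or linker):

* **range (outlier-excluded)** — max − min after removing points outside the
  Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR];
* **sd** — sample standard deviation;
* **iqr** — Q3 − Q1.

Quartiles use R's default type-7 rule (numpy's linear interpolation), the
convention behind the box-and-whisker outliers the range statistic excludes.
Classification per metric: both sides ≤ tol → *no variability*; difference
≤ tol with dispersion > tol → *variable in both*; otherwise the larger side
wins. The tie tolerance defaults to 0 and is exposed in the API, since any
nonzero choice is a judgment call.

Group comparison applies a two-sided Welch t-test and a two-sided
Mann–Whitney test to the per-set dispersion values (OIE vs nonOIE across
sets; averaging is per set, not over pooled proteins). The Mann–Whitney
implementation follows R's `wilcox.test` defaults: exact when both samples
have fewer than 50 observations and the pooled sample is tie-free, otherwise
the normal approximation with continuity correction and tie-corrected
variance. Degenerate all-equal input yields t-test p = NA and Mann–Whitney
p = 1. No multiple-testing correction is applied anywhere. Ordinary
least-squares regressions (species-average ortholog length against genome
size) report slope, R² (= squared Pearson correlation) and the slope's
two-sided t-test p; a constant response is returned as slope 0, R² 0 rather
than NaN. Species-level summaries use only curated sets, and the "variance
of averages" statistic is the sample variance of species-average lengths
within a lifestyle (NaN for a single-species lifestyle).

## Gap profiles

Each alignment's columns are divided into 10 equal sections of
⌊width/10⌋ columns plus an 11th C-terminal section holding the remainder
when width mod 10 ≠ 0; widths under 10 are rejected rather than producing
empty sections. Sections are defined over columns — the only reading under
which all rows share section boundaries and the remainder clause is
well-defined. Gap characters ('-' only; '.' is normalized on read with a
warning) are counted per section, pooled over rows; per-row counts are also
available in long format. Replicate alignments of the same sequence set
(shuffled input orders, guarding against aligner order-dependence) are
averaged after zero-padding to 11 sections. The summary statistic
`terminal_bias` is the fraction of mean gap counts in sections 1, 2, 9, 10
and 11; it is NaN for gap-free alignments. Aligner execution is out of
scope: replicate alignments are inputs (the generator's deterministic
edit-replay aligner provides them for synthetic data).

## Census

The clade cutoff is the maximum protein length over the clade's OIE
proteomes; a "large protein" is a nonOIE protein *strictly* longer. Length
ties for a proteome's maximum report the lexicographically smallest protein
id. Categorization (core cellular processes vs secondary/unknown) comes from
an auditable map file — direct id mappings take precedence, then ordered
keyword rules against annotation text, first match wins; unmapped entries
stay `unassigned` and are logged. Category length distributions are compared
with the Mann–Whitney test; alongside U and p the report includes a
continuity- and tie-corrected normal z and its χ² (= z²) equivalent, since
software commonly prints the test in χ² form with 1 df.

A large protein "has an OIE ortholog" iff some OIE protein aligns with
identity > 65% over > 80% of the *OIE* protein's length (coverage is over
the shorter, subject protein). Either precomputed 12-column BLAST tabular
hits are consumed (subject lengths resolved from the OIE proteomes), or an
internal Smith–Waterman is run: BLOSUM62, affine gaps 11/1, identity =
matches / alignment columns with gap columns in the denominator (stated
explicitly because BLAST divides by alignment length of the reported HSP).
A shared 10-mer prescreen skips hopeless pairs before alignment — with the
identity threshold at 65%, any qualifying pair shares many exact 10-mers, so
the screen cannot reject a true positive at these thresholds while making
the all-vs-all census linear in practice.

## Synthetic data

The generator produces a complete input bundle (metadata, proteome FASTAs,
groups file, domain table, triplicate alignments, category map) from a
single integer seed; one `numpy` generator drives all sampling, and a fixed
seed reproduces the bundle byte-for-byte.

Per ortholog set: a random base sequence (default 240–600 aa) carries 1–3
planted non-overlapping domains (30–80 aa) with ≥ 45-aa terminal tails and
≥ 12-aa internal linkers. Each species' copy applies ~2% point substitutions
and at most one indel confined to a linker region, with signed length drawn
as round(N(0, jitter SD)) — default SD 10 aa for OIE copies, 2 aa for nonOIE.
With probability 0.8 the indel lands in the terminal 10% of the sequence
(intersected with the tail linker), otherwise uniformly across linker
regions. Deletions are clamped to fit their linker, which slightly truncates
the lower jitter tail at large draws; domains are never touched, so domain
totals are constant within a set, the architecture filter passes by
construction, and the generator's bookkept total/domain/linker values are an
exact ground truth. Alignments are replayed from the recorded edits: base
positions become columns, insertion sites become padded blocks. Replicates
differ only in row order.

Census structure: one OIE proteome carries a 1,420-aa anchor (making the
cutoff deterministic); each nonOIE proteome receives two secondary-process
accessories of 1,600–3,000 aa; two "core" large proteins (1,450–1,600 aa)
in nonOIE proteomes have OIE counterparts that are prefixes (1,250–1,420 aa)
with ~2% substitutions — comfortably inside the 65%/80% thresholds, while
the random accessories sit far outside them. A `plant_errors` mode appends
deliberately invalid groups (inparalog, overlapping domains, fusion-inflated
SD, extra-domain architecture) to exercise exclusion logging.

What the generator does **not** emulate: phylogenetic correlation among
species, realistic substitution processes (no rate matrices or codon
models), multiple indels per sequence, aligner error, genome-size–dependent
length trends (lengths are independent of genome size by design — the
lifestyle contrast is variance-only, so the regression operations are
validated on their own unit fixtures, and the analysis driver honestly
reports a near-zero slope on synthetic data), and annotation noise in the
domain table. Passing tests therefore demonstrate that the statistics,
filters and bookkeeping are correct and that planted structure of realistic
magnitude is recovered — not that real proteomes behave this way.

## Problem sizes and numerical choices

The default panel is 50 ortholog sets over 6 + 6 species — large enough that
classification proportions are stable to a few percent and the group tests
are decisive, small enough that the full pipeline runs in seconds. The
conservation study uses 200 independent miniature bundles (3 sets, 2 + 2
species); the null-calibration study uses 200 lengths-only datasets of 20
sets each (equal jitter SD 5 in both groups) and checks the Welch t-test's
rejection rate against the central 99% binomial interval around 5%.
Floats in TSV outputs are printed with 6 significant digits; NaN prints as
`NA`. Quantile and fence arithmetic is double precision throughout; the
oracle-agreement checks tolerate only rounding-level discrepancy (≤1e-9).
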