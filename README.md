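# ffascreen

Proteome-based screening, scoring and ranking of microbial strains — in
particular cyanobacteria — for their potential to produce and secrete free
fatty acids (FFAs), the precursor molecules of drop-in biofuels.

Experimentally evaluating a strain as a microbial-cell-factory chassis is
slow and expensive, and sequenced genomes far outnumber characterised
strains. `ffascreen` ranks candidate strains *in silico* from their predicted
proteomes: a curated panel of proteins known to raise, lower, or be required
for FFA production is searched against each proteome, and each strain is
summarised, scored and placed into a producer category. It is aimed at
biotechnologists choosing which strains to take into the lab, upstream of
flux-design tools that plan the actual genetic interventions.

## Method

**Feature generation.** For each panel criterion protein *c*, homology
evidence (BLAST tabular) and domain evidence (HMMER `domtblout`) are
combined under a stringent completeness rule: a hit of *c* on strain protein
*p* counts only if

- E-value(c→p) ≤ τ (default 10⁻⁵), and
- dom(c) ⊆ dom(p) — *p* carries **every** domain of *c* (set inclusion on
  accessions; annotations pass an i-Evalue cut of 10⁻⁵).

Criteria are organised into orthologous groups (OGs); a group is *satisfied*
when any member is present, so a backup enzyme catalysing the same metabolic
step substitutes for the primary one. The strain's profile records
per-criterion hit counts x_c, presence 1[x_c > 0], and per-OG satisfaction.

**Scoring and categorisation.** The raw score is a signed weighted sum

    S = Σ_c w_c · x_c ,   w_c > 0 for positive/required criteria,
                          w_c < 0 for negative ones

with presence features by default and unit magnitudes unless calibrated.
Cohort scores are min-max normalised, S̃ = (S − S_min)/(S_max − S_min), so
the top strain scores 1 and the bottom 0, then ranked (ties broken by strain
id). Categories are anchored to reference strains: scores strictly above the
positive upper-reference strain are **Top-ranked**; scores above the lower
boundary strain — the lowest-scoring member of the 2-means score cluster
that contains the positive references — are **Positive**; the rest are
**Negative**. Weight magnitudes can be calibrated by maximising the worst
positive-vs-negative reference margin (L2-normalised hinge, coordinate
ascent) so that every positive reference outranks every negative one.

Each screened strain also receives engineering recommendations: insert or
overexpress each absent positive criterion and one representative member of
each unsatisfied required OG; delete or underexpress each present negative
criterion.

A built-in Smith–Waterman aligner and segment-based domain annotator let the
entire pipeline run without external search binaries; real screens should
supply BLAST/HMMER output.

## Worked example

```sh
python examples/rank_cohort.py
```

generates a 64-criterion panel (12 required OGs) and a 12-strain cohort with
injected reference strains, runs the full evidence pipeline and prints:

```
rank  strain          raw  normalized  category
   1  REF_POS_2      49.0      1.0000  Top-ranked
   2  REF_POS_1      48.0      0.9800  Positive
   3  STR002         35.0      0.7200  Positive
   ...
  10  STR005         22.0      0.4600  Negative
  11  REF_BOUND      13.0      0.2800  Negative
  12  REF_NEG_1      -1.0      0.0000  Negative
```

The raw score counts presence of beneficial criteria minus presence of
detrimental ones; the normalized column rescales it over the cohort (top
strain = 1). `REF_POS_1` is the upper category boundary — the one strain
scoring above it is Top-ranked — and the 2-means split put strains from
`STR005` down into the Negative category. The other examples screen a single
new strain against a stored cohort (`screen_new_strain.py`), demonstrate the
domain-completeness rule (`domain_complete_filter.py`), and calibrate
weights against references (`calibrate_weights.py`).

The same workflows are available from the shell:

```sh
ffascreen simulate --n-strains 12 --seed 1 --out demo/
ffascreen rank --panel demo/panel.tsv --panel-fasta demo/panel.fasta \
               --bundle demo/ --out demo_ranked/
ffascreen screen --panel demo/panel.tsv --panel-fasta demo/panel.fasta \
                 --proteome my_strain.fasta --strain-id my_strain \
                 --blast-tab my_strain.blast.tsv --domtbl my_strain.domtbl \
                 --cohort demo_ranked/cohort.csv --out my_strain_report/
```

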