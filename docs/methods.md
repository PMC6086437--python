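# Methods

## The screening model

`ffascreen` treats chassis selection as a presence/absence screening problem
over a curated protein panel. Each panel criterion is a protein with a known
impact on free-fatty-acid (FFA) production — `positive` (its presence helps,
e.g. thioesterases), `negative` (its presence diverts flux or degrades FFAs),
or `required` (part of the fatty-acid synthesis route itself). Criteria are
grouped into orthologous groups (OGs); required OGs may contain a backup
enzyme catalysing the same step (e.g. pyruvate,water dikinase EC 2.7.9.2
backed by pyruvate,phosphate dikinase EC 2.7.9.1), and a group is satisfied
by any member. The model assumes that native proteome composition is
informative about engineerability — it deliberately ignores expression
levels, flux, growth conditions and FFA chain-length preference.

### Presence calls

A criterion is present in a strain when at least one proteome protein is a
*domain-complete* homolog:

1. homology: a BLAST-tabular hit with E-value ≤ `max_evalue`;
2. completeness: the subject carries every domain accession of the query
   (HMMER domtblout annotations with i-Evalue ≤ `max_ievalue`).

Domain comparison is set inclusion on version-stripped accessions; order and
copy number are ignored, because completeness — not architecture layout — is
the condition being enforced. Criteria with no recorded domains pass the
domain test vacuously. Hit counts are distinct subject proteins per
criterion, which is robust to one alignment fragmenting into several HSPs.

### Score, normalisation, categories

Raw score: S = Σ_c w_c·x_c with sign-constrained weights (positive/required
> 0, negative < 0) and presence features by default (`feature_mode="count"`
switches to hit counts). Cohort scores are min-max normalised; a fully
degenerate cohort (all raw scores equal) maps every strain to 0.5 rather
than dividing by zero. Ranks descend by score with ascending-id tie-breaks
so output is reproducible.

Categories are anchored to reference strains rather than absolute
thresholds, because the score scale is cohort-relative. "Higher than" is
strict: a score equal to the upper reference is Positive, equal to the lower
boundary is Negative. The lower boundary strain is found by clustering the
cohort's 1-D scores into two groups and taking the lowest-scoring strain of
the cluster containing all positive references. Because the 2-means optimum
on a line is a contiguous split of the sorted values, the split is computed
exactly by scanning the N−1 candidate splits for minimal within-cluster SSE
(ties resolve to the smaller low-cluster). This is deterministic and
verifiably optimal, whereas Lloyd iteration from heuristic centers can stall
in a local optimum; the `seed` argument is retained for API stability only.
If the positive references straddle the split the boundary is undefined and
an error is raised instead of guessing.

### Weight calibration

The only supervision available is qualitative: positive reference strains
must outrank negative ones. Calibration therefore maximises the worst
pairwise margin min_{p,n} (S_p − S_n) / ‖w‖₂ by deterministic coordinate
ascent over per-criterion magnitudes (multiplicative steps ×2, ×1.25, ×0.8,
×0.5), starting from unit magnitudes. Two choices matter:

- the margin is L2-normalised because the raw margin is scale-covariant
  (doubling all weights doubles it), which would make ascent divergent;
- magnitudes are clamped to [0.25, 4], keeping calibrated weights anchored
  to the unit prior. A handful of reference strains cannot identify 64
  magnitudes; the clamp prevents the few criteria that happen to
  discriminate the references from dominating the cohort-wide ranking.

A final margin ≤ 0 flags the references as non-separable (returned, not
raised: the caller decides whether to proceed). `max_iter` bounds the number
of full coordinate passes (default 30; ascent typically converges earlier).

### New-strain evaluation

A new strain's raw score joins the stored cohort raw scores; normalisation
and ranks are recomputed over cohort ∪ {new} so normalized scores stay in
[0, 1] even when the newcomer beats the old maximum. Stored cohort data is
never mutated — the updated ranking is a recomputed view. The result exposes
the four user-facing outputs: score, category, recommendations, rank.

### Recommendations

One insert/overexpress entry per absent positive criterion, one per
unsatisfied required OG (its first panel-order member only — any single
member satisfies the group, so listing all would be redundant), and one
delete/underexpress entry per present negative criterion, in panel order.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `max_evalue` | 1e-5 | BLAST E-value cut (dimensionless expectation) |
| `max_ievalue` | 1e-5 | HMMER per-domain independent E-value cut |
| `feature_mode` | presence | binary features; `count` uses hit counts |
| weights | ±1 | unit magnitudes, sign from impact class |
| calibration clamp | [0.25, 4] | allowed magnitude range around unit |
| `min_score_ratio` (fallback search) | 0.5 | fraction of query self-score to accept |

The homology thresholds are conventional cutoffs for protein searches; the
filtering *semantics* (domain completeness) carries the methodological
weight, and both cuts are configurable.

## The synthetic-data generator

The generator emulates the structure of the real evaluation so every stage
is testable without genome downloads: panels of 64 criteria with 12 required
OGs (extra required members join groups as backups), cohorts of 140 strains
by default, and four injected reference-like strains (two strong producers
with all required OGs, a marginal boundary strain, a poor producer) mirroring
the role of experimentally characterised anchors. Default presence
probabilities (positive 0.6, negative 0.4, required 0.9) reflect that the
complete synthesis route is present in well over half of real strains while
beneficial and detrimental accessories vary. Ground-truth weights for
recovery studies draw magnitudes from U(0.5, 1.5) — a modest effect-size
spread around the unit prior.

Proteomes contain per-residue-mutated copies (default rate 0.02) of the
present panel sequences plus 5 random decoys, rejection-sampled to share
fewer than two 6-mers with any panel sequence so they are unambiguous
negatives for the seeded fallback search. Emitted evidence files are
consistent with the proteome by construction: one BLAST hit per present
criterion, full domain annotations laid out on equal sequence segments (the
same segmentation the fallback annotator assumes), and optional deliberate
domain omissions to exercise the completeness filter end to end. Everything
derives from `numpy` generators seeded from the cohort seed (per-strain
streams keyed by CRC32 of the strain id), so identical specs give
byte-identical files.

What the generator does **not** emulate: real sequence evolution (no
indels, no domain shuffling, uniform substitution), real BLAST/HMMER
statistics (fixture E-values are fixed constants), paralog interference, or
incomplete genome assemblies. Passing tests therefore demonstrate that the
pipeline's logic is correct under clean, controlled evidence — not that any
particular real strain ranking is right, which additionally depends on the
curated panel and search quality.

## The fallback aligner and annotator

`align_local` is a Smith–Waterman implementation with linear gap penalty,
returning the maximal score and one optimal span with a fixed tie-break
(smallest (q_end, s_end); traceback prefers diagonal, then up, then left).
The internal search prefilters candidate subjects by shared 6-mer count
(a seed-and-extend heuristic) and accepts a subject at ≥ 50% of the query's
self-alignment score; domains are annotated by aligning the query's equal
sequence segments individually under the same rule. This substitutes for
external binaries in tests and demos only — it computes no E-value
statistics and is not a BLAST/HMMER replacement.

## Numerical and edge-case choices

- Min-max normalisation with an explicit all-equal → 0.5 rule.
- The exact 1-D 2-means split uses prefix sums; tie on SSE → smallest split.
- If every cohort score is equal, boundary detection returns the first
  strain id — one indistinguishable cluster — instead of erroring.
- The lower boundary score is clipped to the upper reference score if
  clustering places it above (possible when the upper reference is not the
  top positive reference).
- Alignment scoring accepts floats but returns integer scores when the
  parameters are integral; fixture scoring uses integers so DP and traceback
  comparisons are exact.
- Empty sequences align with score 0 and empty spans rather than erroring.

## Problem sizes used in the shipped studies

The test suite and acceptance script run at desk scale by design: cohorts of
12–140 strains over 30–64 criteria, 20 calibration replicates of 50 strains,
1,000-profile scoring oracles and 200-cohort boundary oracles, and 20-strain
noise-free end-to-end recovery with the built-in aligner. These sizes
exercise every code path while keeping a full run to a few minutes on one
CPU.

## Known limitations

- The score is linear and presence-based; epistasis between panel proteins,
  expression and flux are out of model.
- Calibration recovers reference *ordering*, not true weight magnitudes;
  with a handful of references many weight vectors are equivalent.
- The categorisation is cohort-relative: adding strains can move the
  boundary and relabel existing strains (by design, matching the
  renormalise-on-insert semantics).
- The fallback aligner is quadratic per pair and unsuitable for real
  proteome-scale searches; use BLAST/HMMER evidence files there.
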