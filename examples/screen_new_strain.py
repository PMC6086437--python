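"""Screen one new strain against a pre-evaluated cohort.

A new strain joins an already-scored cohort: its raw score is computed from
its profile, normalization and ranks are recomputed over the enlarged
cohort, and the strain gets a category plus engineering recommendations
(insert/overexpress absent positive or required proteins, delete/
underexpress present negative ones).
"""

from ffascreen import (
    CohortSpec,
    StrainProfile,
    evaluate_new_strain,
    make_panel,
    make_profile_cohort,
    score_raw,
    unit_weights,
)

panel = make_panel(40, 12, 12, 12, 3, seed=1)
pc = make_profile_cohort(panel, CohortSpec(n_strains=20, seed=1))
weights = unit_weights(panel)
cohort_raws = {p.strain_id: score_raw(p, weights) for p in pc.profiles}

# the new strain: all required groups satisfied, most positives, two negatives
present = [
    c.criterion_id
    for c in panel.criteria
    if c.impact.value in ("positive", "required")
][:-5] + ["NEG001", "NEG002"]
new = StrainProfile.from_presence("my_new_isolate", present, panel)

result = evaluate_new_strain(new, cohort_raws, weights, pc.refs, panel)

print(f"strain        : {result.record.strain_id}")
print(f"score         : {result.score:.4f}   (min-max normalized over the cohort)")
print(f"category      : {result.category.value}")
print(f"rank          : {result.rank} of {len(result.ranking)}")
print(f"recommendations ({len(result.recommendations)}):")
for rec in result.recommendations[:8]:
    print(f"  {rec.criterion_id:<8} {rec.action.value:<24} {rec.reason.value}")
print(
    "\nEach recommendation names a panel protein: additions raise the predicted"
    "\nFFA potential, deletions remove proteins that suppress it."
)
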