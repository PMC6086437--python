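"""Calibrate criterion weights against reference strains.

Starting from unit weights (+1 positive/required, -1 negative), coordinate
ascent adjusts per-criterion magnitudes to maximize the worst margin between
positive and negative reference strains. The calibrated weights must keep
every positive reference above every negative reference in the final
ranking — the anchoring property of the score scale.
"""

from ffascreen import (
    CohortSpec,
    calibrate_weights,
    make_panel,
    make_profile_cohort,
    score_cohort,
)

panel = make_panel(40, 12, 12, 12, 3, seed=2)
pc = make_profile_cohort(panel, CohortSpec(n_strains=40, seed=2))

cal = calibrate_weights(pc.profiles, panel, pc.refs)
print(f"separable        : {cal.separable}")
print(f"normalized margin: {cal.margin:.4f}  (worst pos-vs-neg raw gap / ||w||)")

records = score_cohort(pc.profiles, cal.weights, pc.refs)
rank = {r.strain_id: r.rank for r in records}
for ref in (*pc.refs.positive_refs, *pc.refs.negative_refs):
    kind = "positive" if ref in pc.refs.positive_refs else "negative"
    print(f"  {ref:<10} ({kind} reference) rank {rank[ref]:>2} of {len(records)}")
print(
    "\nA positive margin means the references are linearly separable under"
    "\nsign-constrained weights; the ranking above shows the ordering holds."
)
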