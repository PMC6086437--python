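"""The stringent domain-completeness rule on a minimal case.

A homology hit only counts as presence when the subject protein carries
every domain of the query panel protein. A subject missing even one query
domain is discarded — the rule that, in the real screen, declared pyruvate
dehydrogenase E2 absent from a strain whose BLAST hit lacked a domain.
"""

from ffascreen import HomologyHit, filter_domain_complete

query_domains = {"acc_carboxylase": frozenset({"SYND00001", "SYND00002"})}

hit = HomologyHit(
    query_id="acc_carboxylase", subject_id="strainX_p0001",
    pct_identity=91.0, align_length=310, mismatches=28, gap_opens=0,
    q_start=1, q_end=310, s_start=1, s_end=310,
    e_value=1e-60, bit_score=580.0,
)

for annotated, label in [
    ({"strainX_p0001": {"SYND00001", "SYND00002", "SYND00009"}}, "superset of query domains"),
    ({"strainX_p0001": {"SYND00001"}}, "one query domain missing"),
]:
    kept = filter_domain_complete([hit], query_domains, annotated)
    verdict = "retained" if kept else "discarded"
    print(f"subject with {label:<28} -> hit {verdict}")

print(
    "\nOnly the first subject counts toward presence: completeness is set"
    "\ninclusion over domain accessions, regardless of order or copy number."
)
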