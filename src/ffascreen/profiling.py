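"""Feature generation: turn filtered homology hits into strain profiles.

This is the first phase of the evaluation: each strain is summarised as a
per-criterion hit-count/presence vector plus per-orthologous-group
satisfaction flags. A group is satisfied when *any* member is present —
this is how a backup enzyme catalysing the same metabolic step stands in
for the primary one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .evidence import HomologyHit
from .panel import Impact, Panel


@dataclass
class StrainProfile:
    """Per-strain feature vector over a panel's criteria and groups."""

    strain_id: str
    hit_counts: dict[str, int]
    presence: dict[str, bool]
    og_satisfied: dict[str, bool]

    @classmethod
    def from_presence(
        cls, strain_id: str, present: Iterable[str], panel: Panel
    ) -> "StrainProfile":
        """Build a profile directly from a known presence set (count 1/0)."""
        present = set(present)
        unknown = present - set(panel.criterion_ids)
        if unknown:
            raise ConfigurationError(
                f"presence set names unknown criteria: {sorted(unknown)}"
            )
        counts = {cid: int(cid in present) for cid in panel.criterion_ids}
        return cls(strain_id, counts, *_derive(counts, panel))


def _derive(counts: dict[str, int], panel: Panel):
    presence = {cid: counts[cid] > 0 for cid in panel.criterion_ids}
    og = {
        g.og_id: any(presence[m] for m in g.member_criterion_ids)
        for g in panel.groups
    }
    return presence, og


def build_profile(
    strain_id: str, filtered_hits: Sequence[HomologyHit], panel: Panel
) -> StrainProfile:
    """Count distinct subject proteins per criterion and derive presence and
    OG satisfaction.

    ``filtered_hits`` are expected to have passed the domain-completeness
    filter already; a hit naming a criterion outside the panel is an error.
    """
    ids = set(panel.criterion_ids)
    subjects: dict[str, set[str]] = {cid: set() for cid in panel.criterion_ids}
    for h in filtered_hits:
        if h.query_id not in ids:
            raise ConfigurationError(f"hit names unknown criterion {h.query_id!r}")
        subjects[h.query_id].add(h.subject_id)
    counts = {cid: len(s) for cid, s in subjects.items()}
    return StrainProfile(strain_id, counts, *_derive(counts, panel))


def count_required_ogs(profile: StrainProfile, panel: Panel) -> int:
    """Number of required-impact orthologous groups satisfied by the strain.

    Model producer strains satisfy all required groups; a strain missing,
    say, only the pyruvate-water-dikinase group (both the primary enzyme and
    its backup absent) scores one less.
    """
    return sum(
        profile.og_satisfied[g.og_id]
        for g in panel.groups
        if g.impact is Impact.REQUIRED
    )


def profile_table(profiles: Sequence[StrainProfile]) -> pd.DataFrame:
    """Long-format per-criterion export (strain_id, criterion_id, hit_count, presence)."""
    rows = [
        {
            "strain_id": p.strain_id,
            "criterion_id": cid,
            "hit_count": count,
            "presence": p.presence[cid],
        }
        for p in profiles
        for cid, count in p.hit_counts.items()
    ]
    return pd.DataFrame(rows, columns=["strain_id", "criterion_id", "hit_count", "presence"])


def og_summary(profiles: Sequence[StrainProfile], panel: Panel) -> pd.DataFrame:
    """Per-group export (strain_id, og_id, impact, satisfied)."""
    rows = [
        {
            "strain_id": p.strain_id,
            "og_id": g.og_id,
            "impact": g.impact.value,
            "satisfied": p.og_satisfied[g.og_id],
        }
        for p in profiles
        for g in panel.groups
    ]
    return pd.DataFrame(rows, columns=["strain_id", "og_id", "impact", "satisfied"])
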