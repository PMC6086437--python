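"""Engineering suggestions derived from a strain profile.

For each strain the screen reports which panel proteins to add (absent
positive-impact proteins, unsatisfied required groups) and which to remove
(present negative-impact proteins). For an unsatisfied required group only
one representative member is suggested — any single member satisfies the
group, backup enzymes included.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .panel import Impact, Panel
from .profiling import StrainProfile


class Action(str, Enum):
    INSERT_OR_OVEREXPRESS = "insert_or_overexpress"
    DELETE_OR_UNDEREXPRESS = "delete_or_underexpress"


class Reason(str, Enum):
    MISSING_POSITIVE = "missing_positive"
    MISSING_REQUIRED = "missing_required"
    PRESENT_NEGATIVE = "present_negative"


@dataclass(frozen=True)
class Recommendation:
    criterion_id: str
    action: Action
    reason: Reason

    def __post_init__(self):
        insert = self.action is Action.INSERT_OR_OVEREXPRESS
        missing = self.reason in (Reason.MISSING_POSITIVE, Reason.MISSING_REQUIRED)
        if insert != missing:
            raise ValueError("action/reason combination is inconsistent")


def suggest_modifications(profile: StrainProfile, panel: Panel) -> list[Recommendation]:
    """Build the modification list for one strain, in panel order.

    * absent positive criterion → insert/overexpress (missing_positive)
    * unsatisfied required group → insert/overexpress its first panel-order
      member (missing_required)
    * present negative criterion → delete/underexpress (present_negative)
    """
    recs: list[Recommendation] = []
    first_member = {g.og_id: g.member_criterion_ids[0] for g in panel.groups}
    for c in panel.criteria:
        present = profile.presence[c.criterion_id]
        if c.impact is Impact.POSITIVE and not present:
            recs.append(
                Recommendation(c.criterion_id, Action.INSERT_OR_OVEREXPRESS, Reason.MISSING_POSITIVE)
            )
        elif c.impact is Impact.NEGATIVE and present:
            recs.append(
                Recommendation(c.criterion_id, Action.DELETE_OR_UNDEREXPRESS, Reason.PRESENT_NEGATIVE)
            )
        elif (
            c.impact is Impact.REQUIRED
            and not profile.og_satisfied[c.og_id]
            and first_member[c.og_id] == c.criterion_id
        ):
            recs.append(
                Recommendation(c.criterion_id, Action.INSERT_OR_OVEREXPRESS, Reason.MISSING_REQUIRED)
            )
    return recs


def recommendations_table(
    strain_id: str, recs: list[Recommendation], panel: Panel
) -> pd.DataFrame:
    """Recommendations as a CSV-ready table with gene symbols attached."""
    rows = [
        {
            "strain_id": strain_id,
            "criterion_id": r.criterion_id,
            "gene_symbol": panel.criterion(r.criterion_id).gene_symbol,
            "action": r.action.value,
            "reason": r.reason.value,
        }
        for r in recs
    ]
    return pd.DataFrame(
        rows, columns=["strain_id", "criterion_id", "gene_symbol", "action", "reason"]
    )
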