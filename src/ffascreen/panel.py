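"""Criteria-panel data model and I/O.

A *panel* is the curated list of proteins whose presence in a strain's
predicted proteome raises, lowers, or is required for free-fatty-acid (FFA)
production. Each criterion carries its impact class, the orthologous group
(OG) it belongs to, and the domain architecture used by the
domain-completeness filter. The on-disk representation is a UTF-8 TSV with a
fixed header plus a protein FASTA whose record ids are criterion ids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CrossReferenceError,
    PanelSchemaError,
    PanelValidationError,
    PanelValueError,
)

PANEL_COLUMNS = (
    "criterion_id",
    "gene_symbol",
    "kegg_ko",
    "ec_number",
    "impact",
    "og_id",
    "domains",
    "action_hint",
)

#: 20 standard residues plus X (unknown).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Impact(str, Enum):
    """How a criterion protein affects FFA production."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    REQUIRED = "required"


class ActionHint(str, Enum):
    """Engineering action associated with a criterion in the panel."""

    INSERTION = "insertion"
    DELETION = "deletion"
    OVEREXPRESSION = "overexpression"
    UNDEREXPRESSION = "underexpression"
    PRESENT_REQUIRED = "present_required"


@dataclass(frozen=True)
class PanelCriterion:
    """One curated protein criterion."""

    criterion_id: str
    gene_symbol: str
    kegg_ko: str
    ec_number: str
    impact: Impact
    og_id: str
    domain_accessions: tuple[str, ...]
    action_hint: ActionHint


@dataclass(frozen=True)
class OrthologousGroup:
    """A set of functionally interchangeable criteria (e.g. a backup enzyme
    catalysing the same metabolic step); satisfied when any member is
    present."""

    og_id: str
    impact: Impact
    member_criterion_ids: tuple[str, ...]


@dataclass
class Panel:
    """A validated criteria panel: criteria, their OGs and their sequences."""

    criteria: list[PanelCriterion]
    groups: list[OrthologousGroup]
    sequences: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_criteria(
        cls, criteria: Iterable[PanelCriterion], sequences: Mapping[str, str] | None = None
    ) -> "Panel":
        """Build a panel, reconstructing OGs from each criterion's ``og_id``.

        Groups appear in order of first occurrence; members keep criteria
        order. Group impact is taken from the first member (mixed-impact
        groups are reported by :func:`validate_panel`).
        """
        criteria = list(criteria)
        order: list[str] = []
        members: dict[str, list[str]] = {}
        impacts: dict[str, Impact] = {}
        for c in criteria:
            if c.og_id not in members:
                order.append(c.og_id)
                members[c.og_id] = []
                impacts[c.og_id] = c.impact
            members[c.og_id].append(c.criterion_id)
        groups = [
            OrthologousGroup(og, impacts[og], tuple(members[og])) for og in order
        ]
        return cls(criteria, groups, dict(sequences or {}))

    # -- lookups -----------------------------------------------------------

    @property
    def criterion_ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria]

    def criterion(self, criterion_id: str) -> PanelCriterion:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def group(self, og_id: str) -> OrthologousGroup:
        for g in self.groups:
            if g.og_id == og_id:
                return g
        raise KeyError(og_id)

    def required_groups(self) -> list[OrthologousGroup]:
        return [g for g in self.groups if g.impact is Impact.REQUIRED]

    def query_domains(self) -> dict[str, frozenset[str]]:
        """criterion_id -> set of domain accessions (the filter's query side)."""
        return {c.criterion_id: frozenset(c.domain_accessions) for c in self.criteria}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return (
            self.criteria == other.criteria
            and self.groups == other.groups
            and self.sequences == other.sequences
        )


def validate_panel(panel: Panel) -> list[str]:
    """Enumerate every structural invariant violation (empty list = valid).

    Violations are data, not exceptions: each entry names the offending
    criterion or group.
    """
    violations: list[str] = []
    seen_ids: set[str] = set()
    for c in panel.criteria:
        if c.criterion_id in seen_ids:
            violations.append(f"duplicate criterion_id: {c.criterion_id}")
        seen_ids.add(c.criterion_id)

    group_ids: set[str] = set()
    group_by_id: dict[str, OrthologousGroup] = {}
    for g in panel.groups:
        if g.og_id in group_ids:
            violations.append(f"duplicate og_id: {g.og_id}")
        group_ids.add(g.og_id)
        group_by_id[g.og_id] = g
        if not g.member_criterion_ids:
            violations.append(f"group {g.og_id}: empty member list")
        for m in g.member_criterion_ids:
            if m not in seen_ids:
                violations.append(f"group {g.og_id}: member {m} is not a panel criterion")

    for c in panel.criteria:
        g = group_by_id.get(c.og_id)
        if g is None:
            violations.append(f"criterion {c.criterion_id}: og_id {c.og_id} not in groups")
        else:
            if c.criterion_id not in g.member_criterion_ids:
                violations.append(
                    f"criterion {c.criterion_id}: group {c.og_id} does not list it as a member"
                )
            if c.impact is not g.impact:
                violations.append(
                    f"group {c.og_id}: member {c.criterion_id} impact {c.impact.value} "
                    f"differs from group impact {g.impact.value}"
                )

    for cid, seq in panel.sequences.items():
        if cid not in seen_ids:
            violations.append(f"sequence {cid}: no matching criterion")
        if not seq:
            violations.append(f"sequence {cid}: empty")
        else:
            bad = set(seq.upper()) - AMINO_ACIDS
            if bad:
                violations.append(
                    f"sequence {cid}: invalid residues {''.join(sorted(bad))}"
                )
    return violations


def _parse_enum(enum_cls, value: str, column: str, row_id: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise PanelValueError(
            f"criterion {row_id}: {column} value {value!r} not one of: {allowed}"
        ) from None


def load_panel(path: str | Path, seq_path: str | Path) -> Panel:
    """Load and validate a panel from a TSV table plus a protein FASTA.

    Raises a schema error naming any missing column, a value error for an
    unknown impact/action vocabulary entry, a cross-reference error for a
    FASTA id with no criterion row, and a validation error if the assembled
    panel violates a structural invariant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(
            f"panel table {path}: missing column(s): {', '.join(missing)}"
        )

    criteria = []
    for row in df.itertuples(index=False):
        domains = tuple(d for d in (s.strip() for s in row.domains.split(";")) if d)
        criteria.append(
            PanelCriterion(
                criterion_id=row.criterion_id,
                gene_symbol=row.gene_symbol,
                kegg_ko=row.kegg_ko,
                ec_number=row.ec_number,
                impact=_parse_enum(Impact, row.impact, "impact", row.criterion_id),
                og_id=row.og_id,
                domain_accessions=domains,
                action_hint=_parse_enum(
                    ActionHint, row.action_hint, "action_hint", row.criterion_id
                ),
            )
        )

    known_ids = {c.criterion_id for c in criteria}
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(seq_path), "fasta"):
        if rec.id not in known_ids:
            raise CrossReferenceError(
                f"panel FASTA {seq_path}: id {rec.id!r} has no criterion row"
            )
        sequences[rec.id] = str(rec.seq).upper()

    panel = Panel.from_criteria(criteria, sequences)
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(
            f"panel {path}: {len(violations)} invariant violation(s): "
            + "; ".join(violations)
        )
    return panel


def write_panel(panel: Panel, path: str | Path, seq_path: str | Path) -> None:
    """Write a panel back to the TSV + FASTA pair read by :func:`load_panel`."""
    rows = [
        {
            "criterion_id": c.criterion_id,
            "gene_symbol": c.gene_symbol,
            "kegg_ko": c.kegg_ko,
            "ec_number": c.ec_number,
            "impact": c.impact.value,
            "og_id": c.og_id,
            "domains": ";".join(c.domain_accessions),
            "action_hint": c.action_hint.value,
        }
        for c in panel.criteria
    ]
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(path, sep="\t", index=False)

    records = [
        SeqRecord(Seq(panel.sequences[c.criterion_id]), id=c.criterion_id, description="")
        for c in panel.criteria
        if c.criterion_id in panel.sequences
    ]
    with open(seq_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def panel_to_text(panel: Panel) -> tuple[str, str]:
    """Render the panel's TSV and FASTA as strings (used by the generator)."""
    tsv = io.StringIO()
    fasta = io.StringIO()
    rows = [
        {
            "criterion_id": c.criterion_id,
            "gene_symbol": c.gene_symbol,
            "kegg_ko": c.kegg_ko,
            "ec_number": c.ec_number,
            "impact": c.impact.value,
            "og_id": c.og_id,
            "domains": ";".join(c.domain_accessions),
            "action_hint": c.action_hint.value,
        }
        for c in panel.criteria
    ]
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(tsv, sep="\t", index=False)
    records = [
        SeqRecord(Seq(panel.sequences[c.criterion_id]), id=c.criterion_id, description="")
        for c in panel.criteria
        if c.criterion_id in panel.sequences
    ]
    SeqIO.write(records, fasta, "fasta")
    return tsv.getvalue(), fasta.getvalue()
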