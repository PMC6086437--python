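"""Synthetic fixture generator: panels, proteomes, evidence files, cohorts.

Everything the screening pipeline consumes can be generated here with known
ground truth — a criteria panel with positive/negative/required classes and
required orthologous groups (some holding a backup co-member), per-strain
proteomes containing mutated copies of the panel proteins they "possess"
plus random decoys, and evidence files (BLAST tabular + HMMER domtblout)
consistent with those proteomes. Generation is fully deterministic given the
seed: the same spec always yields byte-identical files.

The generator emulates the structure of the real evaluation — a 64-protein
panel with 12 required groups screened over a 140-strain cohort with
experimentally anchored reference strains — not real cyanobacterial
sequence evolution. Decoys are random sequences rejection-sampled to share
fewer than two 6-mers with any panel protein, so they are unambiguous
negatives for the seeded fallback search.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .evidence import HomologyHit, domain_segments, write_blast_tabular
from .panel import ActionHint, Impact, Panel, PanelCriterion, write_panel
from .profiling import StrainProfile
from .scoring import (
    ReferenceConfig,
    WeightVector,
    normalize_scores,
    rank_cohort,
    score_raw,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_PRESENCE = MappingProxyType(
    {Impact.POSITIVE: 0.6, Impact.NEGATIVE: 0.4, Impact.REQUIRED: 0.9}
)

#: Injected reference strains: two strong producers, a marginal boundary
#: strain, and a poor producer; per-class presence probabilities.
REFERENCE_PRESENCE = MappingProxyType(
    {
        "REF_POS_1": {Impact.POSITIVE: 0.95, Impact.NEGATIVE: 0.05, Impact.REQUIRED: 1.0},
        "REF_POS_2": {Impact.POSITIVE: 0.90, Impact.NEGATIVE: 0.10, Impact.REQUIRED: 1.0},
        "REF_BOUND": {Impact.POSITIVE: 0.35, Impact.NEGATIVE: 0.55, Impact.REQUIRED: 0.75},
        "REF_NEG_1": {Impact.POSITIVE: 0.05, Impact.NEGATIVE: 0.95, Impact.REQUIRED: 0.30},
    }
)

SYNTHETIC_REFS = ReferenceConfig(
    positive_refs=("REF_POS_1", "REF_POS_2"),
    negative_refs=("REF_NEG_1",),
    upper_boundary="REF_POS_1",
    lower_boundary="REF_BOUND",
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the evaluated collection: 140 strains, most strains
    carrying most required-group members (the complete synthesis route is
    present in well over half of real strains), positive-impact proteins
    moderately common and negative-impact proteins widespread, a handful of
    decoy proteins per strain, and light sequence divergence from the panel
    representatives.
    """

    n_strains: int = 140
    presence_probability: Mapping[Impact, float] = field(
        default_factory=lambda: dict(_DEFAULT_PRESENCE)
    )
    decoys_per_strain: int = 5
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        for impact, p in self.presence_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability for {impact} outside [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate outside [0, 1]")


def _random_seq(rng: np.random.Generator, lo: int = 120, hi: int = 400) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA), size=length))


def make_panel(
    n_positive: int = 40,
    n_negative: int = 12,
    n_required: int = 12,
    n_required_ogs: int = 12,
    n_domains_max: int = 3,
    seed: int = 0,
) -> Panel:
    """Generate a synthetic criteria panel.

    Positive and negative criteria sit in singleton groups; required
    criteria are spread over ``n_required_ogs`` groups, extra members joining
    existing groups round-robin as backup enzymes. Each criterion gets a
    random protein sequence (length 120-400) and 0 to ``n_domains_max``
    synthetic domain accessions in the reserved SYND namespace.
    """
    if n_required < n_required_ogs:
        raise ValueError(
            f"cannot spread {n_required} required criteria over {n_required_ogs} groups"
        )
    if n_required_ogs < 1:
        raise ValueError("need at least one required orthologous group")
    rng = np.random.default_rng(seed)

    criteria: list[PanelCriterion] = []
    sequences: dict[str, str] = {}
    domain_counter = 0

    def next_domains() -> tuple[str, ...]:
        nonlocal domain_counter
        k = int(rng.integers(0, n_domains_max + 1))
        accs = tuple(f"SYND{domain_counter + i + 1:05d}" for i in range(k))
        domain_counter += k
        return accs

    def add(cid: str, impact: Impact, og_id: str, hint: ActionHint) -> None:
        ko = f"K{int(rng.integers(0, 100000)):05d}"
        ec = ".".join(str(int(rng.integers(1, 8))) for _ in range(4))
        criteria.append(
            PanelCriterion(
                criterion_id=cid,
                gene_symbol=f"gene{len(criteria) + 1:03d}",
                kegg_ko=ko,
                ec_number=ec,
                impact=impact,
                og_id=og_id,
                domain_accessions=next_domains(),
                action_hint=hint,
            )
        )
        sequences[cid] = _random_seq(rng)

    for i in range(n_positive):
        hint = ActionHint.INSERTION if rng.random() < 0.5 else ActionHint.OVEREXPRESSION
        add(f"POS{i + 1:03d}", Impact.POSITIVE, f"OG_P{i + 1:03d}", hint)
    for i in range(n_negative):
        hint = ActionHint.DELETION if rng.random() < 0.5 else ActionHint.UNDEREXPRESSION
        add(f"NEG{i + 1:03d}", Impact.NEGATIVE, f"OG_N{i + 1:03d}", hint)
    for i in range(n_required):
        og = f"OG_R{(i % n_required_ogs) + 1:02d}"  # extras become backups
        add(f"REQ{i + 1:03d}", Impact.REQUIRED, og, ActionHint.PRESENT_REQUIRED)

    return Panel.from_criteria(criteria, sequences)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    chars = list(seq)
    n_mut = 0
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [a for a in AA if a != chars[i]]
            chars[i] = choices[int(rng.integers(0, len(choices)))]
            n_mut += 1
    return "".join(chars), n_mut


def _kmers(seq: str, k: int = 6) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _make_decoy(panel_kmers: set[str], rng: np.random.Generator) -> str:
    """Random protein guaranteed nearly 6-mer-disjoint from all panel sequences."""
    while True:
        seq = _random_seq(rng)
        if len(_kmers(seq) & panel_kmers) < 2:
            return seq


@dataclass(frozen=True)
class ProteomeBundle:
    """One strain's generated files plus its ground truth."""

    strain_id: str
    fasta: str
    blast_tab: str
    domtbl: str
    truth: StrainProfile
    present: frozenset[str]


def _domtbl_row(
    domain_name: str,
    accession: str,
    protein_id: str,
    qlen: int,
    i_evalue: float,
    env: tuple[int, int],
) -> str:
    # hmmscan orientation: target = domain model, query = strain protein.
    cols = [
        domain_name, accession, "200", protein_id, "-", str(qlen),
        f"{i_evalue:.1e}", "150.0", "0.1", "1", "1",
        f"{i_evalue:.1e}", f"{i_evalue:.1e}", "148.0", "0.1",
        "1", "200", str(env[0]), str(env[1]), str(env[0]), str(env[1]),
        "0.95", "synthetic domain",
    ]
    return " ".join(cols)


def make_proteome(
    panel: Panel,
    present: Sequence[str] | frozenset[str],
    spec: CohortSpec,
    strain_id: str = "STRAIN",
    drop_domains: Mapping[str, str] | None = None,
) -> ProteomeBundle:
    """Generate one strain's proteome FASTA plus consistent evidence files.

    The proteome holds a mutated copy of every ``present`` panel sequence and
    ``spec.decoys_per_strain`` decoys. The BLAST table records one hit per
    present criterion onto its copy (e-value well below any sane threshold);
    the domtblout annotates every domain of the criterion on that copy —
    except accessions listed in ``drop_domains`` (criterion_id → accession),
    which are deliberately omitted so the domain-completeness filter can be
    exercised end to end. The truth profile marks exactly ``present``.
    """
    present = frozenset(present)
    unknown = present - set(panel.criterion_ids)
    if unknown:
        raise ValueError(f"present names unknown criteria: {sorted(unknown)}")
    drop_domains = dict(drop_domains or {})
    rng = np.random.default_rng((spec.seed, zlib.crc32(strain_id.encode())))

    fasta_parts: list[str] = []
    hits: list[HomologyHit] = []
    dom_rows: list[str] = [
        "# synthetic per-domain annotation (hmmscan orientation)",
        "#",
    ]

    k = 0
    for crit in panel.criteria:  # panel order keeps output deterministic
        if crit.criterion_id not in present:
            continue
        k += 1
        pid = f"{strain_id}_p{k:04d}"
        ref = panel.sequences[crit.criterion_id]
        seq, n_mut = _mutate(ref, spec.mutation_rate, rng)
        fasta_parts.append(f">{pid} homolog of {crit.criterion_id}\n{seq}\n")
        length = len(seq)
        hits.append(
            HomologyHit(
                query_id=crit.criterion_id,
                subject_id=pid,
                pct_identity=round(100.0 * (length - n_mut) / length, 2),
                align_length=length,
                mismatches=n_mut,
                gap_opens=0,
                q_start=1,
                q_end=length,
                s_start=1,
                s_end=length,
                e_value=1e-80,
                bit_score=round(2.0 * length, 1),
            )
        )
        if crit.domain_accessions:
            segs = domain_segments(length, len(crit.domain_accessions))
            for acc, env in zip(crit.domain_accessions, segs):
                if drop_domains.get(crit.criterion_id) == acc:
                    continue
                dom_rows.append(
                    _domtbl_row(acc.lower(), f"{acc}.1", pid, length, 1e-12, env)
                )

    panel_kmers: set[str] = set()
    for s in panel.sequences.values():
        panel_kmers |= _kmers(s)
    for d in range(spec.decoys_per_strain):
        pid = f"{strain_id}_d{d + 1:04d}"
        seq = _make_decoy(panel_kmers, rng)
        fasta_parts.append(f">{pid} decoy\n{seq}\n")
        # decoy self-noise: an annotation in a namespace no criterion uses
        dom_rows.append(
            _domtbl_row(f"noise{d + 1}", f"SYNDX{d + 1:04d}.1", pid, len(seq), 1e-8, (1, len(seq)))
        )

    dom_rows.append("#")
    truth = StrainProfile.from_presence(strain_id, present, panel)
    return ProteomeBundle(
        strain_id=strain_id,
        fasta="".join(fasta_parts),
        blast_tab=write_blast_tabular(hits),
        domtbl="\n".join(dom_rows) + "\n",
        truth=truth,
        present=present,
    )


def sample_true_weights(panel: Panel, seed: int = 0) -> WeightVector:
    """Ground-truth weights: impact-signed magnitudes drawn U(0.5, 1.5)."""
    rng = np.random.default_rng(seed)
    w = {}
    for c in panel.criteria:
        mag = float(rng.uniform(0.5, 1.5))
        w[c.criterion_id] = -mag if c.impact is Impact.NEGATIVE else mag
    return WeightVector(w)


def _sample_presence(
    panel: Panel, probs: Mapping[Impact, float], rng: np.random.Generator
) -> frozenset[str]:
    return frozenset(
        c.criterion_id for c in panel.criteria if rng.random() < probs[c.impact]
    )


def _strain_ids(n: int, inject_references: bool) -> list[str]:
    if not inject_references:
        return [f"STR{i + 1:03d}" for i in range(n)]
    refs = list(REFERENCE_PRESENCE)
    if n <= len(refs):
        return refs[:n]
    return refs + [f"STR{i + 1:03d}" for i in range(n - len(refs))]


@dataclass
class ProfileCohort:
    """Profile-level cohort: truth profiles, references, optional truth ranking."""

    profiles: list[StrainProfile]
    refs: ReferenceConfig | None
    truth_ranking: list[tuple[str, int]] | None = None
    presence: dict[str, frozenset[str]] = field(default_factory=dict)


def make_profile_cohort(
    panel: Panel,
    spec: CohortSpec,
    true_weights: WeightVector | None = None,
    inject_references: bool = True,
) -> ProfileCohort:
    """Sample presence vectors only (no sequences/evidence) — fast path for
    scoring and calibration studies.

    By default the first strains are the injected references (strong
    producers, a boundary strain, a poor producer) with their own presence
    probabilities; the rest draw presence per impact class from
    ``spec.presence_probability``. With ``true_weights`` given, the
    ground-truth cohort ranking under those weights is attached.
    """
    rng = np.random.default_rng(spec.seed)
    profiles: list[StrainProfile] = []
    presence: dict[str, frozenset[str]] = {}
    for sid in _strain_ids(spec.n_strains, inject_references):
        probs = (
            REFERENCE_PRESENCE.get(sid, spec.presence_probability)
            if inject_references
            else spec.presence_probability
        )
        pres = _sample_presence(panel, probs, rng)
        presence[sid] = pres
        profiles.append(StrainProfile.from_presence(sid, pres, panel))

    truth_ranking = None
    if true_weights is not None:
        raw = {p.strain_id: score_raw(p, true_weights) for p in profiles}
        truth_ranking = rank_cohort(normalize_scores(raw))
    refs = SYNTHETIC_REFS if inject_references else None
    return ProfileCohort(profiles, refs, truth_ranking, presence)


@dataclass
class Cohort:
    """Full cohort: per-strain file bundles plus ground truth."""

    bundles: list[ProteomeBundle]
    refs: ReferenceConfig
    truth_ranking: list[tuple[str, int]] | None = None

    @property
    def truth_profiles(self) -> list[StrainProfile]:
        return [b.truth for b in self.bundles]


def make_cohort(
    panel: Panel, spec: CohortSpec, true_weights: WeightVector | None = None
) -> Cohort:
    """Generate a full cohort of proteome + evidence bundles.

    Presence is sampled exactly as in :func:`make_profile_cohort` (same seed
    → same presence), then each strain's files are emitted by
    :func:`make_proteome`.
    """
    pc = make_profile_cohort(panel, spec, true_weights)
    bundles = [
        make_proteome(panel, pc.presence[p.strain_id], spec, p.strain_id)
        for p in pc.profiles
    ]
    return Cohort(bundles, pc.refs, pc.truth_ranking)


def write_bundle(panel: Panel, cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort to disk in the layout the CLI consumes.

    ``panel.tsv`` + ``panel.fasta`` at the top level; per strain
    ``strains/<id>.fasta``, ``strains/<id>.blast.tsv``,
    ``strains/<id>.domtbl``; ground truth in ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "strains").mkdir(parents=True, exist_ok=True)
    write_panel(panel, outdir / "panel.tsv", outdir / "panel.fasta")
    for b in cohort.bundles:
        (outdir / "strains" / f"{b.strain_id}.fasta").write_text(b.fasta)
        (outdir / "strains" / f"{b.strain_id}.blast.tsv").write_text(b.blast_tab)
        (outdir / "strains" / f"{b.strain_id}.domtbl").write_text(b.domtbl)
    truth = {
        "present": {b.strain_id: sorted(b.present) for b in cohort.bundles},
        "references": {
            "positive_refs": list(cohort.refs.positive_refs),
            "negative_refs": list(cohort.refs.negative_refs),
            "upper_boundary": cohort.refs.upper_boundary,
            "lower_boundary": cohort.refs.lower_boundary,
        },
        "truth_ranking": cohort.truth_ranking,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
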