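"""Homology and domain evidence: parsers, fallback aligner, domain filter.

The screening method accepts presence evidence from two standard text
formats — BLAST tabular (``-outfmt 6``, 12 columns) and HMMER per-domain
tabular output (``domtblout``) — and applies a stringent completeness rule:
a homology hit counts only if the subject protein carries *every* domain of
the query panel protein. A dependency-free Smith–Waterman aligner plus a
segment-based domain annotator let the whole pipeline run on synthetic
fixtures without external search binaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, EvidenceFormatError
from .panel import Panel

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MAX_IEVALUE = 1e-5

_VERSION_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST-style local alignment between a panel query and a strain
    protein. Coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on a strain protein (accession version stripped)."""

    protein_id: str
    domain_accession: str
    i_evalue: float
    env_from: int
    env_to: int


def _lines(stream: Iterable[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def parse_blast_tabular(stream: Iterable[str] | str) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``).

    Blank lines and ``#`` comments are ignored. A line with the wrong column
    count or an unparsable numeric field raises a format error naming the
    line.
    """
    hits: list[HomologyHit] = []
    for n, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise EvidenceFormatError(
                f"expected 12 tab-separated columns, found {len(fields)}", n
            )
        try:
            hit = HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                pct_identity=float(fields[2]),
                align_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
            )
        except ValueError as exc:
            raise EvidenceFormatError(f"unparsable numeric field ({exc})", n) from None
        if hit.q_start > hit.q_end or hit.s_start > hit.s_end or hit.e_value < 0:
            raise EvidenceFormatError("coordinate/e-value invariant violated", n)
        hits.append(hit)
    return hits


def write_blast_tabular(hits: Iterable[HomologyHit]) -> str:
    """Render hits back to 12-column tabular text (round-trips with the parser)."""
    out = []
    for h in hits:
        out.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.pct_identity:.2f}",
                    str(h.align_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.e_value:.2e}" if h.e_value != 0 else "0.0",
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    return "\n".join(out) + ("\n" if out else "")


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix from a domain accession."""
    return _VERSION_SUFFIX.sub("", accession)


def parse_domtblout(stream: Iterable[str] | str) -> list[DomainAnnotation]:
    """Parse HMMER per-domain tabular output (``--domtblout``).

    Rows are read in hmmscan orientation: the query is the strain protein,
    the target is the domain model. The target accession (version stripped)
    becomes the annotation's domain accession; when HMMER prints ``-`` for
    the accession the target name is used instead.
    """
    annots: list[DomainAnnotation] = []
    for n, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 22:
            raise EvidenceFormatError(
                f"expected >= 22 whitespace-separated columns, found {len(fields)}", n
            )
        acc = fields[1] if fields[1] != "-" else fields[0]
        try:
            annot = DomainAnnotation(
                protein_id=fields[3],
                domain_accession=strip_version(acc),
                i_evalue=float(fields[12]),
                env_from=int(fields[19]),
                env_to=int(fields[20]),
            )
        except ValueError as exc:
            raise EvidenceFormatError(f"unparsable numeric field ({exc})", n) from None
        if annot.env_from > annot.env_to or annot.i_evalue < 0:
            raise EvidenceFormatError("envelope/i-evalue invariant violated", n)
        annots.append(annot)
    return annots


def domain_sets(
    annotations: Iterable[DomainAnnotation], max_ievalue: float = DEFAULT_MAX_IEVALUE
) -> dict[str, frozenset[str]]:
    """Collapse domain annotations passing the i-Evalue cut into per-protein
    accession sets."""
    acc: dict[str, set[str]] = {}
    for a in annotations:
        if a.i_evalue <= max_ievalue:
            acc.setdefault(a.protein_id, set()).add(a.domain_accession)
    return {pid: frozenset(s) for pid, s in acc.items()}


def filter_domain_complete(
    hits: Sequence[HomologyHit],
    query_domains: Mapping[str, frozenset[str] | set[str]],
    subject_domains: Mapping[str, frozenset[str] | set[str]] | Iterable[DomainAnnotation],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    max_ievalue: float = DEFAULT_MAX_IEVALUE,
) -> list[HomologyHit]:
    """Keep only domain-complete hits.

    A hit is retained iff its e-value is at or below ``max_evalue`` and the
    subject protein carries every domain of the query criterion (set
    inclusion on accessions; order and copy number are ignored). Criteria
    with no recorded domains pass the domain test vacuously.

    ``subject_domains`` may be a prebuilt protein→accession-set mapping or a
    raw iterable of :class:`DomainAnnotation` (then ``max_ievalue`` is
    applied here). Output preserves input order; the operation is idempotent.
    """
    if not isinstance(subject_domains, Mapping):
        subject_domains = domain_sets(subject_domains, max_ievalue)

    kept: list[HomologyHit] = []
    for h in hits:
        if h.query_id not in query_domains:
            raise ConfigurationError(
                f"hit query {h.query_id!r} has no domain definition in the panel"
            )
        if h.e_value > max_evalue:
            continue
        need = query_domains[h.query_id]
        if need and not set(need) <= set(subject_domains.get(h.subject_id, frozenset())):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Fallback aligner (Smith–Waterman, linear gap) and internal search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment: score plus 1-based inclusive spans.

    ``q_span``/``s_span`` are ``None`` when no positive-scoring alignment
    exists (including empty inputs). ``matches`` and ``columns`` describe the
    traced-back alignment and give percent identity for hit records.
    """

    score: float
    q_span: tuple[int, int] | None
    s_span: tuple[int, int] | None
    matches: int = 0
    columns: int = 0


def align_local(
    query: str,
    subject: str,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
) -> LocalAlignment:
    """Smith–Waterman local alignment with linear gap penalty.

    Returns the maximal local score and one optimal span pair. Among cells
    attaining the maximum, the one with the smallest ``(q_end, s_end)`` is
    chosen; the traceback prefers diagonal over up over left, so the result
    is fully deterministic.
    """
    if not query or not subject:
        return LocalAlignment(0, None, None)
    q = np.frombuffer(query.upper().encode("ascii"), dtype=np.uint8)
    s = np.frombuffer(subject.upper().encode("ascii"), dtype=np.uint8)
    n, m = len(q), len(s)

    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    jdx = np.arange(1, m + 1, dtype=np.float64)
    gap_j = gap * jdx
    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        sub = np.where(s == q[i - 1], float(match), float(mismatch))
        t = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        np.maximum(t, 0.0, out=t)
        # Linear-gap closure of H[i,j] = max(t[j], H[i,j-1] + gap):
        # H[i,j] = gap*j + running-max of (t[k] - gap*k) over k <= j.
        row = np.maximum.accumulate(t - gap_j) + gap_j
        H[i, 1:] = row
        j_best = int(np.argmax(row))  # first occurrence -> smallest s_end
        if row[j_best] > best:
            best, best_i, best_j = float(row[j_best]), i, j_best + 1

    if best <= 0:
        return LocalAlignment(0, None, None)

    i, j = best_i, best_j
    matches = columns = 0
    while H[i, j] > 0:
        diag = H[i - 1, j - 1] + (match if q[i - 1] == s[j - 1] else mismatch)
        if i > 0 and j > 0 and H[i, j] == diag:
            matches += int(q[i - 1] == s[j - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    score = int(best) if float(best).is_integer() else best
    return LocalAlignment(score, (i + 1, best_i), (j + 1, best_j), matches, columns)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def domain_segments(length: int, n_domains: int) -> list[tuple[int, int]]:
    """Partition ``1..length`` into ``n_domains`` contiguous 1-based segments.

    The generator places synthetic domain *d* of a criterion on segment *d*
    of its sequence; the fallback annotator assumes the same layout, so the
    two sides of the pipeline agree by construction.
    """
    bounds = np.linspace(0, length, n_domains + 1).astype(int)
    return [(int(a) + 1, int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def internal_search(
    panel: Panel,
    proteome: Mapping[str, str],
    *,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
    min_score_ratio: float = 0.5,
    kmer: int = 6,
    min_shared_kmers: int = 2,
) -> tuple[list[HomologyHit], dict[str, frozenset[str]]]:
    """Dependency-free substitute for an external homology + domain search.

    Candidate subjects are prefiltered by shared ``kmer``-mer count (a
    seed-and-extend heuristic), then verified by :func:`align_local`; a
    subject is a hit when its local score reaches ``min_score_ratio`` of the
    query's self-alignment score. For each hit, the query's domain segments
    (see :func:`domain_segments`) are aligned individually and annotated on
    the subject under the same rule. Emitted hits carry e-value 0, so they
    pass any downstream e-value threshold: the score ratio is the acceptance
    criterion here.
    """
    hits: list[HomologyHit] = []
    subject_domains: dict[str, set[str]] = {}
    subject_kmers = {pid: _kmer_set(seq.upper(), kmer) for pid, seq in proteome.items()}

    for crit in panel.criteria:
        qseq = panel.sequences.get(crit.criterion_id, "")
        if not qseq:
            continue
        qkmers = _kmer_set(qseq, kmer)
        self_score = len(qseq) * match
        for pid, sseq in proteome.items():
            if len(qkmers & subject_kmers[pid]) < min_shared_kmers:
                continue
            aln = align_local(qseq, sseq, match, mismatch, gap)
            if aln.score < min_score_ratio * self_score or aln.q_span is None:
                continue
            pident = 100.0 * aln.matches / aln.columns if aln.columns else 0.0
            hits.append(
                HomologyHit(
                    query_id=crit.criterion_id,
                    subject_id=pid,
                    pct_identity=round(pident, 2),
                    align_length=aln.columns,
                    mismatches=aln.columns - aln.matches,
                    gap_opens=0,
                    q_start=aln.q_span[0],
                    q_end=aln.q_span[1],
                    s_start=aln.s_span[0],
                    s_end=aln.s_span[1],
                    e_value=0.0,
                    bit_score=float(aln.score),
                )
            )
            if crit.domain_accessions:
                segs = domain_segments(len(qseq), len(crit.domain_accessions))
                found = subject_domains.setdefault(pid, set())
                for acc, (a, b) in zip(crit.domain_accessions, segs):
                    seg = qseq[a - 1 : b]
                    if not seg:
                        continue
                    seg_aln = align_local(seg, sseq, match, mismatch, gap)
                    if seg_aln.score >= min_score_ratio * len(seg) * match:
                        found.add(acc)
    return hits, {pid: frozenset(s) for pid, s in subject_domains.items()}
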