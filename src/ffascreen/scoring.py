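"""Strain scoring, cohort normalization, ranking and categorization.

Second phase of the evaluation. The raw score is a signed weighted sum of
per-criterion features (presence by default): positive- and required-impact
criteria carry positive weights, negative-impact criteria negative weights.
Scores are min-max normalized over the evaluated cohort, ranked, and each
strain is placed into one of three categories:

* ``Top-ranked`` — scores strictly above the positive upper-reference strain;
* ``Positive``   — at or below the upper reference but strictly above the
  lower boundary strain, which is the lowest-scoring member of the K-means
  (k=2) cluster that contains the positive reference strains;
* ``Negative``   — everything else.

Weight magnitudes can be calibrated so that every positive reference strain
outranks every negative reference strain (hinge-margin coordinate ascent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundaryUndefinedError, ConfigurationError
from .panel import Impact, Panel
from .profiling import StrainProfile


class Category(str, Enum):
    TOP_RANKED = "Top-ranked"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion weights; sign encodes impact (negative impact < 0)."""

    weights: Mapping[str, float]

    def __getitem__(self, criterion_id: str) -> float:
        return self.weights[criterion_id]


def unit_weights(panel: Panel) -> WeightVector:
    """Default weights: +1 for positive/required criteria, -1 for negative."""
    return WeightVector(
        {
            c.criterion_id: (-1.0 if c.impact is Impact.NEGATIVE else 1.0)
            for c in panel.criteria
        }
    )


def validate_weights(weights: WeightVector, panel: Panel) -> None:
    """Check coverage and the sign constraint; raise on violation."""
    for c in panel.criteria:
        if c.criterion_id not in weights.weights:
            raise ConfigurationError(f"no weight for criterion {c.criterion_id}")
        w = weights[c.criterion_id]
        if c.impact is Impact.NEGATIVE and not w < 0:
            raise ConfigurationError(
                f"criterion {c.criterion_id} (negative impact) must have weight < 0"
            )
        if c.impact is not Impact.NEGATIVE and not w > 0:
            raise ConfigurationError(
                f"criterion {c.criterion_id} ({c.impact.value} impact) must have weight > 0"
            )


@dataclass(frozen=True)
class ScoreRecord:
    """One strain's cohort result row."""

    strain_id: str
    raw_score: float
    normalized_score: float
    rank: int
    category: Category | None = None


@dataclass(frozen=True)
class ReferenceConfig:
    """Reference strains anchoring the score scale and category boundaries.

    Defaults name the experimentally characterised cyanobacterial FFA
    producers (positive) and poor producers (negative); synthetic cohorts
    supply their own injected reference ids.
    """

    positive_refs: tuple[str, ...] = (
        "Synechococcus sp. PCC 7002",
        "Synechocystis sp. PCC 6803",
        "Synechococcus elongatus PCC 7942",
    )
    negative_refs: tuple[str, ...] = (
        "Arthrospira platensis NIES-39",
        "Lyngbya sp. PCC 8106",
    )
    upper_boundary: str = "Synechococcus sp. PCC 7002"
    lower_boundary: str = "Pseudanabaena sp. PCC 7367"

    def __post_init__(self):
        if not self.positive_refs or not self.negative_refs:
            raise ConfigurationError("reference lists must be non-empty")
        overlap = set(self.positive_refs) & set(self.negative_refs)
        if overlap:
            raise ConfigurationError(
                f"strains cannot be both positive and negative references: {sorted(overlap)}"
            )


def score_raw(
    profile: StrainProfile,
    weights: WeightVector,
    feature_mode: str = "presence",
) -> float:
    """Signed weighted sum of the strain's features.

    ``feature_mode`` selects binary presence (default) or hit counts as the
    per-criterion feature.
    """
    if feature_mode not in ("presence", "count"):
        raise ConfigurationError(f"unknown feature_mode {feature_mode!r}")
    total = 0.0
    for cid, count in profile.hit_counts.items():
        try:
            w = weights[cid]
        except KeyError:
            raise ConfigurationError(f"no weight for criterion {cid}") from None
        x = float(count) if feature_mode == "count" else float(count > 0)
        total += w * x
    return total


def normalize_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize raw scores to [0, 1] over the cohort.

    The cohort maximum maps to 1 and the minimum to 0; a degenerate cohort
    (all scores equal) maps every strain to 0.5.
    """
    if not raw:
        raise ConfigurationError("cannot normalize an empty cohort")
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {sid: 0.5 for sid in raw}
    return {sid: (x - lo) / (hi - lo) for sid, x in raw.items()}


def rank_cohort(normalized: Mapping[str, float]) -> list[tuple[str, int]]:
    """Rank strains 1..N by descending score, ties broken by ascending id."""
    ordered = sorted(normalized.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(sid, i + 1) for i, (sid, _) in enumerate(ordered)]


def kmeans_split_1d(values: Sequence[float]) -> int:
    """Exact 1-D 2-means: index k splitting sorted values into [:k] / [k:].

    The 2-means optimum on a line is a contiguous split of the sorted
    values, so scanning the N-1 splits for minimal within-cluster SSE gives
    the global K-means solution deterministically (ties resolve to the
    smallest k). Lloyd-style iteration from heuristic centers can stall in a
    local optimum; this cannot.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = len(v)
    if n < 2:
        raise ConfigurationError("need at least 2 values to split")
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    k = np.arange(1, n)
    sse_low = csq[k - 1] - csum[k - 1] ** 2 / k
    sse_high = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
    return int(k[np.argmin(sse_low + sse_high)])


def find_boundary(
    normalized: Mapping[str, float],
    positive_refs: Sequence[str],
    seed: int = 0,
) -> str:
    """Locate the lower category boundary strain by K-means (k=2) on scores.

    Splits the cohort's 1-D scores into two clusters at the exact 2-means
    optimum (see :func:`kmeans_split_1d`) and returns the lowest-scoring
    strain of the cluster holding *all* positive reference strains.
    References split across clusters leave the boundary undefined. ``seed``
    is accepted for API stability; the solution is exact and deterministic.
    """
    del seed
    if len(normalized) < 2:
        raise ConfigurationError("boundary detection needs at least 2 strains")
    missing = [r for r in positive_refs if r not in normalized]
    if missing:
        raise ConfigurationError(f"positive reference(s) not in cohort: {missing}")

    sids = sorted(normalized, key=lambda s: (normalized[s], s))
    if normalized[sids[0]] == normalized[sids[-1]]:
        # indistinguishable scores: a single cluster containing everyone
        return sids[0]
    k = kmeans_split_1d([normalized[s] for s in sids])
    low, high = set(sids[:k]), set(sids[k:])
    if all(r in high for r in positive_refs):
        cluster = sids[k:]
    elif all(r in low for r in positive_refs):
        cluster = sids[:k]
    else:
        raise BoundaryUndefinedError(
            "positive reference strains were split across the two score clusters"
        )
    return cluster[0]


def categorize(score: float, upper_score: float, lower_score: float) -> Category:
    """Assign the category for one score against the two boundary scores.

    "Higher than" is strict: a score equal to the upper boundary is
    Positive; equal to the lower boundary is Negative.
    """
    if lower_score > upper_score:
        raise ConfigurationError(
            f"lower boundary score {lower_score} exceeds upper {upper_score}"
        )
    if score > upper_score:
        return Category.TOP_RANKED
    if score > lower_score:
        return Category.POSITIVE
    return Category.NEGATIVE


def score_cohort(
    profiles: Sequence[StrainProfile],
    weights: WeightVector,
    refs: ReferenceConfig,
    feature_mode: str = "presence",
    detect_boundary: bool = True,
    seed: int = 0,
) -> list[ScoreRecord]:
    """Score, normalize, rank and categorize a whole cohort.

    The upper category boundary is the upper-reference strain's normalized
    score; the lower boundary comes from :func:`find_boundary` (or, with
    ``detect_boundary=False``, from the configured lower-boundary strain).
    Returns records in rank order.
    """
    raw = {p.strain_id: score_raw(p, weights, feature_mode) for p in profiles}
    if len(raw) != len(profiles):
        raise ConfigurationError("duplicate strain_id in cohort")
    norm = normalize_scores(raw)
    ranks = rank_cohort(norm)

    if refs.upper_boundary not in norm:
        raise ConfigurationError(
            f"upper boundary strain {refs.upper_boundary!r} not in cohort"
        )
    upper = norm[refs.upper_boundary]
    if detect_boundary:
        boundary_sid = find_boundary(norm, refs.positive_refs, seed)
    else:
        if refs.lower_boundary not in norm:
            raise ConfigurationError(
                f"lower boundary strain {refs.lower_boundary!r} not in cohort"
            )
        boundary_sid = refs.lower_boundary
    lower = min(norm[boundary_sid], upper)

    return [
        ScoreRecord(sid, raw[sid], norm[sid], rank, categorize(norm[sid], upper, lower))
        for sid, rank in ranks
    ]


def records_table(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Cohort results as a ranking-table DataFrame."""
    return pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "raw_score": r.raw_score,
                "normalized_score": r.normalized_score,
                "rank": r.rank,
                "category": r.category.value if r.category else "",
            }
            for r in records
        ],
        columns=["strain_id", "raw_score", "normalized_score", "rank", "category"],
    )


# ---------------------------------------------------------------------------
# Weight calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    weights: WeightVector
    margin: float  # worst positive-vs-negative raw margin, L2-normalized
    separable: bool


_FACTORS = (2.0, 1.25, 0.8, 0.5)
_MIN_MAG, _MAX_MAG = 0.25, 4.0


def calibrate_weights(
    profiles: Sequence[StrainProfile],
    panel: Panel,
    refs: ReferenceConfig,
    feature_mode: str = "presence",
    seed: int = 0,
    max_iter: int = 30,
) -> CalibrationResult:
    """Calibrate weight magnitudes against the reference strains.

    Maximizes the worst pairwise margin ``min over (p, n) of (raw_p - raw_n)``
    between positive and negative reference strains, normalized by the weight
    vector's L2 norm so the objective is scale-free. Deterministic coordinate
    ascent over per-criterion magnitudes starts from unit weights and keeps
    magnitudes within [0.25, 4], so calibrated weights stay anchored to the
    unit-magnitude prior rather than being dictated entirely by the handful
    of reference strains. ``seed`` is accepted for API stability; the
    procedure is deterministic.

    A final normalized margin <= 0 flags the references as non-separable
    under any sign-constrained reweighting found.
    """
    del seed
    by_id = {p.strain_id: p for p in profiles}
    for r in (*refs.positive_refs, *refs.negative_refs):
        if r not in by_id:
            raise ConfigurationError(f"reference strain {r!r} missing from cohort")

    cids = panel.criterion_ids
    signs = np.array(
        [-1.0 if panel.criterion(c).impact is Impact.NEGATIVE else 1.0 for c in cids]
    )

    def features(p: StrainProfile) -> np.ndarray:
        if feature_mode == "count":
            return np.array([float(p.hit_counts[c]) for c in cids])
        return np.array([float(p.presence[c]) for c in cids])

    pos = np.stack([features(by_id[r]) for r in refs.positive_refs])
    neg = np.stack([features(by_id[r]) for r in refs.negative_refs])
    # All pairwise positive-minus-negative feature differences.
    diffs = (pos[:, None, :] - neg[None, :, :]).reshape(-1, len(cids))

    def objective(mags: np.ndarray) -> float:
        w = signs * mags
        return float((diffs @ w).min() / np.linalg.norm(w))

    mags = np.ones(len(cids))
    current = objective(mags)
    for _ in range(max_iter):
        improved = False
        for i in range(len(cids)):
            best_trial, best_val = None, current
            for f in _FACTORS:
                m = float(np.clip(mags[i] * f, _MIN_MAG, _MAX_MAG))
                if m == mags[i]:
                    continue
                trial = mags.copy()
                trial[i] = m
                val = objective(trial)
                if val > best_val + 1e-12:
                    best_trial, best_val = trial, val
            if best_trial is not None:
                mags, current = best_trial, best_val
                improved = True
        if not improved:
            break

    weights = WeightVector({c: float(s * m) for c, s, m in zip(cids, signs, mags)})
    return CalibrationResult(weights, current, separable=current > 0)


def write_weights(weights: WeightVector, path) -> None:
    pd.DataFrame(
        sorted(weights.weights.items()), columns=["criterion_id", "weight"]
    ).to_csv(path, sep="\t", index=False)


def load_weights(path) -> WeightVector:
    df = pd.read_csv(path, sep="\t", dtype={"criterion_id": str, "weight": float})
    if list(df.columns) != ["criterion_id", "weight"]:
        raise ConfigurationError(
            f"weights file {path}: expected columns criterion_id, weight"
        )
    return WeightVector(dict(zip(df["criterion_id"], df["weight"])))


# ---------------------------------------------------------------------------
# New-strain evaluation against a stored cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainEvaluation:
    """Result of evaluating a new strain against a pre-evaluated cohort.

    Exposes the four user-facing outputs — score, category, recommendations
    and rank — plus the full renormalized cohort ranking including the new
    strain. Stored cohort data is never mutated; the updated ranking is a
    view recomputed over cohort ∪ {new}.
    """

    record: ScoreRecord
    recommendations: list = field(default_factory=list)
    ranking: list[ScoreRecord] = field(default_factory=list)

    @property
    def score(self) -> float:
        return self.record.normalized_score

    @property
    def category(self) -> Category | None:
        return self.record.category

    @property
    def rank(self) -> int:
        return self.record.rank


def evaluate_new_strain(
    new_profile: StrainProfile,
    cohort_raws: Mapping[str, float],
    weights: WeightVector,
    refs: ReferenceConfig,
    panel: Panel | None = None,
    feature_mode: str = "presence",
) -> StrainEvaluation:
    """Score a new strain and place it within a pre-evaluated cohort.

    The new raw score joins the stored cohort raw scores; normalization and
    ranks are recomputed over the union, and the category is assigned against
    the renormalized scores of the configured upper and lower boundary
    strains. When a panel is given, engineering recommendations are attached.
    """
    if not cohort_raws:
        raise ConfigurationError("cohort is empty")
    if new_profile.strain_id in cohort_raws:
        raise ConfigurationError(
            f"strain_id {new_profile.strain_id!r} already exists in the cohort"
        )
    for b in (refs.upper_boundary, refs.lower_boundary):
        if b not in cohort_raws:
            raise ConfigurationError(f"boundary strain {b!r} not in cohort")

    raw = dict(cohort_raws)
    raw[new_profile.strain_id] = score_raw(new_profile, weights, feature_mode)
    norm = normalize_scores(raw)
    ranks = rank_cohort(norm)
    upper = norm[refs.upper_boundary]
    lower = min(norm[refs.lower_boundary], upper)

    ranking = [
        ScoreRecord(sid, raw[sid], norm[sid], rank, categorize(norm[sid], upper, lower))
        for sid, rank in ranks
    ]
    record = next(r for r in ranking if r.strain_id == new_profile.strain_id)

    recommendations = []
    if panel is not None:
        from .recommend import suggest_modifications

        recommendations = suggest_modifications(new_profile, panel)
    return StrainEvaluation(record, recommendations, ranking)
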