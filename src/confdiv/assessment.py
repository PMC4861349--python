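"""Dual-reference decoy assessment.

Filters decoy populations against the target numbering, ranks decoys
against both members of the maximally distant conformer pair under each
similarity measure, correlates the two rankings, selects best decoys,
cross-compares them, and classifies each target as resolving one or two
members of the native ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import ConformerPair
from .metrics import (
    SimilarityScores,
    default_significance,
    rmsd_aligned,
    score_pair,
)
from .structure_io import (
    CalphaStructure,
    DisjointNumberingError,
    coverage as coverage_of,
)

__all__ = [
    "METRICS",
    "DecoyRecord",
    "Ranking",
    "TargetAssessment",
    "filter_decoys",
    "significance_gate",
    "rank_decoys",
    "spearman_rho",
    "assess_target",
    "cohort_report",
    "SAME_BEST",
    "DIFFERENT_BEST",
]

METRICS = ("RMSD", "GDT_TS", "TM")
SAME_BEST = "SAME_BEST"
DIFFERENT_BEST = "DIFFERENT_BEST"

#: Inclusive filter bounds: a decoy passes with coverage >= 0.80 and a
#: longest missing run <= 5 consecutive reference residues.
MIN_COVERAGE = 0.8
MAX_CONSECUTIVE_MISSING = 5

# score direction: +1 ranks ascending (smaller is better), -1 descending
_DIRECTION = {"RMSD": 1.0, "GDT_TS": -1.0, "TM": -1.0}
_SCORE_ATTR = {"RMSD": "rmsd", "GDT_TS": "gdt_ts", "TM": "tm_score"}


@dataclass
class DecoyRecord:
    """One decoy with filter state and per-conformer similarity scores."""

    decoy_id: str
    structure: CalphaStructure
    group_label: str = ""
    passed_filters: Optional[bool] = None
    filter_coverage: Optional[float] = None
    max_consecutive_missing: Optional[int] = None
    scores_a: Optional[SimilarityScores] = None
    scores_b: Optional[SimilarityScores] = None
    true_source: Optional[str] = None  # ground-truth label for synthetic decoys


def filter_decoys(
    decoys: Sequence[DecoyRecord],
    reference: CalphaStructure,
    min_coverage: float = MIN_COVERAGE,
    max_missing: int = MAX_CONSECUTIVE_MISSING,
) -> tuple[list[DecoyRecord], list[DecoyRecord]]:
    """Partition decoys into (passed, rejected) against the target numbering.

    A decoy is rejected when its coverage of the reference is below
    ``min_coverage`` or it is missing more than ``max_missing`` consecutive
    reference residues; both bounds are inclusive on the passing side.
    Decoys whose numbering is disjoint from the reference fail the filters.
    """
    passed: list[DecoyRecord] = []
    rejected: list[DecoyRecord] = []
    for rec in decoys:
        try:
            cov, max_run = coverage_of(rec.structure, reference)
        except DisjointNumberingError:
            rec.passed_filters = False
            rec.filter_coverage = 0.0
            rec.max_consecutive_missing = len(reference)
            rejected.append(rec)
            continue
        rec.filter_coverage = cov
        rec.max_consecutive_missing = max_run
        rec.passed_filters = cov >= min_coverage and max_run <= max_missing
        (passed if rec.passed_filters else rejected).append(rec)
    return passed, rejected


def significance_gate(
    scores: SimilarityScores,
    predicate: Callable[[SimilarityScores], bool] = default_significance,
) -> bool:
    """Evaluate and record the alignment-significance predicate."""
    return bool(predicate(scores))


@dataclass(frozen=True)
class Ranking:
    """Ordered decoy ranking under one metric against one conformer."""

    metric: str
    scores: Mapping[str, float]  # decoy_id -> raw score
    ranks: Mapping[str, float]  # decoy_id -> average rank (1 = best)

    @property
    def ordered_ids(self) -> list[str]:
        return sorted(self.ranks, key=lambda i: (self.ranks[i], i))

    @property
    def best_id(self) -> str:
        return self.ordered_ids[0]


def rank_decoys(
    decoys: Sequence[DecoyRecord],
    conformer: str,
    metric: str,
    significant_only: Optional[bool] = None,
) -> Ranking:
    """Rank passed decoys against one conformer ('a' or 'b') under a metric.

    RMSD ranks ascending; GDT_TS and TM descending.  Exact score ties get
    average ranks.  By default RMSD-based rankings keep only comparisons
    passing the significance gate (mirroring an alignment-significance
    cutoff); set ``significant_only`` to override.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if conformer not in ("a", "b"):
        raise ValueError("conformer must be 'a' or 'b'")
    if significant_only is None:
        significant_only = metric == "RMSD"
    attr = _SCORE_ATTR[metric]
    ids: list[str] = []
    values: list[float] = []
    for rec in decoys:
        scores = rec.scores_a if conformer == "a" else rec.scores_b
        if scores is None or getattr(scores, attr) is None:
            continue
        if significant_only and not scores.significant:
            continue
        ids.append(rec.decoy_id)
        values.append(float(getattr(scores, attr)))
    if not ids:
        raise ValueError(f"no scored decoys to rank for metric {metric}")
    order = np.argsort(ids)  # deterministic under permutation of input
    ids = [ids[i] for i in order]
    values = [values[i] for i in order]
    ranks = rankdata(_DIRECTION[metric] * np.asarray(values), method="average")
    return Ranking(
        metric=metric,
        scores=dict(zip(ids, values)),
        ranks=dict(zip(ids, ranks.tolist())),
    )


def spearman_rho(ranking_a: Ranking, ranking_b: Ranking) -> Optional[float]:
    """Spearman rank correlation between two rankings of the same decoys.

    Computed as the Pearson correlation of the average-rank vectors over the
    intersection of decoy ids (tie-robust form); ranks are recomputed on the
    intersection.  Returns None with fewer than 3 shared decoys or when a
    rank vector is constant.
    """
    shared = sorted(set(ranking_a.ranks) & set(ranking_b.ranks))
    if len(shared) < 3:
        return None
    ra = rankdata([ranking_a.ranks[i] for i in shared], method="average")
    rb = rankdata([ranking_b.ranks[i] for i in shared], method="average")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        return None
    return float(np.corrcoef(ra, rb)[0, 1])


@dataclass
class TargetAssessment:
    """Full dual-reference assessment outcome for one target."""

    target_id: str
    n_decoys_total: int
    n_decoys_passed: int
    n_significant_comparisons: int
    high_quality: bool
    spearman: dict[str, Optional[float]] = field(default_factory=dict)
    best_decoy: dict[str, dict[str, str]] = field(default_factory=dict)
    classification: dict[str, Optional[str]] = field(default_factory=dict)
    best_rmsd_own: dict[str, float] = field(default_factory=dict)
    best_rmsd_cross: dict[str, float] = field(default_factory=dict)
    conformer_pair_rmsd: Optional[float] = None
    group_label: str = ""
    decoy_score_summary: dict[str, float] = field(default_factory=dict)
    tie_log: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "n_decoys_total": self.n_decoys_total,
            "n_decoys_passed": self.n_decoys_passed,
            "n_significant_comparisons": self.n_significant_comparisons,
            "high_quality": self.high_quality,
            "spearman": self.spearman,
            "best_decoy": self.best_decoy,
            "classification": self.classification,
            "best_rmsd_own": self.best_rmsd_own,
            "best_rmsd_cross": self.best_rmsd_cross,
            "conformer_pair_rmsd": self.conformer_pair_rmsd,
            "group_label": self.group_label,
            "decoy_score_summary": self.decoy_score_summary,
            "tie_log": self.tie_log,
            "flags": self.flags,
        }


def _score_decoys(
    pair: ConformerPair,
    decoys: Sequence[DecoyRecord],
    metrics: Iterable[str],
    significance: Callable[[SimilarityScores], bool],
) -> None:
    wanted = []
    for m in metrics:
        wanted.append({"RMSD": "rmsd", "GDT_TS": "gdt_ts", "TM": "tm"}[m])
    for rec in decoys:
        if rec.scores_a is None:
            rec.scores_a = score_pair(
                rec.structure, pair.conformer_a, metrics=wanted,
                significance=significance,
            )
        if rec.scores_b is None:
            rec.scores_b = score_pair(
                rec.structure, pair.conformer_b, metrics=wanted,
                significance=significance,
            )


def assess_target(
    pair: ConformerPair,
    decoys: Sequence[DecoyRecord],
    min_significant: int = 3,
    metrics: Sequence[str] = METRICS,
    significance: Callable[[SimilarityScores], bool] = default_significance,
    group_label: str = "",
    min_coverage: float = MIN_COVERAGE,
    max_missing: int = MAX_CONSECUTIVE_MISSING,
) -> TargetAssessment:
    """Run the full dual-reference analysis for one target.

    Decoys are filtered, scored against both conformers, ranked per metric,
    and the per-metric Spearman correlation, best decoys, cross-RMSDs and
    SAME/DIFFERENT classification are derived.  ``high_quality`` is set when
    at least ``min_significant`` decoy-conformer comparisons pass the
    significance gate.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    passed, _ = filter_decoys(
        list(decoys), pair.conformer_a, min_coverage=min_coverage,
        max_missing=max_missing,
    )
    out = TargetAssessment(
        target_id=pair.target_id,
        n_decoys_total=len(decoys),
        n_decoys_passed=len(passed),
        n_significant_comparisons=0,
        high_quality=False,
        conformer_pair_rmsd=pair.scores_ab.rmsd,
        group_label=group_label,
    )
    if not passed:
        out.flags.append("no_decoys_passed_filters")
        out.classification = {m: None for m in metrics}
        out.spearman = {m: None for m in metrics}
        return out
    _score_decoys(pair, passed, metrics, significance)
    n_sig = sum(rec.scores_a.significant for rec in passed) + sum(
        rec.scores_b.significant for rec in passed
    )
    out.n_significant_comparisons = n_sig
    out.high_quality = n_sig >= min_significant

    rmsds_a = [rec.scores_a.rmsd for rec in passed]
    summary = {"n_scored": float(len(passed)), "rmsd_max_a": max(rmsds_a),
               "rmsd_mean_a": float(np.mean(rmsds_a))}
    if "GDT_TS" in metrics:
        g = [rec.scores_a.gdt_ts for rec in passed]
        summary.update(gdt_ts_min_a=min(g), gdt_ts_mean_a=float(np.mean(g)))
    if "TM" in metrics:
        t = [rec.scores_a.tm_score for rec in passed]
        summary.update(tm_min_a=min(t), tm_mean_a=float(np.mean(t)))
    out.decoy_score_summary = summary

    by_id = {rec.decoy_id: rec for rec in passed}
    for m in metrics:
        try:
            rank_a = rank_decoys(passed, "a", m)
            rank_b = rank_decoys(passed, "b", m)
        except ValueError:
            out.spearman[m] = None
            out.classification[m] = None
            out.flags.append(f"no_rankable_decoys_{m}")
            continue
        out.spearman[m] = spearman_rho(rank_a, rank_b)
        best_a, best_b = rank_a.best_id, rank_b.best_id
        for rank, best in ((rank_a, best_a), (rank_b, best_b)):
            tied = [i for i in rank.ranks if rank.ranks[i] == rank.ranks[best]]
            if len(tied) > 1:
                out.tie_log.append(f"{m}: best-decoy tie among {sorted(tied)}")
        out.best_decoy[m] = {"a": best_a, "b": best_b}
        out.classification[m] = SAME_BEST if best_a == best_b else DIFFERENT_BEST
        if m == "RMSD":
            rec_a, rec_b = by_id[best_a], by_id[best_b]
            out.best_rmsd_own = {
                "a": rec_a.scores_a.rmsd,
                "b": rec_b.scores_b.rmsd,
            }
            out.best_rmsd_cross = {
                "a": rmsd_aligned(rec_a.structure, pair.conformer_b),
                "b": rmsd_aligned(rec_b.structure, pair.conformer_a),
            }
    return out


def cohort_report(
    assessments: Sequence[TargetAssessment],
    high_quality_only: bool = False,
) -> dict:
    """Aggregate per-target assessments into cohort-level statistics.

    Per metric: SAME_BEST / DIFFERENT_BEST fractions (complementary over
    classified targets), mean Spearman rho, and for RMSD the mean own- and
    cross-RMSD of best decoys over DIFFERENT_BEST and SAME_BEST targets.
    Per-group (dataset) summary tables are included under ``per_group``.
    """
    if not assessments:
        raise ValueError("no assessments to report")
    pool = [a for a in assessments if a.high_quality] if high_quality_only else list(assessments)
    report: dict = {
        "n_targets": len(pool),
        "n_high_quality": sum(a.high_quality for a in assessments),
        "high_quality_only": high_quality_only,
        "metrics": {},
    }
    for m in METRICS:
        classified = [a for a in pool if a.classification.get(m) in (SAME_BEST, DIFFERENT_BEST)]
        rhos = [a.spearman.get(m) for a in pool if a.spearman.get(m) is not None]
        entry: dict = {
            "n_classified": len(classified),
            "mean_spearman": float(np.mean(rhos)) if rhos else None,
        }
        if classified:
            n_same = sum(a.classification[m] == SAME_BEST for a in classified)
            entry["fraction_same_best"] = n_same / len(classified)
            entry["fraction_different_best"] = 1.0 - entry["fraction_same_best"]
        else:
            entry["fraction_same_best"] = None
            entry["fraction_different_best"] = None
        if m == "RMSD" and classified:
            diff = [a for a in classified if a.classification[m] == DIFFERENT_BEST]
            same = [a for a in classified if a.classification[m] == SAME_BEST]
            if diff:
                entry["mean_best_rmsd_own_different"] = float(np.mean(
                    [v for a in diff for v in a.best_rmsd_own.values()]
                ))
                entry["mean_best_rmsd_cross_different"] = float(np.mean(
                    [v for a in diff for v in a.best_rmsd_cross.values()]
                ))
            if same:
                entry["mean_best_rmsd_own_same"] = float(np.mean(
                    [v for a in same for v in a.best_rmsd_own.values()]
                ))
        report["metrics"][m] = entry

    groups: dict[str, list[TargetAssessment]] = {}
    for a in pool:
        groups.setdefault(a.group_label or "all", []).append(a)
    per_group = []
    for label in sorted(groups):
        members = groups[label]
        row = {
            "dataset": label,
            "proteins": len(members),
            "decoys": int(sum(a.n_decoys_passed for a in members)),
        }
        for key, how in (
            ("gdt_ts_min_a", "min"), ("gdt_ts_mean_a", "mean"),
            ("tm_min_a", "min"), ("tm_mean_a", "mean"),
            ("rmsd_max_a", "max"), ("rmsd_mean_a", "mean"),
        ):
            vals = [a.decoy_score_summary.get(key) for a in members
                    if a.decoy_score_summary.get(key) is not None]
            if vals:
                row[key] = float({"min": min, "max": max, "mean": np.mean}[how](vals))
            else:
                row[key] = math.nan
        per_group.append(row)
    report["per_group"] = per_group
    return report


def cohort_table(report: dict) -> pd.DataFrame:
    """Tabular (dataset-per-row) view of the per-group cohort statistics."""
    return pd.DataFrame(report["per_group"])
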