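"""Selection of the maximally distant conformer pair per target and
per-group diversity summaries."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import SimilarityScores, rmsd_aligned, score_pair
from .structure_io import CalphaStructure

__all__ = ["ConformerPair", "select_max_diverse_pair", "diversity_summary"]

CAUSES = ("LIGAND", "PTM", "OLIGOMER", "NMR", "UNKNOWN")


@dataclass
class ConformerPair:
    """The two most structurally distant conformers of one target."""

    target_id: str
    conformer_a: CalphaStructure
    conformer_b: CalphaStructure
    scores_ab: SimilarityScores
    cause: Optional[str] = None
    delta_rasa: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cause is not None and self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}")
        if self.conformer_a.conformer_key > self.conformer_b.conformer_key:
            self.conformer_a, self.conformer_b = self.conformer_b, self.conformer_a


def select_max_diverse_pair(
    conformers: Sequence[CalphaStructure],
    target_id: Optional[str] = None,
    cause: Optional[str] = None,
    metrics: Iterable[str] = ("rmsd", "gdt_ts", "tm"),
) -> ConformerPair:
    """Pick the conformer pair with maximal pairwise C-alpha RMSD.

    All C(n, 2) pairwise RMSDs are computed; ties are broken
    lexicographically by the (id_a, id_b) conformer keys.  The full score
    set for the winning pair is computed with ``conformer_a`` as model and
    ``conformer_b`` as reference.
    """
    if len(conformers) < 2:
        raise ValueError("need at least 2 conformers")
    ranked = sorted(conformers, key=lambda s: s.conformer_key)
    best: Optional[tuple[float, str, str, CalphaStructure, CalphaStructure]] = None
    for a, b in combinations(ranked, 2):
        r = rmsd_aligned(a, b)
        key = (-r, a.conformer_key, b.conformer_key)
        if best is None or key < best[0]:
            best = (key, a, b)
    _, a, b = best
    tid = target_id if target_id is not None else a.structure_id
    return ConformerPair(
        target_id=tid,
        conformer_a=a,
        conformer_b=b,
        scores_ab=score_pair(a, b, metrics=metrics),
        cause=cause,
    )


def diversity_summary(
    pairs: Sequence[ConformerPair], group_by: str = "cause"
) -> pd.DataFrame:
    """Per-group statistics of conformer-pair diversity.

    ``group_by`` is ``"cause"`` or ``"method"`` (experimental method of
    conformer_a).  Columns: count, RMSD mean/max/min, mean GDT_TS, mean
    TM-score, mean delta-rASA (NaN when not computed).
    """
    if not pairs:
        raise ValueError("no pairs to summarise")
    if group_by not in ("cause", "method"):
        raise ValueError("group_by must be 'cause' or 'method'")
    rows = []
    for p in pairs:
        group = (
            (p.cause or "UNKNOWN")
            if group_by == "cause"
            else p.conformer_a.method.value
        )
        rows.append(
            {
                "group": group,
                "target_id": p.target_id,
                "rmsd": p.scores_ab.rmsd,
                "gdt_ts": p.scores_ab.gdt_ts,
                "tm_score": p.scores_ab.tm_score,
                "delta_rasa": np.nan if p.delta_rasa is None else p.delta_rasa,
            }
        )
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(
        count=("target_id", "size"),
        rmsd_mean=("rmsd", "mean"),
        rmsd_max=("rmsd", "max"),
        rmsd_min=("rmsd", "min"),
        gdt_ts_mean=("gdt_ts", "mean"),
        tm_score_mean=("tm_score", "mean"),
        delta_rasa_mean=("delta_rasa", "mean"),
    )
    return out.reset_index()
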