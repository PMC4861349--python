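"""End-to-end orchestration: manifests in, report bundle out.

Reads the conformer and decoy manifests, selects the maximally distant
conformer pair per target, filters and scores decoys against both
conformers, ranks and correlates, classifies targets, and writes TSV/JSON
reports plus a run log with the configuration hash and per-stage counts.
All outputs are written in manifest order, so identical inputs and config
yield byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .assessment import (
    METRICS,
    DecoyRecord,
    TargetAssessment,
    assess_target,
    cohort_report,
    cohort_table,
)
from .diversity import ConformerPair, diversity_summary, select_max_diverse_pair
from .metrics import make_significance, per_position_profile
from .structure_io import CalphaStructure, read_structures

__all__ = ["RunConfig", "run_pipeline", "load_conformer_manifest", "load_decoy_manifest"]

_METRIC_ALIASES = {
    "rmsd": "RMSD", "gdt_ts": "GDT_TS", "gdt": "GDT_TS",
    "tm": "TM", "tm_score": "TM",
}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; every threshold is echoed into the run log."""

    conformers_tsv: str
    decoys_tsv: str
    outdir: str
    metric_set: tuple[str, ...] = METRICS
    min_coverage: float = 0.8
    max_consecutive_missing: int = 5
    sig_min_aligned: int = 30
    sig_min_coverage: float = 0.8
    min_significant: int = 3
    seed: int = 0

    @staticmethod
    def parse_metric_set(text: str) -> tuple[str, ...]:
        out = []
        for token in text.replace(";", ",").split(","):
            token = token.strip().lower()
            if not token:
                continue
            if token not in _METRIC_ALIASES:
                raise ValueError(f"unknown metric {token!r}")
            out.append(_METRIC_ALIASES[token])
        if not out:
            raise ValueError("metric set is empty")
        return tuple(dict.fromkeys(out))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_conformer_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target_id", "model_number", "chain", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"conformer manifest missing columns: {sorted(missing)}")
    df["model_number"] = df["model_number"].astype(int)
    return df


def load_decoy_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target_id", "decoy_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decoy manifest missing columns: {sorted(missing)}")
    return df


def _load_conformers(rows: pd.DataFrame, base: Path) -> list[CalphaStructure]:
    cache: dict[tuple[str, str], list[CalphaStructure]] = {}
    out = []
    for _, row in rows.iterrows():
        chain = row["chain"] if isinstance(row["chain"], str) and row["chain"] else None
        key = (row["path"], chain or "")
        if key not in cache:
            cache[key] = read_structures(_resolve(row["path"], base), chain=chain)
        models = cache[key]
        wanted = int(row["model_number"])
        match = [s for s in models if s.model_number == wanted]
        if not match:
            raise ValueError(
                f"model {wanted} not found in {row['path']} "
                f"(has {[s.model_number for s in models]})"
            )
        out.append(match[0])
    return out


def _resolve(p: str, base: Path) -> Path:
    path = Path(p)
    return path if path.is_absolute() else base / path


def _comparison_rows(target_id: str, which: str, decoys: list[DecoyRecord]) -> list[dict]:
    rows = []
    for rec in decoys:
        scores = rec.scores_a if which == "a" else rec.scores_b
        if scores is None:
            continue
        rows.append(
            {
                "target_id": target_id,
                "reference_conformer": which,
                "model_id": rec.decoy_id,
                "rmsd": round(scores.rmsd, 6),
                "gdt_ts": None if scores.gdt_ts is None else round(scores.gdt_ts, 6),
                "tm_score": None if scores.tm_score is None else round(scores.tm_score, 6),
                "n_aligned": scores.n_aligned,
                "coverage": round(scores.coverage, 6),
                "significant": scores.significant,
            }
        )
    return rows


def _profile_rows(
    target_id: str, comparison: str, model: CalphaStructure, reference: CalphaStructure
) -> list[dict]:
    prof = per_position_profile(model, reference)
    return [
        {
            "target": target_id,
            "comparison": comparison,
            "residue_number": pos,
            "d": round(float(d), 6),
            "z": round(float(z), 6),
        }
        for pos, d, z in zip(prof.positions, prof.d, prof.z)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full assessment and write the report bundle.

    Per-target failures are logged into the run log and skipped; the
    returned dict is the run log (also written to ``run_log.json``).
    """
    outdir = Path(config.outdir)
    (outdir / "targets").mkdir(parents=True, exist_ok=True)
    conf_df = load_conformer_manifest(config.conformers_tsv)
    decoy_df = load_decoy_manifest(config.decoys_tsv)
    conf_base = Path(config.conformers_tsv).parent
    decoy_base = Path(config.decoys_tsv).parent
    significance = make_significance(config.sig_min_aligned, config.sig_min_coverage)

    assessments: list[TargetAssessment] = []
    pairs: list[ConformerPair] = []
    comparison_rows: list[dict] = []
    profile_rows: list[dict] = []
    errors: list[dict] = []
    n_decoys_seen = 0

    target_order = list(dict.fromkeys(conf_df["target_id"]))
    for target_id in target_order:
        rows = conf_df[conf_df["target_id"] == target_id]
        try:
            conformers = _load_conformers(rows, conf_base)
            cause = None
            if "cause" in rows.columns:
                causes = [c for c in rows["cause"] if isinstance(c, str) and c]
                cause = causes[0] if causes else None
            pair = select_max_diverse_pair(
                conformers, target_id=target_id, cause=cause,
                metrics=[m.lower() for m in config.metric_set],
            )
            drows = decoy_df[decoy_df["target_id"] == target_id]
            decoys = []
            for _, dr in drows.iterrows():
                chain = dr.get("chain") if isinstance(dr.get("chain"), str) else None
                structs = read_structures(
                    _resolve(dr["path"], decoy_base), chain=chain,
                    structure_id=dr["decoy_id"],
                )
                decoys.append(
                    DecoyRecord(
                        decoy_id=dr["decoy_id"],
                        structure=structs[0],
                        group_label=str(dr.get("group_label", "") or ""),
                    )
                )
            n_decoys_seen += len(decoys)
            assessment = assess_target(
                pair,
                decoys,
                min_significant=config.min_significant,
                metrics=config.metric_set,
                significance=significance,
                group_label=decoys[0].group_label if decoys else "",
                min_coverage=config.min_coverage,
                max_missing=config.max_consecutive_missing,
            )
            assessments.append(assessment)
            pairs.append(pair)
            passed = [d for d in decoys if d.passed_filters]
            comparison_rows += _comparison_rows(target_id, "a", passed)
            comparison_rows += _comparison_rows(target_id, "b", passed)
            profile_rows += _profile_rows(
                target_id, "conformer_a_vs_b", pair.conformer_a, pair.conformer_b
            )
            best = assessment.best_decoy.get("RMSD")
            if best:
                by_id = {d.decoy_id: d for d in passed}
                for which, other in (("a", "b"), ("b", "a")):
                    rec = by_id[best[which]]
                    own = pair.conformer_a if which == "a" else pair.conformer_b
                    alt = pair.conformer_b if which == "a" else pair.conformer_a
                    profile_rows += _profile_rows(
                        target_id, f"best_decoy_{which}_vs_{which}", rec.structure, own
                    )
                    profile_rows += _profile_rows(
                        target_id, f"best_decoy_{which}_vs_{other}", rec.structure, alt
                    )
            with open(outdir / "targets" / f"{target_id}.json", "w") as fh:
                json.dump(assessment.to_dict(), fh, indent=2, sort_keys=True)
        except Exception as exc:  # per-target isolation
            errors.append({"target_id": target_id, "error": f"{type(exc).__name__}: {exc}"})

    if not assessments:
        raise RuntimeError(f"no target could be assessed; errors: {errors}")

    cols = ["target_id", "reference_conformer", "model_id", "rmsd",
            "gdt_ts", "tm_score", "n_aligned", "coverage", "significant"]
    comp_df = pd.DataFrame(comparison_rows, columns=cols)
    if "GDT_TS" not in config.metric_set:
        comp_df = comp_df.drop(columns=["gdt_ts"])
    if "TM" not in config.metric_set:
        comp_df = comp_df.drop(columns=["tm_score"])
    comp_df.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    pd.DataFrame(
        profile_rows, columns=["target", "comparison", "residue_number", "d", "z"]
    ).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    pair_rows = [
        {
            "target_id": p.target_id,
            "conformer_a": p.conformer_a.conformer_key,
            "conformer_b": p.conformer_b.conformer_key,
            "rmsd": round(p.scores_ab.rmsd, 6),
            "gdt_ts": None if p.scores_ab.gdt_ts is None else round(p.scores_ab.gdt_ts, 6),
            "tm_score": None if p.scores_ab.tm_score is None else round(p.scores_ab.tm_score, 6),
            "cause": p.cause or "UNKNOWN",
        }
        for p in pairs
    ]
    pd.DataFrame(pair_rows).to_csv(outdir / "conformer_pairs.tsv", sep="\t", index=False)
    diversity_summary(pairs).to_csv(outdir / "diversity_summary.tsv", sep="\t", index=False)

    report_all = cohort_report(assessments, high_quality_only=False)
    report_hq = cohort_report(assessments, high_quality_only=True)
    with open(outdir / "cohort_report.json", "w") as fh:
        json.dump(
            {"all_targets": report_all, "high_quality_subset": report_hq},
            fh, indent=2, sort_keys=True,
        )
    cohort_table(report_all).to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)

    schema = {
        "comparisons.tsv": {
            "rmsd": "Angstrom", "gdt_ts": "fraction [0,1]",
            "tm_score": "fraction (0,1]", "coverage": "fraction [0,1]",
        },
        "profiles.tsv": {"d": "Angstrom", "z": "unitless z-score"},
        "conformer_pairs.tsv": {"rmsd": "Angstrom"},
        "cohort_table.tsv": {"rmsd_*": "Angstrom", "gdt_ts_*": "fraction",
                             "tm_*": "fraction"},
    }
    with open(outdir / "schema.json", "w") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)

    run_log = {
        "tool_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "counts": {
            "targets_in_manifest": len(target_order),
            "targets_assessed": len(assessments),
            "targets_failed": len(errors),
            "decoys_in_manifest": int(len(decoy_df)),
            "decoys_loaded": n_decoys_seen,
            "decoys_passed_filters": int(sum(a.n_decoys_passed for a in assessments)),
            "significant_comparisons": int(
                sum(a.n_significant_comparisons for a in assessments)
            ),
        },
        "errors": errors,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return run_log
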