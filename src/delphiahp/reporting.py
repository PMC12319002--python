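"""Report writers and the two-round study pipeline.

Reports mirror the published layout: one row per indicator with
``id, name, mean±sd, cv, weight, rank`` (2-decimal statistics, 4-decimal
weights), written as TSV and JSON with deterministic ordering by id. Every
stage appends machine-readable entries to an audit log (JSON lines, no
timestamps, so identical inputs give byte-identical output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import ahp as _ahp
from . import delphi as _delphi
from .config import PipelineConfig
from .delphi import IndicatorStats, round_half_up
from .hierarchy import IndicatorHierarchy, load_final_framework, load_hierarchy

__all__ = [
    "ReportError",
    "StudyReport",
    "build_table",
    "write_report",
    "run_pipeline",
    "write_audit",
]


class ReportError(ValueError):
    pass


@dataclass
class StudyReport:
    hierarchy: IndicatorHierarchy
    table: pd.DataFrame
    ahp: _ahp.AhpReport
    rounds: list[_delphi.RoundReport] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)


def _id_key(indicator_id: str) -> tuple[int, ...]:
    return tuple(int(p) for p in indicator_id.split("."))


def build_table(
    hierarchy: IndicatorHierarchy,
    stats: Sequence[IndicatorStats],
    weights: _ahp.WeightVector,
    stats_decimals: int = 2,
    weight_decimals: int = 4,
) -> pd.DataFrame:
    """Assemble the report table; raises on id mismatch between inputs."""
    stat_by_id = {s.indicator_id: s for s in stats}
    active_ids = [i.id for i in hierarchy.active()]
    missing = sorted(set(active_ids) - set(stat_by_id))
    if missing:
        raise ReportError(f"stats missing for indicator(s): {', '.join(missing)}")
    extra = sorted(set(stat_by_id) - set(active_ids))
    if extra:
        raise ReportError(f"stats for unknown indicator(s): {', '.join(extra)}")
    rows = []
    for iid in sorted(active_ids, key=_id_key):
        ind = hierarchy.get(iid)
        st = stat_by_id[iid]
        mean, sd, cv = (
            round_half_up(st.mean, stats_decimals),
            round_half_up(st.sd, stats_decimals),
            round_half_up(st.cv, stats_decimals),
        )
        rows.append(
            {
                "id": iid,
                "name": ind.name,
                "mean": mean,
                "sd": sd,
                "mean_sd": f"{mean:.{stats_decimals}f} ± {sd:.{stats_decimals}f}",
                "cv": cv,
                "weight": round_half_up(weights.combination[iid], weight_decimals),
                "rank": weights.leaf_rank.get(iid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "name", "mean", "sd", "mean_sd", "cv", "weight", "rank"],
    )


def write_report(
    table: pd.DataFrame, out_dir: str | Path, stem: str = "weights", fmt: str = "both"
) -> list[Path]:
    """Write the report table as TSV and/or JSON; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    cols = ["id", "name", "mean_sd", "cv", "weight", "rank"]
    view = table[cols]
    if fmt in ("tsv", "both"):
        p = out_dir / f"{stem}.tsv"
        view.to_csv(p, sep="\t", index=False)
        written.append(p)
    if fmt in ("json", "both"):
        p = out_dir / f"{stem}.json"
        p.write_text(
            json.dumps(
                table.where(table.notna(), None).to_dict(orient="records"),
                indent=1,
                ensure_ascii=False,
            )
            + "\n",
            encoding="utf-8",
        )
        written.append(p)
    return written


def _stats_from_reference(hierarchy: IndicatorHierarchy) -> list[IndicatorStats]:
    ref = _delphi.load_reference_stats().set_index("indicator_id")
    out = []
    for ind in hierarchy.active():
        row = ref.loc[ind.id]
        out.append(
            IndicatorStats(
                ind.id, float(row["mean"]), float(row["sd"]), float(row["cv"])
            )
        )
    return out


def run_pipeline(config: PipelineConfig, force: bool = False) -> StudyReport:
    """Execute the study: round-1 stats → screening → revision → round-2
    stats → convergence check → AHP → report table.

    With no panel paths configured, the bundled reference dataset (final
    framework + published summary statistics) drives the AHP stage directly.
    Any stage error halts the run naming the stage and offending ids.
    """
    audit: list[dict] = []
    hierarchy = (
        load_hierarchy(config.hierarchy_path)
        if config.hierarchy_path
        else load_final_framework()
    )
    audit.append(
        {
            "stage": "load_hierarchy",
            "active_counts": list(hierarchy.active_counts()),
        }
    )

    rounds: list[_delphi.RoundReport] = []
    means: dict[str, float]
    if config.round1_scores is not None:
        if config.round2_scores is None:
            raise FileNotFoundError("round 2 panel not found")
        panel1 = _delphi.read_score_panel(
            config.round1_scores,
            round_id=1,
            votes_path=config.round1_votes,
            authority_path=config.round1_authority,
        )
        report1 = _delphi.run_round(hierarchy, panel1, config.screening)
        rounds.append(report1)
        for d in report1.decisions:
            audit.append(
                {
                    "stage": "screening",
                    "round": 1,
                    "indicator_id": d.indicator_id,
                    "verdict": d.verdict,
                    "rules": list(d.triggered_rules),
                }
            )
        deletions = [
            {"action": "delete", "id": d.indicator_id, "note": "screened out in round 1"}
            for d in report1.decisions
            if d.verdict == "delete"
        ]
        if deletions:
            hierarchy = hierarchy.apply_revision(1, deletions)
            audit.append(
                {
                    "stage": "revision",
                    "round": 1,
                    "deleted": [a["id"] for a in deletions],
                }
            )
        panel2 = _delphi.read_score_panel(
            config.round2_scores,
            round_id=2,
            votes_path=config.round2_votes,
            authority_path=config.round2_authority,
        )
        keep = [i for i in panel2.indicator_ids if i in {x.id for x in hierarchy.active()}]
        if len(keep) < len(panel2.indicator_ids):
            import numpy as np

            idx = [panel2.indicator_ids.index(i) for i in keep]
            panel2 = _delphi.ScorePanel(
                round_id=2,
                expert_ids=panel2.expert_ids,
                indicator_ids=keep,
                scores=panel2.scores[:, idx],
                necessity_votes=(
                    panel2.necessity_votes[:, idx]
                    if panel2.necessity_votes is not None
                    else None
                ),
                judgment_grades=panel2.judgment_grades,
                familiarity=panel2.familiarity,
            )
        report2 = _delphi.run_round(hierarchy, panel2, config.screening)
        rounds.append(report2)
        for d in report2.decisions:
            audit.append(
                {
                    "stage": "screening",
                    "round": 2,
                    "indicator_id": d.indicator_id,
                    "verdict": d.verdict,
                    "rules": list(d.triggered_rules),
                }
            )
        audit.append(
            {
                "stage": "convergence",
                "round": 2,
                "w": report2.concordance.w,
                "converged": report2.converged,
            }
        )
        stats = list(report2.stats)
        means = {s.indicator_id: s.mean for s in stats}
    elif config.means_path is not None:
        df = pd.read_csv(config.means_path, dtype={"indicator_id": str})
        means = dict(zip(df["indicator_id"], df["mean"].astype(float)))
        if "sd" in df.columns:
            sd = dict(zip(df["indicator_id"], df["sd"].astype(float)))
        else:
            sd = {i: 0.0 for i in means}
        stats = [
            IndicatorStats(
                i, means[i], sd[i], sd[i] / means[i] if means[i] else 0.0
            )
            for i in means
        ]
    else:
        stats = _stats_from_reference(hierarchy)
        means = {s.indicator_id: s.mean for s in stats}
    audit.append({"stage": "means", "n_indicators": len(means)})

    ahp_report = _ahp.full_ahp(
        hierarchy,
        means,
        mapping=config.saaty_mapping,
        random_index=config.random_index,
        force=force,
    )
    for parent, cres in ahp_report.consistency.items():
        audit.append(
            {
                "stage": "consistency",
                "parent": parent if parent is not None else "<top level>",
                "lambda_max": round(cres.lambda_max, 6),
                "cr": round(cres.cr, 4),
                "passed": cres.passed,
            }
        )
    table = build_table(
        hierarchy,
        stats,
        ahp_report.weights,
        stats_decimals=config.stats_decimals,
        weight_decimals=config.weight_decimals,
    )
    return StudyReport(
        hierarchy=hierarchy, table=table, ahp=ahp_report, rounds=rounds, audit=audit
    )


def write_audit(report: StudyReport, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / "audit.jsonl"
    p.write_text(
        "".join(json.dumps(e, ensure_ascii=False) + "\n" for e in report.audit),
        encoding="utf-8",
    )
    return p
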