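"""Aggregate validation output into the study's reporting tables.

Four surfaces: the per-precursor validation table (verdicts, per-run
detections, q-values), the replicate-overlap (UpSet) exclusive-intersection
count table, the iRT index of validated precursors, and the
negative-control contrast table.  All outputs are plain CSV and
deterministic functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import pandas as pd

from .irt_align import IrtModel
from .validation import ValidationRecord, upset_counts

__all__ = ["StudyReport", "build_report", "write_report"]


@dataclass
class StudyReport:
    validation_table: pd.DataFrame
    upset_table: pd.DataFrame
    irt_index: pd.DataFrame
    control_contrast: pd.DataFrame
    summary: Dict[str, float]


def build_report(
    records: Sequence[ValidationRecord],
    irt_models: Mapping[str, IrtModel],
    id_sets: Mapping[str, Sequence[str]],
    control_runs: Sequence[str] = (),
) -> StudyReport:
    """Build all report tables from validation records.

    ``id_sets`` maps replicate run names to the precursor keys identified
    (by XSM) in that run; its exclusive intersections form the UpSet table.
    The summary includes ``fraction_xsm_all_replicates``: among precursors
    assessed, the fraction whose XSMs appear in every replicate set.
    """
    val_rows = []
    for r in sorted(records, key=lambda r: r.precursor):
        row = {
            "precursor": r.precursor,
            "q_value": r.q_value,
            "consensus_irt": r.consensus_irt,
            "replicate_detection_count": r.replicate_detection_count,
            "n_replicates": r.n_replicates,
            "negative_control_detected": r.negative_control_detected,
            "verdict": r.verdict,
        }
        for run_id, detected in sorted(r.per_run_detected.items()):
            row[f"detected[{run_id}]"] = detected
        val_rows.append(row)
    validation_table = pd.DataFrame(val_rows)

    counts = upset_counts(id_sets) if id_sets else {}
    upset_table = pd.DataFrame(
        [
            {"sets": "&".join(combo), "degree": len(combo), "count": n}
            for combo, n in sorted(
                counts.items(), key=lambda kv: (-len(kv[0]), kv[0])
            )
        ],
        columns=["sets", "degree", "count"],
    )

    validated = [r for r in records if r.verdict == "validated"]
    irt_index = pd.DataFrame(
        [
            {"precursor": r.precursor, "consensus_irt": r.consensus_irt,
             "q_value": r.q_value}
            for r in sorted(validated, key=lambda r: r.consensus_irt)
        ],
        columns=["precursor", "consensus_irt", "q_value"],
    )

    contrast_rows = []
    for r in sorted(records, key=lambda r: r.precursor):
        for run in control_runs:
            peak = r.per_run_peaks.get(run)
            contrast_rows.append(
                {
                    "precursor": r.precursor,
                    "control_run": run,
                    "peak_found": r.per_run_detected.get(run, False),
                    "apex_rt": peak.apex_rt if peak else float("nan"),
                    "consensus_irt": r.consensus_irt,
                }
            )
    control_contrast = pd.DataFrame(
        contrast_rows,
        columns=["precursor", "control_run", "peak_found", "apex_rt",
                 "consensus_irt"],
    )

    n_assessed = len(records)
    verdict_counts = {
        v: sum(r.verdict == v for r in records)
        for v in ("validated", "rejected_fdr", "rejected_control",
                  "rejected_replicates", "not_detected")
    }
    assert sum(verdict_counts.values()) == n_assessed
    all_sets = list(id_sets.values())
    if all_sets and n_assessed:
        in_all = set(all_sets[0]).intersection(*map(set, all_sets[1:]))
        frac = sum(r.precursor in in_all for r in records) / n_assessed
    else:
        frac = 0.0
    summary = {
        "n_assessed": float(n_assessed),
        "fraction_xsm_all_replicates": frac,
        **{f"n_{k}": float(v) for k, v in verdict_counts.items()},
    }
    return StudyReport(
        validation_table=validation_table,
        upset_table=upset_table,
        irt_index=irt_index,
        control_contrast=control_contrast,
        summary=summary,
    )


def write_report(report: StudyReport, out_dir: Union[str, Path]) -> List[Path]:
    """Write all report tables as CSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("validation_table.csv", report.validation_table),
        ("upset_counts.csv", report.upset_table),
        ("irt_index.csv", report.irt_index),
        ("control_contrast.csv", report.control_contrast),
    ):
        path = out / name
        df.to_csv(path, index=False)
        paths.append(path)
    summary_path = out / "summary.csv"
    pd.DataFrame(
        [{"metric": k, "value": v} for k, v in report.summary.items()]
    ).to_csv(summary_path, index=False)
    paths.append(summary_path)
    return paths
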