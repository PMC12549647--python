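"""Publication-style outputs: study tables, effect curves, battery summaries.

Table rows follow the convention of per-drug telemetry summaries: a
``(lb;ub) [peak hour]`` string per model (bounds rounded to 0.1 ms, the
peak hour in square brackets), a signed maximum heart-rate change column,
and the TQT-style classification.  Machine-readable CSVs keep full
precision; plots mark hours whose lower bound reaches the 5 ms threshold
with an asterisk rather than conventional p-value stars.
"""

from __future__ import annotations

import os
import re

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .effect_stats import HourlyEffect, StudyReport  # noqa: E402

_BOUNDS_RE = re.compile(
    r"^\((-?\d+(?:\.\d+)?);(-?\d+(?:\.\d+)?)\)\s*\[(-?\d+)\]$")


def format_bounds(report: StudyReport) -> str:
    """``(lb;ub) [peak hour]`` at 0.1 ms, for the study's peak-effect hour."""
    if report.peak is None:
        return "(n/a)"
    return (f"({report.peak.lb:.1f};{report.peak.ub:.1f}) "
            f"[{report.peak_hour}]")


def parse_bounds(text: str) -> tuple[float, float, int]:
    """Invert :func:`format_bounds` (exact at the 0.1 ms precision)."""
    m = _BOUNDS_RE.match(text.strip())
    if not m:
        raise ValueError(f"not a bounds string: {text!r}")
    return float(m.group(1)), float(m.group(2)), int(m.group(3))


def effects_frame(report: StudyReport) -> pd.DataFrame:
    """Per-hour effect table (full precision) for one model."""
    return pd.DataFrame(
        [(e.hour_index, e.n, e.mean, e.lb, e.ub, e.lsd)
         for e in report.effects],
        columns=["hour_index", "n", "mean", "lb", "ub", "lsd"])


def study_row(reports: dict[str, StudyReport],
              treatment: str | None = None) -> dict:
    """One summary-table row across models for a single study."""
    any_report = next(iter(reports.values()))
    row = {
        "treatment": treatment or any_report.study_id,
        "hr_max_change": (None if any_report.max_hr_change is None
                          else round(any_report.max_hr_change, 1)),
    }
    for model, rep in reports.items():
        row[model] = format_bounds(rep)
        row[f"{model}_classification"] = rep.classification
    return row


def study_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def table_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(row[c]) else str(row[c])
                                       for c in cols) + " |")
    return "\n".join(lines) + "\n"


def write_report(result_reports: dict[str, StudyReport], out_dir: str,
                 treatment: str | None = None) -> None:
    """Write per-hour CSVs per model plus the summary row (CSV + Markdown)."""
    os.makedirs(out_dir, exist_ok=True)
    any_report = next(iter(result_reports.values()))
    stem = f"{any_report.study_id}_{any_report.mode}"
    for model, rep in result_reports.items():
        effects_frame(rep).to_csv(
            os.path.join(out_dir, f"{stem}_{model}_hourly.csv"), index=False)
    table = study_table([study_row(result_reports, treatment)])
    table.to_csv(os.path.join(out_dir, f"{stem}_summary.csv"), index=False)
    with open(os.path.join(out_dir, f"{stem}_summary.md"), "w",
              encoding="utf-8") as fh:
        fh.write(table_markdown(table))


def plot_effects(effects: pd.DataFrame, out_path: str,
                 threshold: float = 5.0, title: str = "") -> None:
    """Hourly mean with one-sided 95% CI whiskers and threshold markers.

    Hours whose lower bound reaches the threshold are marked with an
    asterisk above the upper whisker.
    """
    if effects.empty:
        raise ValueError("nothing to plot: empty effect table")
    for col in ("hour_index", "mean", "lb", "ub", "lsd"):
        if col not in effects.columns:
            raise ValueError(f"effect table lacks column {col!r}")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(effects["hour_index"], effects["mean"],
                yerr=effects["lsd"], fmt="o-", capsize=3, lw=1.2)
    ax.axhline(threshold, ls="--", color="crimson", lw=1,
               label=f"{threshold:g} ms threshold")
    ax.axhline(0, color="0.6", lw=0.8)
    starred = effects[effects["lb"] >= threshold]
    for _, row in starred.iterrows():
        ax.annotate("*", (row["hour_index"], row["ub"]),
                    textcoords="offset points", xytext=(0, 4),
                    ha="center", fontsize=14)
    ax.set_xlabel("hours post dose")
    ax.set_ylabel("ΔQTc (ms)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
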