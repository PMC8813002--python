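"""Summaries of an ITA run: round tables, theme listings, metric curves.

The round table mirrors how such analyses are reported: one row per round
with variable counts, new themes, the dropped theme and held-out AUC/BER;
the theme table lists each theme with the variables ever coded into it.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import pandas as pd

from .ita import ITAResult
from .themes import _norm, UNCATEGORIZED

__all__ = ["RunReport", "build_report", "render_report"]

FORMATS = ("json", "csv", "markdown")


@dataclass
class RunReport:
    outcome_label: str
    rows: list  # one dict per completed round
    theme_table: dict  # theme label -> list of variables
    stop_reason: str
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "outcome_label": self.outcome_label,
            "stop_reason": self.stop_reason,
            "degenerate": self.degenerate,
            "rows": self.rows,
            "theme_table": self.theme_table,
        }


def build_report(result: ITAResult, outcome_label: str = "outcome") -> RunReport:
    rows = []
    theme_table: dict = {}
    for r in result.rounds:
        rows.append({
            "round": r.round,
            "n_input_vars": len(r.input_vars),
            "n_survivors": len(r.survivors),
            "n_selected": (len(r.selection.selected) if r.selection else 0),
            "new_themes": list(r.new_themes),
            "n_new_vars": len(r.new_vars),
            "dropped_theme": r.dropped_theme,
            "auc": r.metrics.auc if r.metrics else None,
            "ber": r.metrics.ber if r.metrics else None,
            "degenerate": r.degenerate,
        })
        if r.assignment is not None:
            for v, t in r.assignment.mapping.items():
                key = next(
                    (k for k in theme_table if _norm(k) == _norm(t)), t
                )
                theme_table.setdefault(key, [])
                if v not in theme_table[key]:
                    theme_table[key].append(v)
    return RunReport(
        outcome_label=outcome_label,
        rows=rows,
        theme_table=theme_table,
        stop_reason=result.stop_reason,
        degenerate=any(r.degenerate for r in result.rounds),
    )


def render_report(result: ITAResult, format: str = "json",
                  outcome_label: str = "outcome") -> str:
    """Render a run as lossless JSON, a CSV round table, or markdown.

    JSON round-trips bit-exactly (floats serialize at full precision) and
    re-rendering a parsed report is idempotent.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    report = build_report(result, outcome_label=outcome_label)
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format == "csv":
        df = pd.DataFrame(report.rows)
        df["new_themes"] = df["new_themes"].apply("; ".join)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()

    lines = [f"# ITA run — outcome: {report.outcome_label}", ""]
    if report.degenerate:
        lines += ["**Degenerate run: at least one round produced no usable "
                  "selection.**", ""]
    lines += [f"Stop reason: `{report.stop_reason}`", "",
              "## Rounds", "",
              "| round | input vars | survivors | selected | new themes | "
              "dropped theme | AUC | BER |",
              "|---|---|---|---|---|---|---|---|"]
    for row in report.rows:
        auc = "" if row["auc"] is None else f"{row['auc']:.3f}"
        ber = "" if row["ber"] is None else f"{row['ber']:.3f}"
        lines.append(
            f"| {row['round']} | {row['n_input_vars']} | "
            f"{row['n_survivors']} | {row['n_selected']} | "
            f"{'; '.join(row['new_themes'])} | "
            f"{row['dropped_theme'] or ''} | {auc} | {ber} |"
        )
    lines += ["", "## Themes and their variables", ""]
    for theme, variables in report.theme_table.items():
        marker = " (no theme)" if _norm(theme) == _norm(UNCATEGORIZED) else ""
        lines.append(f"- **{theme}**{marker}: {', '.join(variables)}")
    lines.append("")
    return "\n".join(lines)


def plot_metrics(result: ITAResult, path=None):
    """Optional AUC/BER-by-round figure; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rounds = [r.round for r in result.rounds if r.metrics]
    auc = [r.metrics.auc for r in result.rounds if r.metrics]
    ber = [r.metrics.ber for r in result.rounds if r.metrics]
    fig, ax = plt.subplots()
    ax.plot(rounds, auc, "-o", label="AUC")
    ax.plot(rounds, ber, "-s", label="BER")
    ax.set_xlabel("ITA round")
    ax.set_ylabel("metric on held-out test set")
    ax.set_ylim(0, 1)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
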