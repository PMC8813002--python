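"""Qualitative theme coding of selected variables and coder agreement.

A theme is a group of topically related variables ('social class',
'religion' and 'age' might all be coded socio-demographics).  Coding is a
human judgment; this module manages its artifacts: per-round assignment
files mapping each selected variable to a theme label, inter-coder
agreement as the percentage of variables coded identically, and the
max-coefficient rule that picks which theme to drop before the next round.

In fully automated runs (tests, synthetic benchmarks) the generator's
ground-truth theme map stands in for the human coder via
:class:`TruthCoder`; :class:`FileCoder` replays assignment files for real
analyses, and the CLI offers an interactive prompt mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .knee import KneeSelection

__all__ = [
    "UNCATEGORIZED",
    "ThemeAssignment",
    "load_assignment",
    "coder_agreement",
    "max_coefficient_theme",
    "TruthCoder",
    "FileCoder",
]

#: label for selected variables that fit no theme; permitted but never
#: chosen for dropping while a categorized theme is available among ties
UNCATEGORIZED = "uncategorized"


def _norm(label: str) -> str:
    return " ".join(str(label).split()).casefold()


@dataclass
class ThemeAssignment:
    """One coder's mapping of a round's selected variables to theme labels."""

    round: int
    coder_id: str
    mapping: dict  # variable name -> theme label

    def __post_init__(self):
        empties = [v for v, t in self.mapping.items() if not str(t).strip()]
        if empties:
            raise ValueError(f"empty theme labels for: {sorted(empties)}")

    def themes(self) -> list:
        """Distinct theme labels in first-appearance order."""
        seen = {}
        for t in self.mapping.values():
            seen.setdefault(_norm(t), t)
        return list(seen.values())

    def variables_in(self, theme: str) -> list:
        key = _norm(theme)
        return [v for v, t in self.mapping.items() if _norm(t) == key]


def load_assignment(path, expected_vars, round: int = 1,
                    coder_id: str = "coder") -> ThemeAssignment:
    """Read a two-column (variable, theme) delimited file.

    The file must cover ``expected_vars`` exactly — missing, extra, or
    duplicated variables are fatal, listing the offenders.
    """
    df = pd.read_csv(path, header=None, names=["variable", "theme"],
                     skipinitialspace=True, comment="#")
    if df["variable"].duplicated().any():
        dups = sorted(df.loc[df["variable"].duplicated(), "variable"])
        raise ValueError(f"duplicate variable rows: {dups}")
    got, want = set(df["variable"]), set(expected_vars)
    missing, extra = sorted(want - got), sorted(got - want)
    if missing or extra:
        raise ValueError(
            f"assignment does not match the selection; missing={missing} "
            f"extra={extra}"
        )
    mapping = dict(zip(df["variable"], df["theme"].astype(str).str.strip()))
    return ThemeAssignment(round=round, coder_id=coder_id, mapping=mapping)


def coder_agreement(a: ThemeAssignment, b: ThemeAssignment) -> float:
    """Percentage of variables both coders placed in the same theme.

    Labels are compared after whitespace/case normalization.  100 iff the
    mappings are identical up to normalization; symmetric by construction.
    """
    if set(a.mapping) != set(b.mapping):
        raise ValueError("coders assigned different variable sets")
    if not a.mapping:
        raise ValueError("empty assignments")
    same = sum(_norm(a.mapping[v]) == _norm(b.mapping[v]) for v in a.mapping)
    return 100.0 * same / len(a.mapping)


def max_coefficient_theme(assignment: ThemeAssignment,
                          selection: KneeSelection) -> str:
    """Theme of the top-ranked selected variable — the round's drop target.

    This operationalizes "the theme with the maximum variance" as the theme
    containing the variable with the highest coefficient magnitude.  Exact
    magnitude ties are resolved by sort order, except that the
    ``uncategorized`` label is never returned while a categorized theme
    exists among the tied leaders.
    """
    if not selection.selected:
        raise ValueError("empty selection: no theme to drop")
    missing = [v for v in selection.selected if v not in assignment.mapping]
    if missing:
        raise ValueError(f"assignment does not cover selection: {missing}")
    value = {n: float(v) for n, v in
             zip(selection.sorted_names, selection.sorted_values)}
    top = value[selection.selected[0]]
    tied = [v for v in selection.selected if value[v] == top]
    for v in tied:
        if _norm(assignment.mapping[v]) != _norm(UNCATEGORIZED):
            return assignment.mapping[v]
    return assignment.mapping[tied[0]]


class TruthCoder:
    """Automated coder backed by a ground-truth variable -> theme map.

    Encoded column labels (``variable=level``) are matched on either the
    full label or the source variable name; unknown variables get the
    ``uncategorized`` label, mimicking selected noise that a human could
    not place in any theme.
    """

    def __init__(self, theme_map: dict, coder_id: str = "truth"):
        self.theme_map = dict(theme_map)
        self.coder_id = coder_id

    def __call__(self, round: int, selection: KneeSelection) -> ThemeAssignment:
        mapping = {}
        for name in selection.selected:
            source = name.split("=", 1)[0]
            mapping[name] = self.theme_map.get(
                name, self.theme_map.get(source, UNCATEGORIZED)
            )
        return ThemeAssignment(round=round, coder_id=self.coder_id,
                               mapping=mapping)


class FileCoder:
    """Replay per-round assignment files (round number -> file path)."""

    def __init__(self, paths_by_round: dict, coder_id: str = "file"):
        self.paths_by_round = dict(paths_by_round)
        self.coder_id = coder_id

    def __call__(self, round: int, selection: KneeSelection) -> ThemeAssignment:
        if round not in self.paths_by_round:
            raise KeyError(f"no assignment file registered for round {round}")
        return load_assignment(self.paths_by_round[round], selection.selected,
                               round=round, coder_id=self.coder_id)
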