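"""Survey tables in, model-ready matrices out.

Respondent-level survey data (DHS-style exports) arrive as a delimited text
table plus a variable-metadata file.  This module reads and types the table,
constructs the binary help-seeking outcome, screens redundant variables,
discretizes continuous ones, one-hot encodes everything into a numeric design
matrix, and splits it into train/test partitions.  Row count is invariant
through every step except the split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

__all__ = [
    "VariableMeta",
    "RawDataset",
    "EncodedDataset",
    "OutcomeRule",
    "load_metadata",
    "read_table",
    "construct_outcome",
    "screen_variables",
    "discretize_continuous",
    "one_hot_encode",
    "split_train_test",
]

VALID_KINDS = ("continuous", "categorical", "binary")

#: values recognised as affirmative when coercing yes/no survey items
YES_VALUES = frozenset({"yes", "y", "1", "true", 1, 1.0, True})
NO_VALUES = frozenset({"no", "n", "0", "false", 0, 0.0, False})


@dataclass
class VariableMeta:
    """Metadata for one survey variable.

    Parameters
    ----------
    name : str
        Column name, unique within a metadata set.
    kind : {"continuous", "categorical", "binary"}
    categories : list of str
        Ordered level labels; required for categorical variables (>= 2
        levels), defaults to ``["no", "yes"]`` for binary.
    construct_id : str or None
        Identifier grouping variables that measure the same underlying
        construct (e.g. several age recodes); at most one non-excluded
        variable per construct survives screening.
    excluded : bool
        Drop this variable during screening.
    exclusion_reason : str
        Free-text reason ("respondent ID", "survey design", ...).
    canonical : bool
        Within a construct group, the variable that survives screening.
    """

    name: str
    kind: str
    categories: list = field(default_factory=list)
    construct_id: str | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    canonical: bool = False

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(
                f"variable {self.name!r}: kind must be one of {VALID_KINDS}, "
                f"got {self.kind!r}"
            )
        if self.kind == "categorical" and len(self.categories) < 2:
            raise ValueError(
                f"categorical variable {self.name!r} needs >= 2 categories, "
                f"got {len(self.categories)}"
            )
        if self.kind == "binary" and not self.categories:
            self.categories = ["no", "yes"]


@dataclass
class RawDataset:
    """A typed respondent-level table plus its variable metadata."""

    df: pd.DataFrame
    outcome_name: str
    weight_name: str
    meta: dict  # name -> VariableMeta

    @property
    def n(self) -> int:
        return len(self.df)

    def covariate_names(self) -> list:
        """Names of all variables that are neither outcome nor weight."""
        return [
            c
            for c in self.df.columns
            if c not in (self.outcome_name, self.weight_name)
        ]


@dataclass
class EncodedDataset:
    """Numeric design matrix with outcome, weights, and column labels.

    ``X`` holds one-hot indicator columns named ``variable=level``; ``y`` is
    the binary outcome; ``w`` the strictly positive sampling weights.
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    colnames: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=np.float64)
        self.colnames = list(self.colnames)
        n, p = self.X.shape
        if len(self.y) != n or len(self.w) != n:
            raise ValueError("X, y, w row counts disagree")
        if len(self.colnames) != p:
            raise ValueError("colnames length does not match X columns")
        if len(set(self.colnames)) != p:
            raise ValueError("duplicate column names in encoded dataset")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if not np.all((self.y == 0) | (self.y == 1)):
            raise ValueError("y must be binary 0/1")
        if not np.all(self.w > 0):
            raise ValueError("weights must be strictly positive")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def take_rows(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(self.X[idx], self.y[idx], self.w[idx], self.colnames)

    def drop_columns(self, names) -> "EncodedDataset":
        """Return a copy without the named columns (row count unchanged)."""
        names = list(names)
        unknown = sorted(set(names) - set(self.colnames))
        if unknown:
            raise KeyError(f"unknown columns: {unknown}")
        keep = [j for j, c in enumerate(self.colnames) if c not in set(names)]
        if not keep:
            raise ValueError("empty design: dropping all columns")
        return EncodedDataset(
            self.X[:, keep], self.y, self.w, [self.colnames[j] for j in keep]
        )

    def select_columns(self, names) -> "EncodedDataset":
        names = list(names)
        pos = {c: j for j, c in enumerate(self.colnames)}
        unknown = sorted(set(names) - set(pos))
        if unknown:
            raise KeyError(f"unknown columns: {unknown}")
        keep = [pos[c] for c in names]
        return EncodedDataset(self.X[:, keep], self.y, self.w, names)

    def source_variable(self, colname: str) -> str:
        """Map an encoded column label back to its source variable name."""
        return colname.split("=", 1)[0]

    def to_csv(self, path, colmap_path=None):
        """Persist as delimited text plus an optional JSON column-name map."""
        df = pd.DataFrame(self.X, columns=self.colnames)
        df.insert(0, "__outcome__", self.y)
        df.insert(1, "__weight__", self.w)
        df.to_csv(path, index=False)
        if colmap_path is not None:
            with open(colmap_path, "w") as fh:
                json.dump(
                    {c: self.source_variable(c) for c in self.colnames},
                    fh,
                    indent=2,
                )


@dataclass
class OutcomeRule:
    """Rule constructing a binary help-seeking outcome.

    ``kind="any"`` uses the single gate question (did the respondent ever try
    to seek help).  ``kind="formal"`` fires only when the gate is affirmative
    AND at least one of the formal source indicators (police, lawyer, doctor,
    social services) is affirmative; respondents answering no to the gate get
    0 regardless of source columns.
    """

    kind: str  # "any" | "formal"
    gate: str
    sources: tuple = ()

    def __post_init__(self):
        if self.kind not in ("any", "formal"):
            raise ValueError(f"unknown outcome rule kind {self.kind!r}")
        if self.kind == "formal" and not self.sources:
            raise ValueError("formal outcome rule requires source indicators")


def _as_binary(series: pd.Series, name: str) -> np.ndarray:
    out = np.zeros(len(series), dtype=np.int64)
    for i, v in enumerate(series):
        key = v.strip().lower() if isinstance(v, str) else v
        if key in YES_VALUES:
            out[i] = 1
        elif key in NO_VALUES or pd.isna(v):
            out[i] = 0
        else:
            raise ValueError(f"column {name!r}: cannot coerce {v!r} to yes/no")
    return out


def load_metadata(path) -> dict:
    """Load a YAML variable-metadata file into ``{name: VariableMeta}``.

    The file is a list of mappings with keys name, kind, and optionally
    categories, construct_id, excluded, exclusion_reason, canonical.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("metadata file must be a list of variable entries")
    meta = {}
    for e in entries:
        m = VariableMeta(
            name=e["name"],
            kind=e["kind"],
            categories=[str(c) for c in e.get("categories", [])],
            construct_id=e.get("construct_id"),
            excluded=bool(e.get("excluded", False)),
            exclusion_reason=e.get("exclusion_reason", ""),
            canonical=bool(e.get("canonical", False)),
        )
        if m.name in meta:
            raise ValueError(f"duplicate variable name in metadata: {m.name!r}")
        meta[m.name] = m
    return meta


def read_table(
    path,
    meta_path,
    outcome: str,
    weight: str,
    delimiter: str = ",",
) -> RawDataset:
    """Read a delimited survey table, typing columns per the metadata file.

    Every data column must appear in the metadata and vice versa; the outcome
    and weight columns must be present.  Continuous columns are coerced to
    numeric (non-numeric values are fatal, naming the column).
    """
    meta = load_metadata(meta_path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    cols = list(df.columns)

    extra = sorted(set(cols) - set(meta))
    if extra:
        raise ValueError(f"columns absent from metadata: {extra}")
    missing = sorted(set(meta) - set(cols))
    if missing:
        raise ValueError(f"metadata variables absent from table: {missing}")
    for required, label in ((outcome, "outcome"), (weight, "weight")):
        if required not in cols:
            raise ValueError(f"{label} column {required!r} not found in table")

    for name, m in meta.items():
        if m.kind == "continuous" or name == weight:
            coerced = pd.to_numeric(df[name], errors="coerce")
            bad = df[name].notna() & coerced.isna()
            if bad.any():
                raise ValueError(
                    f"column {name!r} is declared continuous but holds "
                    f"non-numeric values, e.g. {df.loc[bad, name].iloc[0]!r}"
                )
            df[name] = coerced

    w = df[weight].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError(f"weight column {weight!r} must be strictly positive")

    return RawDataset(df=df, outcome_name=outcome, weight_name=weight, meta=meta)


def construct_outcome(raw: RawDataset, rule: OutcomeRule) -> RawDataset:
    """Build the 0/1 outcome column from the gate (and source) questions.

    Returns a new dataset whose outcome column is binary; the original gate
    and source columns are removed from the covariate pool (they define the
    outcome and must not predict it).
    """
    df = raw.df.copy()
    if rule.gate not in df.columns:
        raise ValueError(f"gate question {rule.gate!r} not found")
    gate = _as_binary(df[rule.gate], rule.gate)
    if rule.kind == "any":
        y = gate
        used = [rule.gate]
    else:
        absent = [s for s in rule.sources if s not in df.columns]
        if absent:
            raise ValueError(f"source indicators not found: {absent}")
        src = np.zeros(len(df), dtype=np.int64)
        for s in rule.sources:
            src |= _as_binary(df[s], s)
        y = gate & src
        used = [rule.gate, *rule.sources]

    df[raw.outcome_name] = y
    drop = [c for c in used if c != raw.outcome_name]
    df = df.drop(columns=drop)
    meta = {k: v for k, v in raw.meta.items() if k not in drop}
    meta[raw.outcome_name] = VariableMeta(raw.outcome_name, "binary")
    return RawDataset(df, raw.outcome_name, raw.weight_name, meta)


def screen_variables(raw: RawDataset) -> RawDataset:
    """Drop excluded variables and de-duplicate construct groups.

    Within each ``construct_id`` group all but the canonical variable are
    dropped, mirroring the manual review step in which multiple recodes of
    the same construct (several age codings, say) are collapsed to one.
    The outcome and weight columns are never dropped.
    """
    protected = {raw.outcome_name, raw.weight_name}
    drop = set()
    for name, m in raw.meta.items():
        if name in protected or name not in raw.df.columns:
            continue
        if m.excluded:
            drop.add(name)

    groups: dict = {}
    for name, m in raw.meta.items():
        if (
            m.construct_id is not None
            and name not in drop
            and name not in protected
            and name in raw.df.columns
        ):
            groups.setdefault(m.construct_id, []).append(name)
    for cid, members in groups.items():
        if len(members) == 1:
            continue
        canon = [n for n in members if raw.meta[n].canonical]
        if not canon:
            raise ValueError(
                f"construct group {cid!r} has no canonical member among {members}"
            )
        drop.update(n for n in members if n not in canon[:1])

    df = raw.df.drop(columns=sorted(drop))
    meta = {k: v for k, v in raw.meta.items() if k not in drop}
    return RawDataset(df, raw.outcome_name, raw.weight_name, meta)


def _interval_labels(cuts) -> list:
    edges = [-np.inf, *cuts, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_s = "-inf" if np.isinf(lo) else f"{lo:g}"
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        labels.append(f"[{lo_s},{hi_s})")
    return labels


def discretize_continuous(raw: RawDataset, bins: dict) -> RawDataset:
    """Convert continuous variables into ordered categoricals by cut points.

    ``bins`` maps variable name -> strictly increasing cut points; a value v
    falls in the half-open interval [lo, hi).  The bins always cover the real
    line (outer intervals are unbounded).  An empty cut list yields a
    degenerate single-level categorical and a warning.  NaN stays missing and
    is resolved by the encoder.
    """
    df = raw.df.copy()
    meta = dict(raw.meta)
    for name, cuts in bins.items():
        if name not in df.columns:
            raise KeyError(f"unknown variable {name!r}")
        if meta[name].kind != "continuous":
            raise ValueError(f"variable {name!r} is not continuous")
        cuts = list(cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"non-increasing cuts for {name!r}: {cuts}")
        if not cuts:
            warnings.warn(
                f"empty cut list for {name!r}: degenerate single-level variable"
            )
            labels = ["all"]
            coded = pd.Series(
                np.where(df[name].isna(), None, "all"), index=df.index
            )
        else:
            labels = _interval_labels(cuts)
            idx = np.digitize(df[name].to_numpy(dtype=float), cuts, right=False)
            coded = pd.Series(
                [labels[i] if not np.isnan(v) else None
                 for i, v in zip(idx, df[name].to_numpy(dtype=float))],
                index=df.index,
            )
        df[name] = coded
        if len(labels) >= 2:
            meta[name] = replace(
                meta[name], kind="categorical", categories=labels
            )
        else:
            # degenerate single-level result: bypass the >=2-level invariant,
            # the encoder will drop the variable with its own warning
            m = VariableMeta.__new__(VariableMeta)
            m.__dict__.update(meta[name].__dict__)
            m.kind = "categorical"
            m.categories = labels
            meta[name] = m
    return RawDataset(df, raw.outcome_name, raw.weight_name, meta)


def one_hot_encode(
    raw: RawDataset,
    drop_reference: bool = True,
    missing_indicator: bool = True,
) -> EncodedDataset:
    """One-hot encode all covariates into an :class:`EncodedDataset`.

    A k-level variable contributes k-1 indicator columns (first metadata
    level is the reference) unless ``drop_reference`` is off, in which case
    all k levels get columns.  Missing values yield an all-zero block plus,
    when ``missing_indicator`` is on and missingness occurs, an explicit
    ``variable=<missing>`` column — this preserves n in the face of survey
    skip patterns.  Single-level variables are dropped with a warning.
    """
    cols = []
    names = []
    for name in raw.covariate_names():
        m = raw.meta.get(name)
        if m is None:
            raise KeyError(f"variable {name!r} missing from metadata")
        if m.kind == "continuous":
            raise ValueError(
                f"continuous variable {name!r} must be discretized before encoding"
            )
        levels = [str(c) for c in m.categories]
        series = raw.df[name]
        observed = series.dropna().astype(str)
        unknown = sorted(set(observed.unique()) - set(levels))
        if unknown:
            raise ValueError(
                f"variable {name!r} holds values outside its declared "
                f"categories: {unknown}"
            )
        if len(levels) < 2:
            warnings.warn(f"single-level variable {name!r} dropped")
            continue
        as_str = series.astype("string")
        start = 1 if drop_reference else 0
        for lev in levels[start:]:
            cols.append((as_str == lev).fillna(False).to_numpy(dtype=float))
            names.append(f"{name}={lev}")
        if missing_indicator and series.isna().any():
            cols.append(series.isna().to_numpy(dtype=float))
            names.append(f"{name}=<missing>")

    if not cols:
        raise ValueError("no encodable covariates")
    X = np.column_stack(cols)
    y = raw.df[raw.outcome_name].to_numpy(dtype=np.int64)
    w = raw.df[raw.weight_name].to_numpy(dtype=np.float64)
    return EncodedDataset(X=X, y=y, w=w, colnames=names)


def split_train_test(
    ds: EncodedDataset,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
):
    """Split into disjoint, exhaustive train/test partitions.

    ``ratio`` is the training fraction (the survey-analysis convention here
    is 80:20).  Stratified splitting preserves the positive-class proportion
    within one respondent per stratum — essential at 1% prevalence, where a
    plain random 20% test set can easily lose every positive case.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if ds.n < 10:
        raise ValueError("need at least 10 rows to split")
    idx = np.arange(ds.n)
    tr, te = train_test_split(
        idx,
        train_size=ratio,
        random_state=seed,
        shuffle=True,
        stratify=ds.y if stratified else None,
    )
    tr.sort()
    te.sort()
    train, test = ds.take_rows(tr), ds.take_rows(te)
    for part, label in ((train, "training"), (test, "test")):
        if part.y.sum() == 0:
            raise ValueError(
                f"{label} split contains zero positive cases; "
                "enable stratified splitting"
            )
    return train, test
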