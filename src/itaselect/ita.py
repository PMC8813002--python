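"""The iterative thematic analysis (ITA) loop.

One round: fit a CV-tuned lasso on the training rows (the noise filter),
drop every variable whose lasso coefficient is zero, refit a CV-tuned ridge
on the survivors (the ranking model), sort the ridge coefficients and take
the variables above the knee of the magnitude curve, have a coder group
them into themes, and identify the theme holding the top-coefficient
variable.  Between rounds that theme's selected variables are removed from
both partitions and the procedure repeats, stopping when no new themes
appear for three consecutive rounds, when a round contributes no new
variables, or at a safety cap on rounds.  Every round's ridge model is
scored (AUC, BER) on a test partition fixed before round one and never seen
by any fit or lambda selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import EncodedDataset, split_train_test
from .penalized import PenalizedFit, PenalizedLogit, PenalizedLogitCV
from .knee import KneeSelection, knee_selection
from .themes import ThemeAssignment, max_coefficient_theme, UNCATEGORIZED, _norm
from .metrics import ClassificationMetrics, evaluate, prevalence_threshold

__all__ = [
    "ITAConfig",
    "ITARoundRecord",
    "ITAResult",
    "run_round",
    "drop_theme",
    "check_stop",
    "run_ita",
    "IterativeThematicAnalysis",
]

STOP_NO_NEW_THEMES = "no_new_themes_3_rounds"
STOP_NO_NEW_VARIABLES = "no_new_variables"
STOP_MAX_ROUNDS = "max_rounds"
STOP_DEGENERATE = "degenerate_selection"


@dataclass
class ITAConfig:
    """Tuning knobs of the loop; defaults follow the study's choices.

    80:20 train/test split, k = 5 cross-validation folds, Kneedle
    sensitivity 1, magnitude sorting, lasso zero tolerance 1e-8 on the
    standardized scale, at most 10 rounds.  ``reselect_lambda`` re-tunes
    lambda by CV every round (the variable set changes); turning it off
    reuses round 1's choices.
    """

    test_ratio: float = 0.2
    stratified: bool = True
    k: int = 5
    n_lambdas: int = 50
    lam_min_ratio: float = 1e-4
    knee_sensitivity: float = 1.0
    sort_mode: str = "absolute"
    zero_tol: float = 1e-8
    max_rounds: int = 10
    seed: int = 0
    ber_threshold: float = 0.5
    weighted_metrics: bool = False
    reselect_lambda: bool = True
    resplit_per_round: bool = False

    def fold_seed(self, round: int) -> int:
        return (self.seed * 1009 + round) % (2**31)


@dataclass
class ITARoundRecord:
    """Full audit trail of one round."""

    round: int
    input_vars: list
    lasso_fit: PenalizedFit | None
    lasso_lam: float | None
    survivors: list
    ridge_fit: PenalizedFit | None
    ridge_lam: float | None
    selection: KneeSelection | None
    assignment: ThemeAssignment | None
    new_themes: list
    new_vars: list
    dropped_theme: str | None
    dropped_vars: list
    metrics: ClassificationMetrics | None
    metrics_prev_threshold: ClassificationMetrics | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "n_input_vars": len(self.input_vars),
            "input_vars": list(self.input_vars),
            "lasso_lam": self.lasso_lam,
            "lasso_n_nonzero": (self.lasso_fit.n_nonzero
                                if self.lasso_fit else None),
            "survivors": list(self.survivors),
            "ridge_lam": self.ridge_lam,
            "selection": (self.selection.to_dict() if self.selection else None),
            "assignment": (dict(self.assignment.mapping)
                           if self.assignment else None),
            "new_themes": list(self.new_themes),
            "new_vars": list(self.new_vars),
            "dropped_theme": self.dropped_theme,
            "dropped_vars": list(self.dropped_vars),
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "metrics_prev_threshold": (
                self.metrics_prev_threshold.to_dict()
                if self.metrics_prev_threshold else None),
            "degenerate": self.degenerate,
        }


@dataclass
class ITAResult:
    """All rounds plus the reason the loop stopped."""

    rounds: list
    all_themes: list
    stop_reason: str
    config: ITAConfig = field(default_factory=ITAConfig)

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "stop_reason": self.stop_reason,
            "all_themes": list(self.all_themes),
            "rounds": [r.to_dict() for r in self.rounds],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def selected_union(self) -> list:
        """Union of all rounds' selections, in first-selection order."""
        seen, out = set(), []
        for r in self.rounds:
            if r.selection is None:
                continue
            for v in r.selection.selected:
                if v not in seen:
                    seen.add(v)
                    out.append(v)
        return out


def drop_theme(ds: EncodedDataset, dropped_vars) -> EncodedDataset:
    """Remove a dropped theme's variables from the dataset (n unchanged)."""
    dropped_vars = list(dropped_vars)
    if not dropped_vars:
        return ds
    return ds.drop_columns(dropped_vars)


def check_stop(rounds, max_rounds: int):
    """Stopping rule; returns a stop reason or None to continue.

    Fires when the three most recent rounds each contributed zero new
    themes, when the most recent round contributed zero new variables, or
    at the round cap.
    """
    if not rounds:
        raise ValueError("need at least one completed round")
    if len(rounds) >= 3 and all(not r.new_themes for r in rounds[-3:]):
        return STOP_NO_NEW_THEMES
    if not rounds[-1].new_vars:
        return STOP_NO_NEW_VARIABLES
    if len(rounds) >= max_rounds:
        return STOP_MAX_ROUNDS
    return None


def _degenerate_record(round_no, train, lasso_fit, lasso_lam, survivors,
                       ridge_fit=None, ridge_lam=None, selection=None,
                       metrics=None, metrics_prev=None):
    return ITARoundRecord(
        round=round_no, input_vars=list(train.colnames),
        lasso_fit=lasso_fit, lasso_lam=lasso_lam, survivors=list(survivors),
        ridge_fit=ridge_fit, ridge_lam=ridge_lam, selection=selection,
        assignment=None, new_themes=[], new_vars=[], dropped_theme=None,
        dropped_vars=[], metrics=metrics, metrics_prev_threshold=metrics_prev,
        degenerate=True,
    )


def _cv_fit(train, penalty, config, round_no, fixed_lam=None):
    """CV-tuned (or fixed-lambda) penalized fit on the training partition."""
    if fixed_lam is not None:
        est = PenalizedLogit(penalty=penalty, lam=fixed_lam)
        est.fit(train.X, train.y, sample_weight=train.w)
        return est, float(fixed_lam)
    est = PenalizedLogitCV(
        penalty=penalty, n_lambdas=config.n_lambdas,
        lam_min_ratio=config.lam_min_ratio, k=config.k,
        seed=config.fold_seed(round_no),
    )
    est.fit(train.X, train.y, sample_weight=train.w)
    return est, float(est.best_lam_)


def run_round(train: EncodedDataset, test: EncodedDataset, config: ITAConfig,
              coder, round_no: int = 1, seen_themes=(), seen_vars=(),
              lasso_lam=None, ridge_lam=None) -> ITARoundRecord:
    """Execute one ITA round on a fixed train/test partition."""
    if train.y.sum() == 0 or (train.y == 0).sum() == 0:
        raise ValueError("training partition must contain both classes")

    lasso, llam = _cv_fit(train, "l1", config, round_no, lasso_lam)
    lasso_fit = lasso.as_fit(train.colnames) if hasattr(lasso, "as_fit") \
        else lasso.best_estimator_.as_fit(train.colnames)
    survivors = [n for n, t in zip(train.colnames, lasso_fit.theta_std)
                 if abs(t) > config.zero_tol]
    if len(survivors) < 3:
        # too few survivors to define a coefficient curve, let alone a knee
        return _degenerate_record(round_no, train, lasso_fit, llam, survivors)

    train_s = train.select_columns(survivors)
    test_s = test.select_columns(survivors)
    ridge, rlam = _cv_fit(train_s, "l2", config, round_no, ridge_lam)
    ridge_fit = ridge.as_fit(survivors) if hasattr(ridge, "as_fit") \
        else ridge.best_estimator_.as_fit(survivors)

    p_test = (ridge.predict_proba(test_s.X)[:, 1]
              if hasattr(ridge, "predict_proba") else None)
    metrics = evaluate(test_s.y, p_test, w=test_s.w,
                       threshold=config.ber_threshold,
                       weighted=config.weighted_metrics)
    prev_thr = prevalence_threshold(train_s.y, train_s.w)
    metrics_prev = evaluate(test_s.y, p_test, w=test_s.w,
                            threshold=prev_thr,
                            weighted=config.weighted_metrics)

    selection = knee_selection(ridge_fit, sensitivity=config.knee_sensitivity,
                               mode=config.sort_mode)
    if not selection.selected:
        return _degenerate_record(
            round_no, train, lasso_fit, llam, survivors, ridge_fit, rlam,
            selection, metrics, metrics_prev,
        )

    assignment = coder(round_no, selection)
    dropped_theme = max_coefficient_theme(assignment, selection)
    dropped_vars = [v for v in selection.selected
                    if _norm(assignment.mapping[v]) == _norm(dropped_theme)]

    seen_t = {_norm(t) for t in seen_themes}
    new_themes = [t for t in assignment.themes()
                  if _norm(t) not in seen_t and _norm(t) != _norm(UNCATEGORIZED)]
    new_vars = [v for v in selection.selected if v not in set(seen_vars)]

    return ITARoundRecord(
        round=round_no, input_vars=list(train.colnames),
        lasso_fit=lasso_fit, lasso_lam=llam, survivors=survivors,
        ridge_fit=ridge_fit, ridge_lam=rlam, selection=selection,
        assignment=assignment, new_themes=new_themes, new_vars=new_vars,
        dropped_theme=dropped_theme, dropped_vars=dropped_vars,
        metrics=metrics, metrics_prev_threshold=metrics_prev,
    )


def run_ita(ds: EncodedDataset, config: ITAConfig, coder) -> ITAResult:
    """Run the full loop on one encoded dataset.

    The 80:20 split happens once, before round one; each round's metrics
    are computed on that same held-out test set, with dropped columns
    removed from it symmetrically.  With ``resplit_per_round`` on, the
    split is redrawn each round from a round-indexed seed instead.
    """
    train, test = split_train_test(
        ds, ratio=1.0 - config.test_ratio, seed=config.seed,
        stratified=config.stratified,
    )
    rounds: list = []
    seen_themes: list = []
    seen_vars: list = []
    lasso_lam = ridge_lam = None
    stop = None
    for round_no in range(1, config.max_rounds + 1):
        if config.resplit_per_round and round_no > 1:
            # redraw the partition while keeping the dropped-column state
            merged = EncodedDataset(
                np.vstack([train.X, test.X]),
                np.concatenate([train.y, test.y]),
                np.concatenate([train.w, test.w]),
                train.colnames,
            )
            train, test = split_train_test(
                merged, ratio=1.0 - config.test_ratio,
                seed=config.fold_seed(round_no), stratified=config.stratified,
            )
        rec = run_round(
            train, test, config, coder, round_no=round_no,
            seen_themes=seen_themes, seen_vars=seen_vars,
            lasso_lam=lasso_lam, ridge_lam=ridge_lam,
        )
        rounds.append(rec)
        if rec.degenerate:
            stop = STOP_DEGENERATE
            break
        for t in rec.new_themes:
            seen_themes.append(t)
        seen_vars.extend(rec.new_vars)
        if not config.reselect_lambda:
            lasso_lam, ridge_lam = rec.lasso_lam, rec.ridge_lam
        stop = check_stop(rounds, config.max_rounds)
        if stop is not None:
            break
        if len(rec.dropped_vars) >= train.p:
            stop = STOP_DEGENERATE
            break
        train = drop_theme(train, rec.dropped_vars)
        test = drop_theme(test, rec.dropped_vars)
    if stop is None:  # loop exhausted without an explicit reason
        stop = STOP_MAX_ROUNDS
    return ITAResult(rounds=rounds, all_themes=list(seen_themes),
                     stop_reason=stop, config=config)


class IterativeThematicAnalysis(BaseEstimator):
    """scikit-learn style wrapper around the ITA loop.

    Parameters mirror :class:`ITAConfig`; ``coder`` is any callable
    ``(round, KneeSelection) -> ThemeAssignment`` (see
    :class:`~itaselect.themes.TruthCoder` and
    :class:`~itaselect.themes.FileCoder`).

    After ``fit(X, y, sample_weight=..., feature_names=...)``:

    - ``result_`` — the full :class:`ITAResult` audit trail
    - ``themes_`` — cumulative theme labels in discovery order
    - ``selected_vars_`` — union of all rounds' selections
    - ``stop_reason_`` — why the loop ended
    """

    def __init__(self, coder=None, test_ratio=0.2, stratified=True, k=5,
                 n_lambdas=50, lam_min_ratio=1e-4, knee_sensitivity=1.0,
                 sort_mode="absolute", zero_tol=1e-8, max_rounds=10, seed=0,
                 ber_threshold=0.5, weighted_metrics=False,
                 reselect_lambda=True, resplit_per_round=False):
        self.coder = coder
        self.test_ratio = test_ratio
        self.stratified = stratified
        self.k = k
        self.n_lambdas = n_lambdas
        self.lam_min_ratio = lam_min_ratio
        self.knee_sensitivity = knee_sensitivity
        self.sort_mode = sort_mode
        self.zero_tol = zero_tol
        self.max_rounds = max_rounds
        self.seed = seed
        self.ber_threshold = ber_threshold
        self.weighted_metrics = weighted_metrics
        self.reselect_lambda = reselect_lambda
        self.resplit_per_round = resplit_per_round

    def _config(self) -> ITAConfig:
        return ITAConfig(
            test_ratio=self.test_ratio, stratified=self.stratified, k=self.k,
            n_lambdas=self.n_lambdas, lam_min_ratio=self.lam_min_ratio,
            knee_sensitivity=self.knee_sensitivity, sort_mode=self.sort_mode,
            zero_tol=self.zero_tol, max_rounds=self.max_rounds, seed=self.seed,
            ber_threshold=self.ber_threshold,
            weighted_metrics=self.weighted_metrics,
            reselect_lambda=self.reselect_lambda,
            resplit_per_round=self.resplit_per_round,
        )

    def fit(self, X, y, sample_weight=None, feature_names=None):
        if self.coder is None:
            raise ValueError("a coder callable is required")
        X = np.asarray(X, dtype=float)
        names = (list(feature_names) if feature_names is not None
                 else [f"x{j}" for j in range(X.shape[1])])
        w = (np.ones(X.shape[0]) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        ds = EncodedDataset(X=X, y=np.asarray(y), w=w, colnames=names)
        self.result_ = run_ita(ds, self._config(), self.coder)
        self.themes_ = list(self.result_.all_themes)
        self.selected_vars_ = self.result_.selected_union()
        self.stop_reason_ = self.result_.stop_reason
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        """Boolean mask (or indices) over input features of the selected union."""
        sel = set(self.selected_vars_)
        mask = np.array([n in sel for n in self.feature_names_in_])
        return np.flatnonzero(mask) if indices else mask

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.get_support()]
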