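"""Minimal round-record stubs for exercising the stopping rules in isolation."""

from itaselect.ita import ITARoundRecord


def record_stub(round, new_themes, new_vars):
    return ITARoundRecord(
        round=round, input_vars=[], lasso_fit=None, lasso_lam=None,
        survivors=[], ridge_fit=None, ridge_lam=None, selection=None,
        assignment=None, new_themes=list(new_themes), new_vars=list(new_vars),
        dropped_theme=None, dropped_vars=[], metrics=None,
        metrics_prev_threshold=None,
    )
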