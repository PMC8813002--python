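"""Knee-point detection on sorted coefficient-magnitude curves.

After the ridge refit, coefficients are sorted from high to low and the
round's relevant variables are those above the knee — the point where the
curve "becomes flat".  The knee is located with the Kneedle algorithm:
min-max normalize the curve, form the difference curve between the
normalized values and the diagonal, and accept the first local maximum of
the difference curve whose lead over the subsequent points exceeds a
sensitivity-scaled threshold.  Implemented here for the decreasing convex
curves that sorted penalized-coefficient magnitudes produce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .penalized import PenalizedFit

__all__ = [
    "KneeSelection",
    "sort_coefficients",
    "kneedle",
    "select_above_knee",
    "knee_selection",
]


@dataclass
class KneeSelection:
    """Sorted magnitude curve, knee position, and the selected prefix."""

    sorted_names: list
    sorted_values: np.ndarray
    knee_index: int | None
    threshold: float | None
    selected: list
    sensitivity: float

    def to_dict(self) -> dict:
        return {
            "sorted_names": list(self.sorted_names),
            "sorted_values": [float(v) for v in self.sorted_values],
            "knee_index": self.knee_index,
            "threshold": self.threshold,
            "selected": list(self.selected),
            "sensitivity": self.sensitivity,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot(self, ax=None):
        """Optional diagnostic plot of the curve with the knee marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.sorted_values)), self.sorted_values, "-o",
                markersize=2)
        if self.knee_index is not None:
            ax.axvline(self.knee_index, color="red", linestyle="--",
                       label=f"knee @ {self.knee_index}")
            ax.legend()
        ax.set_xlabel("rank")
        ax.set_ylabel("coefficient magnitude")
        return ax


def sort_coefficients(fit: PenalizedFit, mode: str = "absolute"):
    """Sort coefficients from high to low on the standardized scale.

    ``absolute`` (default) ranks |theta_j|, so protective-direction items
    compete on equal footing; ``signed`` ranks raw theta_j.  The sort is
    stable: ties keep original column order.
    """
    if len(fit.theta_std) < 2:
        raise ValueError("need at least 2 coefficients to sort")
    if mode == "absolute":
        key = np.abs(fit.theta_std)
    elif mode == "signed":
        key = np.asarray(fit.theta_std, dtype=float)
    else:
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    order = np.argsort(-key, kind="stable")
    names = [fit.names[j] for j in order]
    return names, key[order]


def kneedle(values, sensitivity: float = 1.0) -> int | None:
    """Locate the knee of a non-increasing curve; None when no knee exists.

    The curve is min-max normalized to the unit square with x the rank
    fraction; for a decreasing curve the difference curve is
    d_i = (1 - y_i) - x_i.  Candidate knees are the local maxima of d; a
    candidate at position m is accepted once some later point (before the
    next local maximum) falls below d_m - S * mean(dx), S being the
    sensitivity.  The first accepted candidate is returned.  Normalization
    makes the result invariant to affine rescaling of the values.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points for knee detection")
    if np.any(np.diff(y) > 1e-12 * max(1.0, np.abs(y).max())):
        raise ValueError("values must be non-increasing")
    span = y[0] - y[-1]
    if span <= 0:
        return None  # flat curve: no knee
    x = np.linspace(0.0, 1.0, n)
    ynorm = (y - y[-1]) / span
    d = (1.0 - ynorm) - x

    # local maxima / minima of the difference curve
    is_max = np.zeros(n, dtype=bool)
    is_min = np.zeros(n, dtype=bool)
    is_max[1:-1] = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:])
    is_min[1:-1] = (d[1:-1] <= d[:-2]) & (d[1:-1] < d[2:])

    dx = 1.0 / (n - 1)
    threshold = 0.0
    candidate = None
    for i in range(1, n):
        if is_max[i]:
            candidate = i
            threshold = d[i] - sensitivity * dx
            continue
        if candidate is None:
            continue
        if is_min[i]:
            candidate, threshold = None, 0.0
            continue
        if d[i] < threshold:
            return candidate
    return None


def select_above_knee(names, values, knee_index: int):
    """Names strictly above the knee: the prefix ``names[:knee_index]``."""
    if not 0 <= knee_index < len(names):
        raise IndexError(f"knee_index {knee_index} out of range")
    if knee_index == 0:
        warnings.warn("knee at position 0: empty selection")
    return list(names[:knee_index])


def knee_selection(fit: PenalizedFit, sensitivity: float = 1.0,
                   mode: str = "absolute") -> KneeSelection:
    """Sort a fit's coefficients, find the knee, and extract the selection.

    A curve with no knee (flat or linear descent) yields an empty selection
    with ``knee_index=None`` — the caller records the round as degenerate
    rather than selecting everything.
    """
    names, values = sort_coefficients(fit, mode=mode)
    if len(values) < 3:
        idx = None
    else:
        idx = kneedle(values, sensitivity=sensitivity)
    if idx is None:
        return KneeSelection(names, values, None, None, [], sensitivity)
    return KneeSelection(
        sorted_names=names,
        sorted_values=values,
        knee_index=idx,
        threshold=float(values[idx]),
        selected=select_above_knee(names, values, idx),
        sensitivity=sensitivity,
    )
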