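"""Prediction-error summaries and S-curves.

An S-curve is the cumulative plot of sorted absolute prediction errors:
the i-th smallest error is paired with percentile 100*i/n.  A model with a
few pathological conformations shows a sharp tail at the top right while
the bulk of the curve stays far left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErrorSummary", "s_curve", "summarize", "write_s_curve_csv",
           "write_summary_json"]


@dataclass
class ErrorSummary:
    """Min / max / mean of a set of absolute prediction errors (au)."""

    min: float
    max: float
    mean: float
    count: int

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError("min <= mean <= max violated")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _validated(errors) -> np.ndarray:
    e = np.asarray(errors, float).ravel()
    if e.size == 0:
        raise ValueError("empty error list")
    if np.any(e < 0):
        raise ValueError("absolute errors must be non-negative")
    return e


def s_curve(errors) -> np.ndarray:
    """(percentile, error) pairs of the sorted errors; percentile = 100*i/n."""
    e = np.sort(_validated(errors))
    pct = 100.0 * np.arange(1, e.size + 1) / e.size
    return np.column_stack([pct, e])


def summarize(errors) -> ErrorSummary:
    """Exact min, max and arithmetic mean of the absolute errors."""
    e = _validated(errors)
    return ErrorSummary(min=float(e.min()), max=float(e.max()),
                        mean=float(e.mean()), count=int(e.size))


def write_s_curve_csv(path, errors) -> None:
    pd.DataFrame(s_curve(errors),
                 columns=["percentile", "abs_error_au"]).to_csv(path,
                                                                index=False)


def write_summary_json(path, errors) -> None:
    s = summarize(errors)
    with open(path, "w") as fh:
        json.dump({"min": s.min, "max": s.max, "mean": s.mean,
                   "count": s.count}, fh, indent=1)
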