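"""Summary statistics from binned satellite-dive-recorder histograms.

Tags report dives in 10 depth bins and 10 duration bins per 6-hr interval;
per-dive values are unobserved. From the bin counts ``n_1..n_10`` (total
``N``) this module derives:

* mean depth/duration — count-weighted bin midpoints, ``sum(n_i m_i) / N``;
* max depth/duration — upper edge of the deepest/longest non-empty bin;
* dive focus — ``sum(n_i (n_i - 1)) / (N (N - 1))``, the probability that
  two dives drawn without replacement share a bin (finite-sample corrected;
  1 = all dives in one bin, 0 = maximal spread);
* focal depth — the dominant bin's midpoint, defined only when dive focus
  exceeds 0.50.

Undefined values (``N = 0``, or ``N < 2`` for the focus) propagate as NaN,
never as zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

FOCUS_THRESHOLD = 0.50


def _check_hist(counts, edges) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, float)
    edges = np.asarray(edges, float)
    if counts.shape != (10,):
        raise ValueError("histogram must have exactly 10 bins")
    if edges.shape != (11,) or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be 11 strictly increasing values")
    if np.any(counts < 0):
        raise ValueError("bin counts must be nonnegative")
    return counts, edges


def mean_from_bins(counts, edges) -> float:
    """Count-weighted mean of bin midpoints; NaN when the interval is empty."""
    counts, edges = _check_hist(counts, edges)
    n = counts.sum()
    if n < 1:
        return float("nan")
    mids = (edges[:-1] + edges[1:]) / 2.0
    return float((counts * mids).sum() / n)


def max_from_bins(counts, edges) -> float:
    """Upper edge of the last non-empty bin; NaN when the interval is empty."""
    counts, edges = _check_hist(counts, edges)
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        return float("nan")
    return float(edges[nz[-1] + 1])


def dive_focus(counts) -> float:
    """Same-bin probability for two dives drawn without replacement.

    ``sum(n_i (n_i - 1)) / (N (N - 1))``; NaN when ``N < 2`` (the correction
    divides by ``N - 1``).
    """
    counts = np.asarray(counts, float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    return float((counts * (counts - 1.0)).sum() / (n * (n - 1.0)))


def focal_depth(counts, edges):
    """Dominant bin when dive focus exceeds 0.50.

    Returns ``(midpoint, bin_index_1based, tied)``; ``(nan, None, False)``
    when the focus is undefined or does not exceed the threshold. Ties for
    the dominant bin resolve to the shallower bin and are flagged.
    """
    counts, edges = _check_hist(counts, edges)
    focus = dive_focus(counts)
    if not np.isfinite(focus) or focus <= FOCUS_THRESHOLD:
        return float("nan"), None, False
    top = int(np.argmax(counts))            # argmax takes the first == shallower
    tied = int((counts == counts[top]).sum()) > 1
    mid = float((edges[top] + edges[top + 1]) / 2.0)
    return mid, top + 1, tied


def summarize_histograms(hists: pd.DataFrame) -> pd.DataFrame:
    """Per-interval dive summaries from the long-format histogram table.

    Expects columns animal_id, interval_start, bin_type in {depth, duration},
    bin_index 1-10, bin_lower, bin_upper, count. Proportion-type rows (any
    ``bin_type`` other than depth/duration, e.g. time-at-depth) are ignored:
    the focus statistic is defined on dive counts. The dive focus and focal
    depth are computed from the depth histogram.
    """
    out = []
    for (animal, start), sub in hists.groupby(["animal_id", "interval_start"],
                                              sort=True):
        rec = {"animal_id": animal, "interval_start": start,
               "mean_depth": np.nan, "max_depth": np.nan,
               "mean_duration": np.nan, "max_duration": np.nan,
               "dive_focus": np.nan, "focal_depth": np.nan,
               "focal_bin": pd.NA, "focal_tied": False}
        for bin_type, hsub in sub.groupby("bin_type"):
            if bin_type not in ("depth", "duration"):
                continue
            hsub = hsub.sort_values("bin_index")
            counts = hsub["count"].to_numpy(float)
            edges = np.append(hsub["bin_lower"].to_numpy(float),
                              hsub["bin_upper"].to_numpy(float)[-1])
            rec[f"mean_{bin_type}"] = mean_from_bins(counts, edges)
            rec[f"max_{bin_type}"] = max_from_bins(counts, edges)
            if bin_type == "depth":
                rec["dive_focus"] = dive_focus(counts)
                mid, bin_ix, tied = focal_depth(counts, edges)
                rec["focal_depth"], rec["focal_bin"], rec["focal_tied"] = \
                    mid, bin_ix if bin_ix is not None else pd.NA, tied
        out.append(rec)
    return pd.DataFrame(out)


class DiveSummarizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer over :func:`summarize_histograms`."""

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return summarize_histograms(X)
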