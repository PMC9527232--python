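"""Saccade detection, early/visual cut-off estimation and trial-state labels.

A trial is *early* (``e``) when its saccade latency on the IS clock is at or
below the cut-off (170 ms by default, including saccades launched during the
foreperiod, i.e. negative latencies), *visual* (``v``) when above it, and
*failed* (``f``) when no latency was recorded or the latency is implausibly
late.  The cut-off can also be estimated from the data as the breakpoint of
a two-segment piecewise-linear fit to the cumulative latency count curve —
the point where the slow accumulation of early saccades gives way to the
steep rise of visually guided ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .trials import TrialTable

__all__ = [
    "CutoffResult",
    "BreakpointCutoff",
    "detect_saccades",
    "detect_cutoff",
    "label_states3",
    "response_percentages",
]


def detect_saccades(
    trace_deg: Sequence[float],
    sample_rate_hz: float,
    threshold_deg_s: float = 30.0,
    smooth_window: int = 5,
) -> np.ndarray:
    """Velocity-threshold saccade detection on a gaze-position trace.

    Position is smoothed with a ``smooth_window``-sample moving average,
    velocity estimated by central differences, and one onset is reported per
    supra-threshold episode (the first sample whose absolute velocity
    exceeds ``threshold_deg_s``).

    Parameters
    ----------
    trace_deg : uniformly sampled gaze position, degrees.
    sample_rate_hz : sampling rate, Hz.
    threshold_deg_s : velocity threshold, deg/s (default 30).
    smooth_window : odd moving-average width, samples.

    Returns
    -------
    ndarray of onset times, ms from trace start.
    """
    x = np.asarray(trace_deg, dtype=float)
    if threshold_deg_s <= 0:
        raise ValueError("threshold must be > 0")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if x.size < smooth_window + 2:
        raise ValueError("trace shorter than the smoothing window")
    kernel = np.ones(smooth_window) / smooth_window
    # reflect-pad so the smoothed trace has no edge shrinkage
    pad = smooth_window // 2
    xp = np.pad(x, pad, mode="edge")
    xs = np.convolve(xp, kernel, mode="valid")
    vel = np.gradient(xs) * sample_rate_hz  # deg/s, central differences
    above = np.abs(vel) > threshold_deg_s
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        onsets = np.union1d(onsets, [0])
    return onsets / sample_rate_hz * 1000.0


@dataclass
class CutoffResult:
    """An early/visual latency cut-off on the IS clock."""

    cutoff_ms: float
    method: str  # "fixed" or "breakpoint"
    sse: float = float("nan")
    n: int = 0
    slope_ratio: float = float("nan")
    fallback_reason: Optional[str] = None


class BreakpointCutoff(BaseEstimator):
    """Breakpoint estimator for the early/visual latency cut-off.

    Fits, on a latency grid, the two-segment continuous piecewise-linear
    model ``y = a + b1*x + b2*max(0, x - c)`` to the cumulative count curve
    ``y(x) = #{latency <= x}`` by exhaustive least squares over candidate
    breakpoints ``c`` (ties broken toward the smaller breakpoint).  When the
    sample is too small or the slope contrast between the two segments is
    too weak (a unimodal, visual-only sample), the estimator falls back to
    the configured fixed cut-off.

    Parameters
    ----------
    search_range : (low, high) ms on the IS clock; candidate breakpoints are
        restricted to this interval.
    grid_ms : grid step for both the curve and the candidate breakpoints.
    min_n : minimum sample size for detection (default 50).
    min_slope_ratio : minimum right/left slope ratio to accept a breakpoint.
    fixed_cutoff_ms : fallback value.

    Attributes
    ----------
    result_ : CutoffResult
    cutoff_ms_ : float
    """

    def __init__(
        self,
        search_range: tuple = (0.0, 400.0),
        grid_ms: float = 1.0,
        min_n: int = 50,
        min_slope_ratio: float = 2.0,
        fixed_cutoff_ms: float = 170.0,
    ):
        self.search_range = search_range
        self.grid_ms = grid_ms
        self.min_n = min_n
        self.min_slope_ratio = min_slope_ratio
        self.fixed_cutoff_ms = fixed_cutoff_ms

    def fit(self, X, y=None):
        lat = np.asarray(X, dtype=float).ravel()
        lat = lat[~np.isnan(lat)]
        n = lat.size
        if n < self.min_n:
            self.result_ = CutoffResult(
                self.fixed_cutoff_ms, "fixed", n=n, fallback_reason="too few latencies"
            )
            self.cutoff_ms_ = self.result_.cutoff_ms
            return self
        lo, hi = self.search_range
        grid = np.arange(lo, hi + self.grid_ms / 2, self.grid_ms)
        ycum = np.searchsorted(np.sort(lat), grid, side="right").astype(float)
        best = None
        for c in grid[1:-1]:
            hinge = np.maximum(0.0, grid - c)
            A = np.column_stack([np.ones_like(grid), grid, hinge])
            coef, *_ = np.linalg.lstsq(A, ycum, rcond=None)
            resid = ycum - A @ coef
            sse = float(resid @ resid)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, float(c), coef)
        sse, c, coef = best
        b1, b2 = coef[1], coef[1] + coef[2]
        ratio = np.inf if abs(b1) < 1e-12 else b2 / b1
        if not np.isfinite(ratio) or ratio < self.min_slope_ratio:
            self.result_ = CutoffResult(
                self.fixed_cutoff_ms,
                "fixed",
                sse=sse,
                n=n,
                slope_ratio=float(ratio) if np.isfinite(ratio) else float("inf"),
                fallback_reason="low breakpoint contrast",
            )
        else:
            self.result_ = CutoffResult(c, "breakpoint", sse=sse, n=n, slope_ratio=float(ratio))
        self.cutoff_ms_ = self.result_.cutoff_ms
        return self


def detect_cutoff(
    latencies_is: Sequence[float],
    search_range: tuple = (0.0, 400.0),
    grid_ms: float = 1.0,
    fixed_cutoff_ms: float = 170.0,
    min_n: int = 50,
) -> CutoffResult:
    """Estimate the early/visual cut-off; see :class:`BreakpointCutoff`."""
    est = BreakpointCutoff(
        search_range=search_range,
        grid_ms=grid_ms,
        min_n=min_n,
        fixed_cutoff_ms=fixed_cutoff_ms,
    ).fit(latencies_is)
    return est.result_


def label_states3(
    table: TrialTable,
    cutoff_ms: float = 170.0,
    max_visual_latency_ms: float = 1000.0,
) -> TrialTable:
    """Label every trial ``e``/``v``/``f`` from its IS-clock latency.

    ``lat_is_ms <= cutoff_ms`` (including negative latencies) is early;
    ``cutoff_ms < lat_is_ms <= max_visual_latency_ms`` is visual; anything
    else — no latency, or an implausibly late saccade — is failed.
    Idempotent: relabeling a labeled table gives the same labels.
    """
    out = table.copy()
    lat = out.data["lat_is_ms"].to_numpy(dtype=float)
    state = np.where(
        np.isnan(lat),
        "f",
        np.where(lat <= cutoff_ms, "e", np.where(lat <= max_visual_latency_ms, "v", "f")),
    )
    out.data["state3"] = state
    # a relabeled late-visual trial loses its latency interpretation; its
    # state4, if any, is reset for non-early trials to stay consistent
    s4 = out.data["state4"].astype(object)
    s4[state == "v"] = "v"
    s4[state == "f"] = "f"
    out.data["state4"] = s4
    return out


def response_percentages(table: TrialTable) -> pd.DataFrame:
    """Per-cell response-type percentages, subject-first.

    For every (group, medication, condition) cell, each subject's percentage
    of failed / visual / early trials is computed over that subject's trials
    in the cell; the table reports the across-subject mean and standard
    error (n-1 sample SD / sqrt(n_subjects)) plus total trial counts per
    category.
    """
    df = table.data
    if df["state3"].isna().any():
        raise ValueError("state3 labels missing; run label_states3 first")
    rows = []
    for (group, med, cond), cell in df.groupby(["group", "medication", "condition"], sort=True):
        per_subj = (
            cell.groupby("subject_id")["state3"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=["f", "v", "e"], fill_value=0.0)
            * 100.0
        )
        n_subj = len(per_subj)
        if n_subj == 0:
            raise ValueError(f"cell {(group, med, cond)} has zero subjects")
        counts = cell["state3"].value_counts()
        rec = {"group": group, "medication": med, "condition": cond, "n_subjects": n_subj}
        for label, name in (("f", "failed"), ("v", "visual"), ("e", "early")):
            vals = per_subj[label].to_numpy()
            rec[f"{name}_pct_mean"] = vals.mean()
            rec[f"{name}_pct_se"] = (
                vals.std(ddof=1) / np.sqrt(n_subj) if n_subj > 1 else float("nan")
            )
            rec[f"{name}_n"] = int(counts.get(label, 0))
        rows.append(rec)
    return pd.DataFrame(rows)
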