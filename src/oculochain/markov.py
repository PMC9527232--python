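"""Observable Markov-chain analysis of trial-state sequences.

Within a block of trials the per-trial states (3-state alphabet ``e/v/f``
or, in the explicit condition, 4-state ``first/second/v/f``) form a
sequence; the working hypothesis is a first-order chain,

    P(S_{n+1} | S_n, S_{n-1}, ...) = P(S_{n+1} | S_n).

This module builds the sequences (never spanning subjects or blocks), tests
the first-order property with a triplet chi-square, estimates transition
matrices by maximum likelihood with per-cell confidence intervals, and
provides the row-uniformity chi-square and the confidence-interval test of
a difference between two transition probabilities (with an optional
Bonferroni correction), used at the study-wide alpha of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .trials import STATES3, STATES4, TrialTable

__all__ = [
    "StateSequence",
    "TransitionMatrix",
    "MarkovPropertyResult",
    "ProbComparison",
    "TransitionMatrixEstimator",
    "build_sequences",
    "verify_markov_property",
    "fit_transition_matrix",
    "row_uniformity_test",
    "compare_probabilities",
    "screen_markov_subjects",
]


@dataclass
class StateSequence:
    """One subject x condition x block run of trial states, in trial order."""

    subject_id: str
    condition: str
    block: int
    states: list

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class TransitionMatrix:
    """MLE transition matrix with per-cell confidence intervals.

    Rows whose state was never visited carry NaN probabilities (never 0).
    """

    states: tuple
    counts: np.ndarray
    probs: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_row: np.ndarray
    ci_level: float

    def to_dict(self) -> dict:
        def nanlist(a):
            return [[None if np.isnan(v) else float(v) for v in row] for row in np.asarray(a)]

        return {
            "states": list(self.states),
            "counts": np.asarray(self.counts).astype(int).tolist(),
            "probs": nanlist(self.probs),
            "ci_low": nanlist(self.ci_low),
            "ci_high": nanlist(self.ci_high),
            "n_row": np.asarray(self.n_row).astype(int).tolist(),
            "ci_level": self.ci_level,
        }


@dataclass
class MarkovPropertyResult:
    statistic: float
    df: int
    p_value: float
    passed: bool
    alpha: float
    n_triplets: int = 0


@dataclass
class ProbComparison:
    """Confidence-interval test of p1 - p2 at level 1 - alpha/m."""

    diff: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    significant: bool


def build_sequences(table: TrialTable, alphabet: str = "three") -> list:
    """One StateSequence per subject x condition x block, in trial order.

    Transitions never span subjects or blocks: downstream pair counting only
    looks at adjacent positions *within* a returned sequence.
    """
    if alphabet == "three":
        col, allowed = "state3", STATES3
    elif alphabet == "four":
        col, allowed = "state4", STATES4
    else:
        raise ValueError("alphabet must be 'three' or 'four'")
    df = table.data
    if df[col].isna().any():
        raise ValueError(f"{col} labels missing; label the table first")
    bad = ~df[col].isin(allowed)
    if bad.any():
        raise ValueError(f"invalid {col} label(s): {sorted(df.loc[bad, col].unique())}")
    seqs = []
    for (sid, cond, block), sub in df.groupby(
        ["subject_id", "condition", "block"], sort=False
    ):
        sub = sub.sort_values("trial_index")
        seqs.append(StateSequence(sid, cond, int(block), sub[col].tolist()))
    return seqs


def _coded(seqs: Sequence[StateSequence], states: tuple) -> list:
    index = {s: i for i, s in enumerate(states)}
    return [np.array([index[s] for s in seq.states], dtype=np.intp) for seq in seqs]


def _alphabet_of(seqs: Sequence[StateSequence]) -> tuple:
    observed = set()
    for seq in seqs:
        observed.update(seq.states)
    for candidate in (STATES3, STATES4):
        if observed <= set(candidate):
            return candidate
    raise ValueError(f"states {sorted(observed)} fit neither alphabet")


def verify_markov_property(
    seqs: Union[StateSequence, Sequence[StateSequence]],
    alpha: float = 0.05,
    min_length: int = 50,
) -> MarkovPropertyResult:
    """Triplet chi-square test of the first-order Markov property.

    For each state ``s``, the triplets (prev, s, next) define a contingency
    table of the state before versus the state after; under a first-order
    chain these are independent given the middle state.  Pearson chi-square
    statistics are summed over middle states (degrees of freedom summed,
    rows/columns with zero margin dropped), and the total is referred to the
    chi-square distribution.  ``passed`` means p > alpha (no evidence
    against the property).
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    total_len = sum(len(s) for s in seqs)
    if total_len < min_length:
        raise ValueError(f"sequences too short: {total_len} states < {min_length}")
    states = _alphabet_of(seqs)
    k = len(states)
    coded = _coded(seqs, states)
    triplet_counts = np.zeros((k, k, k))
    for x in coded:
        if x.size < 3:
            continue
        np.add.at(triplet_counts, (x[:-2], x[1:-1], x[2:]), 1)
    stat = 0.0
    df = 0
    n_triplets = int(triplet_counts.sum())
    for mid in range(k):
        tab = triplet_counts[:, mid, :]
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue  # stratum uninformative; df adjusted by skipping
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        stat += float(((tab - expected) ** 2 / expected).sum())
        df += (tab.shape[0] - 1) * (tab.shape[1] - 1)
    if df == 0:
        raise ValueError("no informative strata for the Markov property test")
    p = float(stats.chi2.sf(stat, df))
    return MarkovPropertyResult(stat, df, p, passed=p > alpha, alpha=alpha, n_triplets=n_triplets)


class TransitionMatrixEstimator(BaseEstimator):
    """MLE transition-matrix estimator over pooled state sequences.

    Counts within-sequence adjacent pairs only (no transition across
    sequence boundaries), estimates p_ij = n_ij / n_i, and attaches
    per-cell Wald intervals ``p +/- z sqrt(p(1-p)/n_i)`` clipped to [0, 1]
    (Wilson score intervals behind ``ci_method="wilson"``).

    Attributes (after fit): ``states_``, ``counts_``, ``probs_``,
    ``ci_low_``, ``ci_high_``, ``n_row_``, ``result_``.
    """

    def __init__(self, ci_level: float = 0.99, ci_method: str = "wald", states: tuple = None):
        self.ci_level = ci_level
        self.ci_method = ci_method
        self.states = states  # explicit alphabet; inferred when None

    def fit(self, X: Sequence[StateSequence], y=None):
        seqs = list(X)
        if not seqs:
            raise ValueError("no sequences to fit")
        states = tuple(self.states) if self.states is not None else _alphabet_of(seqs)
        k = len(states)
        counts = np.zeros((k, k))
        for x in _coded(seqs, states):
            if x.size >= 2:
                np.add.at(counts, (x[:-1], x[1:]), 1)
        n_row = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / n_row[:, None]
        probs[n_row == 0] = np.nan
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        if self.ci_method == "wald":
            with np.errstate(invalid="ignore", divide="ignore"):
                half = z * np.sqrt(probs * (1 - probs) / n_row[:, None])
            lo = np.clip(probs - half, 0.0, 1.0)
            hi = np.clip(probs + half, 0.0, 1.0)
        elif self.ci_method == "wilson":
            lo = np.full_like(probs, np.nan)
            hi = np.full_like(probs, np.nan)
            for i in range(k):
                if n_row[i] == 0:
                    continue
                for j in range(k):
                    lo[i, j], hi[i, j] = _wilson(counts[i, j], n_row[i], z)
        else:
            raise ValueError("ci_method must be 'wald' or 'wilson'")
        lo[np.isnan(probs)] = np.nan
        hi[np.isnan(probs)] = np.nan
        self.states_ = states
        self.counts_ = counts.astype(int)
        self.probs_ = probs
        self.ci_low_ = lo
        self.ci_high_ = hi
        self.n_row_ = n_row.astype(int)
        self.result_ = TransitionMatrix(
            states, self.counts_, probs, lo, hi, self.n_row_, self.ci_level
        )
        return self


def _wilson(x: float, n: float, z: float) -> tuple:
    p = x / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def fit_transition_matrix(
    seqs: Sequence[StateSequence],
    ci_level: float = 0.99,
    ci_method: str = "wald",
    states: tuple = None,
) -> TransitionMatrix:
    """MLE transition matrix; see :class:`TransitionMatrixEstimator`."""
    return (
        TransitionMatrixEstimator(ci_level=ci_level, ci_method=ci_method, states=states)
        .fit(seqs)
        .result_
    )


def row_uniformity_test(counts: Sequence[float]) -> tuple:
    """Pearson chi-square of one transition-count row against uniformity.

    Returns ``(chi2, df, p)`` with df = k - 1.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("row total must be positive")
    chi2, p = stats.chisquare(c)
    return float(chi2), int(c.size - 1), float(p)


def compare_probabilities(
    p1: float,
    n1: int,
    p2: float,
    n2: int,
    alpha: float = 0.01,
    m_comparisons: int = 1,
) -> ProbComparison:
    """CI test of the difference between two transition probabilities.

    Builds the (1 - alpha/m) confidence interval of ``p1 - p2`` with
    ``se = sqrt(p1 (1-p1)/n1 + p2 (1-p2)/n2)``; the difference is
    significant when the interval excludes zero.  ``m_comparisons`` applies
    a Bonferroni correction (e.g. alpha 0.01, m = 3 tests at p < 0.003...).
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    level = 1 - alpha / m_comparisons
    z = stats.norm.ppf(0.5 + level / 2)
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2))
    diff = p1 - p2
    lo, hi = diff - z * se, diff + z * se
    return ProbComparison(diff, se, lo, hi, level, significant=not (lo <= 0.0 <= hi))


def screen_markov_subjects(
    table: TrialTable,
    alphabet: str = "three",
    alpha: float = 0.05,
    min_length: int = 50,
) -> tuple:
    """Per-subject Markov-property screen.

    Tests each subject's pooled (per condition x block) sequences and
    returns ``(kept_subject_ids, results)``; subjects whose sequences reject
    the first-order property at ``alpha`` are excluded from pooled fits.
    Subjects with too few trials to test are kept.
    """
    seqs = build_sequences(table, alphabet)
    by_subject: dict = {}
    for s in seqs:
        by_subject.setdefault(s.subject_id, []).append(s)
    kept, results = [], {}
    for sid, ss in by_subject.items():
        try:
            res = verify_markov_property(ss, alpha=alpha, min_length=min_length)
        except ValueError:
            kept.append(sid)
            results[sid] = None
            continue
        results[sid] = res
        if res.passed:
            kept.append(sid)
    return kept, results
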