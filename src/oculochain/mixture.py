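"""Two-component Gaussian mixture of early-saccade latencies.

Early-saccade latency histograms on the WS clock are bimodal: a premature
mode near 250 ms after warning-stimulus offset and an anticipatory mode
scaling with the cued duration.  This module fits the mixture

    f(x) = lambda1 * phi(x; mu1, sigma1) + lambda2 * phi(x; mu2, sigma2)

by expectation-maximization (best of several seeded restarts, components
returned ordered by mean), and places the premature/anticipatory *cut* at
the crossing of the two weighted component densities — the latency where
dominance flips from the first to the second component.

EM details, stated for reproducibility: means initialized at the 25th/75th
sample percentiles (restarts jitter them by up to +/-10%), sds at the sample
sd, weights at 0.5/0.5; convergence when the relative log-likelihood change
drops below ``tol`` (default 1e-8) or after ``max_iter`` iterations; a 1 ms
floor on component sds prevents likelihood blow-up on duplicated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .trials import FP_VALUES, TrialTable

__all__ = [
    "MixtureFit",
    "LatencyMixture",
    "NoCrossingError",
    "DegenerateFitError",
    "fit_em",
    "gaussian_intersection_cut",
    "assign_modes",
    "mixing_proportions",
]

_SD_FLOOR_MS = 1.0


class NoCrossingError(ValueError):
    """The two weighted component densities do not cross between the means."""


class DegenerateFitError(RuntimeError):
    """Every EM restart collapsed (vanishing weight or sd at the floor)."""


@dataclass
class MixtureFit:
    """A fitted 2-Gaussian mixture, components ordered by mean."""

    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    n: int
    cut_ms: Optional[float] = None
    pooled: bool = False  # True when a cell fell back to the pooled fit

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _log_mixture(x, w, mu, sd):
    comp = (
        np.log(w)
        - 0.5 * math.log(2 * math.pi)
        - np.log(sd)
        - 0.5 * ((x[:, None] - mu) / sd) ** 2
    )
    return comp


def _em_once(x, w, mu, sd, tol, max_iter, sd_floor):
    prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        comp = _log_mixture(x, w, mu, sd)
        ll = float(logsumexp(comp, axis=1).sum())
        resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None  # a component lost all mass
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        if prev > -np.inf and abs(ll - prev) <= tol * abs(prev):
            converged = True
            prev = ll
            break
        prev = ll
    # final log-likelihood at the returned parameters
    ll = float(logsumexp(_log_mixture(x, w, mu, sd), axis=1).sum())
    degenerate = bool(np.any(w < 1e-3) and np.any(sd <= sd_floor * (1 + 1e-9)))
    return w, mu, sd, ll, n_iter, converged, degenerate


class LatencyMixture(BaseEstimator):
    """Sklearn-style 2-component Gaussian mixture estimator.

    Parameters
    ----------
    tol : relative log-likelihood convergence tolerance.
    max_iter : iteration cap per restart.
    restarts : number of jittered restarts beyond the percentile init.
    random_state : seed for the restart jitter.
    min_samples : smallest sample the estimator accepts.

    Attributes (after fit)
    ----------------------
    weights_, means_, sigmas_ : arrays of length 2, ordered by mean.
    loglik_, n_iter_, converged_ : best-restart diagnostics.
    cut_ms_ : density-crossing cut, or None when no crossing exists.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        restarts: int = 5,
        random_state: int = 0,
        min_samples: int = 30,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state
        self.min_samples = min_samples

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if x.size < self.min_samples:
            raise ValueError(f"need at least {self.min_samples} latencies, got {x.size}")
        if np.ptp(x) == 0:
            raise ValueError("zero-variance input: all latencies identical")
        rng = np.random.default_rng(self.random_state)
        q25, q75 = np.percentile(x, [25, 75])
        sd0 = max(float(np.std(x)), _SD_FLOOR_MS)
        iqr = max(q75 - q25, _SD_FLOOR_MS)
        inits = [np.array([q25, q75])]
        for _ in range(self.restarts):
            # additive jitter scaled by the IQR keeps fits shift-equivariant
            inits.append(np.array([q25, q75]) + rng.uniform(-0.1, 0.1, size=2) * iqr)
        best = None
        for mu0 in inits:
            out = _em_once(
                x,
                np.array([0.5, 0.5]),
                mu0.astype(float),
                np.array([sd0, sd0]),
                self.tol,
                self.max_iter,
                _SD_FLOOR_MS,
            )
            if out is None or out[6]:
                continue
            if best is None or out[3] > best[3]:
                best = out
        if best is None:
            raise DegenerateFitError("all EM restarts degenerate")
        w, mu, sd, ll, n_iter, converged, _ = best
        order = np.argsort(mu)
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sigmas_ = sd[order]
        self.loglik_ = ll
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_ = int(x.size)
        try:
            self.cut_ms_ = gaussian_intersection_cut(self._fit())
        except NoCrossingError:
            self.cut_ms_ = None
        return self

    def _fit(self) -> MixtureFit:
        return MixtureFit(
            lambda1=float(self.weights_[0]),
            lambda2=float(self.weights_[1]),
            mu1=float(self.means_[0]),
            mu2=float(self.means_[1]),
            sigma1=float(self.sigmas_[0]),
            sigma2=float(self.sigmas_[1]),
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            n=self.n_,
            cut_ms=getattr(self, "cut_ms_", None),
        )

    def predict(self, X):
        """Mode labels (0 = first, 1 = second) by the crossing cut; a latency
        exactly at the cut goes to the first mode."""
        if getattr(self, "cut_ms_", None) is None:
            raise NoCrossingError("no density crossing; cannot assign modes by cut")
        x = np.asarray(X, dtype=float).ravel()
        return (x > self.cut_ms_).astype(int)


def fit_em(
    latencies: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    min_samples: int = 30,
) -> MixtureFit:
    """Fit the 2-Gaussian latency mixture; see :class:`LatencyMixture`."""
    est = LatencyMixture(
        tol=tol, max_iter=max_iter, restarts=restarts, random_state=seed, min_samples=min_samples
    ).fit(latencies)
    return est._fit()


def gaussian_intersection_cut(fit: MixtureFit) -> float:
    """Latency of the crossing between the two weighted Gaussian densities.

    Solves ``lambda1 phi(x; mu1, s1) = lambda2 phi(x; mu2, s2)`` (after logs,
    a quadratic in x) and returns the root in ``(mu1, mu2)`` at which
    dominance flips from component 1 to component 2 moving rightward.

    Raises :class:`NoCrossingError` when no such root exists (e.g. one
    component dominates throughout the interval).
    """
    l1, l2 = fit.lambda1, fit.lambda2
    m1, m2 = fit.mu1, fit.mu2
    s1, s2 = fit.sigma1, fit.sigma2
    if not m1 < m2:
        raise ValueError("components must be ordered mu1 < mu2")
    if min(l1, l2) <= 0:
        raise NoCrossingError("a component has zero weight")
    # log l1 - log s1 - (x-m1)^2/(2 s1^2) = log l2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = (
        m2**2 / s2**2
        - m1**2 / s1**2
        + 2.0 * math.log((l1 * s2) / (l2 * s1))
    )
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            raise NoCrossingError("densities never cross")
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise NoCrossingError("densities never cross")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]

    def logdiff(x: float) -> float:
        return (
            math.log(l1) - math.log(s1) - (x - m1) ** 2 / (2 * s1**2)
        ) - (math.log(l2) - math.log(s2) - (x - m2) ** 2 / (2 * s2**2))

    eps = 1e-6 * (m2 - m1)
    for r in sorted(roots):
        if m1 < r < m2 and logdiff(r - eps) > 0 > logdiff(r + eps):
            return float(r)
    raise NoCrossingError("no dominance-flipping crossing in (mu1, mu2)")


def assign_modes(
    table: TrialTable,
    cuts: Mapping[float, float],
    pooled_cut: Optional[float] = None,
) -> TrialTable:
    """Assign every early trial to the first or second mode by its cut.

    Early trials (``state3 == 'e'``) get ``state4 = 'first'`` when
    ``lat_ws_ms <= cut`` for their duration (ties to first) and ``'second'``
    otherwise; visual and failed trials are copied through.

    Parameters
    ----------
    cuts : mapping duration (fp_ms) -> cut latency on the WS clock.
    pooled_cut : fallback cut for durations missing from ``cuts``.
    """
    out = table.copy()
    df = out.data
    if df["state3"].isna().any():
        raise ValueError("state3 labels missing; run label_states3 first")
    s4 = np.where(df["state3"] == "v", "v", "f").astype(object)
    early = (df["state3"] == "e").to_numpy()
    fp = df["fp_ms"].to_numpy(dtype=float)
    lat = df["lat_ws_ms"].to_numpy(dtype=float)
    for d in np.unique(fp[early]):
        cut = cuts.get(float(d), pooled_cut)
        if cut is None:
            raise KeyError(f"no cut for duration {d} ms and no pooled fallback")
        m = early & (fp == d)
        s4[m] = np.where(lat[m] <= cut, "first", "second")
    df["state4"] = s4
    return out


def fit_and_assign_modes(
    table: TrialTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    min_samples: int = 30,
    per_duration: bool = True,
) -> tuple:
    """Fit mixtures per group x condition (x duration) and assign modes.

    Within each group x condition (medication pooled), early-saccade WS
    latencies are fitted per duration; cells with fewer than ``min_samples``
    early saccades (or a degenerate fit) fall back to a single pooled fit
    across durations, flagged ``pooled`` in the returned records.

    Returns
    -------
    (modes_table, fit_records) : TrialTable with ``state4`` assigned, and a
    list of dicts (one per group x condition x duration) with the fit
    parameters, the cut and labels.
    """
    records = []
    frames = []
    for (group, cond), sub in table.data.groupby(["group", "condition"], sort=True):
        sub_table = TrialTable(sub.reset_index(drop=True), dict(table.provenance))
        early = sub[sub["state3"] == "e"]
        kwargs = dict(tol=tol, max_iter=max_iter, restarts=restarts, seed=seed,
                      min_samples=min_samples)
        pooled_fit = None
        cuts: dict = {}
        pooled_cut = None

        unfittable = False

        def _pooled():
            nonlocal pooled_fit, pooled_cut, unfittable
            if pooled_fit is None and not unfittable:
                try:
                    pooled_fit = fit_em(early["lat_ws_ms"].to_numpy(dtype=float), **kwargs)
                    pooled_cut = pooled_fit.cut_ms
                except (ValueError, DegenerateFitError) as exc:
                    # too few early saccades even pooled: modes stay
                    # unassigned in this cell
                    unfittable = True
                    records.append(
                        {"group": group, "condition": cond, "error": str(exc)}
                    )
            return pooled_fit

        for d, cell in early.groupby("fp_ms"):
            fit = None
            if per_duration and len(cell) >= min_samples:
                try:
                    fit = fit_em(cell["lat_ws_ms"].to_numpy(dtype=float), **kwargs)
                except (ValueError, DegenerateFitError):
                    fit = None
            pooled = fit is None
            if pooled:
                fit = _pooled()
                if fit is None:
                    continue
            records.append(
                fit.to_dict()
                | {"pooled": pooled, "group": group, "condition": cond, "duration_ms": float(d)}
            )
            if not pooled and fit.cut_ms is not None:
                cuts[float(d)] = fit.cut_ms
        durations = set(float(d) for d in early["fp_ms"].unique())
        if (durations - set(cuts)) and pooled_cut is None:
            _pooled()  # ensure a fallback cut for durations without one
        if unfittable and (durations - set(cuts)):
            # not enough early saccades to fit even pooled: keep v/f labels,
            # leave the early trials' modes unassigned
            part = sub_table.copy()
            s4 = np.where(
                part.data["state3"] == "v", "v",
                np.where(part.data["state3"] == "f", "f", None),
            )
            part.data["state4"] = s4
            frames.append(part.data)
        else:
            frames.append(assign_modes(sub_table, cuts, pooled_cut=pooled_cut).data)
    modes = TrialTable(pd.concat(frames, ignore_index=True), dict(table.provenance))
    return modes, records


def mixing_proportions(table: TrialTable) -> pd.DataFrame:
    """First/second mixing proportions per group x condition x duration.

    Proportions are counts of first (resp. second) mode responses over the
    mode-labeled early responses in the cell; cells with no labeled early
    saccades yield NaN proportions rather than an error.
    """
    df = table.data
    rows = []
    for (group, cond), cell in df.groupby(["group", "condition"], sort=True):
        for d in FP_VALUES:
            sub = cell[(cell["fp_ms"] == d) & (cell["state3"] == "e")]
            n1 = int((sub["state4"] == "first").sum())
            n2 = int((sub["state4"] == "second").sum())
            n = n1 + n2
            rows.append(
                {
                    "group": group,
                    "condition": cond,
                    "duration_ms": d,
                    "proportion_first": n1 / n if n else float("nan"),
                    "proportion_second": n2 / n if n else float("nan"),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
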