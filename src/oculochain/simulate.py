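"""Synthetic trial-table generator.

Emulates the timed saccade task: on each trial a foreperiod (FP) is drawn
uniformly from {400, 900, 1400, 1900} ms, and the behavioral response is one
of four latent states evolving as a first-order Markov chain over
``{first, second, v, f}``:

``first``
    a *premature* saccade — an inhibition failure clustered ~250 ms after
    warning-stimulus offset, whose timing depends only weakly on the
    (cued) duration;
``second``
    an *anticipatory* saccade — a temporally guided movement whose latency
    scales with the duration (slope ≈ 0.75 ms per ms) so that it lands near
    imperative-stimulus onset;
``v``
    a visually guided saccade, latency drawn on the IS clock
    (~319 ms in controls, ~376 ms in patients);
``f``
    a failed trial carrying no latency.

The 3-state description used by the coarse analysis is obtained by merging
``first``/``second`` into a single early state ``e``.  Only a handful of
transition probabilities are printed in the source tables; all other cells
of the default matrices are documented fill-ins constructed from the
marginal response rates (rows proportional to the marginals, printed cells
overriding, remainder redistributed proportionally).

Latency draws are rejection-sampled so that realized labels match latent
states by construction: early-mode draws satisfy ``0 < lat_ws_ms`` and
``lat_is_ms <= separation_cutoff_ms``, visual draws satisfy
``separation_cutoff_ms < lat_is_ms <= max_visual_latency_ms``.  This is a
slight truncation of the Gaussians, documented as such.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trials import CONDITIONS, FP_VALUES, GROUPS, MEDICATIONS, TrialTable

__all__ = [
    "LATENT_STATES",
    "GeneratorParams",
    "default_params",
    "generate_session",
    "generate_cohort",
    "stationary_distribution",
    "merge_to_three_state",
]

LATENT_STATES = ("first", "second", "v", "f")
_STATE3_OF = {"first": "e", "second": "e", "v": "v", "f": "f"}

# ---------------------------------------------------------------------------
# Default latent matrices.
#
# Marginal response rates (failed / visual / early) per group x medication x
# condition come from the summary percentage table; the early marginal is
# split into first/second using the duration-averaged mixing proportions.
# Printed transition probabilities override individual cells:
#   - controls, implicit, merged early row: e->e 0.17, e->v 0.64 (so e->f 0.19)
#   - explicit 4-state diagonals: first->first 0.12 (CONT) / 0.20 (ON) / 0.30
#     (OFF); second->second 0.53 / 0.26 / 0.10
#   - patients OFF, explicit: merged e->e 0.315 (fixes the first<->second
#     cross terms)
# ---------------------------------------------------------------------------

# (group, medication, condition) -> (early%, visual%, failed%, first-share of early)
_MARGINALS = {
    ("CONT", "NA", "implicit"): (0.06, 0.74, 0.20, 0.4425),
    ("CONT", "NA", "explicit"): (0.18, 0.63, 0.19, 0.3375),
    ("iPD", "ON", "implicit"): (0.09, 0.46, 0.45, 0.3475),
    ("iPD", "ON", "explicit"): (0.20, 0.44, 0.38, 0.4075),
    ("iPD", "OFF", "implicit"): (0.12, 0.49, 0.40, 0.3475),
    ("iPD", "OFF", "explicit"): (0.21, 0.49, 0.29, 0.4075),
}

_EXPLICIT_DIAGONALS = {
    # (first->first, second->second)
    ("CONT", "NA"): (0.12, 0.53),
    ("iPD", "ON"): (0.20, 0.26),
    ("iPD", "OFF"): (0.30, 0.10),
}

_VISUAL_MEAN_IS = {
    ("CONT", "implicit"): 319.0,
    ("CONT", "explicit"): 317.0,
    ("iPD", "implicit"): 376.0,
    ("iPD", "explicit"): 364.0,
}


def _row_with_overrides(pi: np.ndarray, overrides: dict[int, float]) -> np.ndarray:
    """A stochastic row proportional to ``pi`` except for fixed cells."""
    row = np.zeros(len(pi))
    for j, v in overrides.items():
        row[j] = v
    rest = 1.0 - sum(overrides.values())
    if rest < -1e-12:
        raise ValueError("overrides exceed 1")
    free = [j for j in range(len(pi)) if j not in overrides]
    w = pi[free] / pi[free].sum()
    row[free] = rest * w
    return row


def _marginal_pi(key) -> np.ndarray:
    early, visual, failed, first_share = _MARGINALS[key]
    pi = np.array(
        [early * first_share, early * (1.0 - first_share), visual, failed]
    )
    return pi / pi.sum()


def _default_matrix(group: str, medication: str, condition: str) -> np.ndarray:
    key = (group, medication, condition)
    pi = _marginal_pi(key)
    first_share = _MARGINALS[key][3]
    rows = [pi.copy() for _ in range(4)]  # memoryless fill-in baseline

    if condition == "implicit" and group == "CONT":
        # printed merged early row: e->e 0.17, e->v 0.64, e->f 0.19,
        # e->e split between first/second in the marginal proportion
        early_row = _row_with_overrides(
            pi,
            {0: 0.17 * first_share, 1: 0.17 * (1.0 - first_share), 2: 0.64, 3: 0.19},
        )
        rows[0] = early_row.copy()
        rows[1] = early_row.copy()
    elif condition == "explicit":
        d_first, d_second = _EXPLICIT_DIAGONALS[(group, medication)]
        if (group, medication) == ("iPD", "OFF"):
            # cross terms chosen so the merged e->e equals the printed 0.315
            w1 = first_share
            merged_diag = w1 * d_first + (1.0 - w1) * d_second
            cross = 0.315 - merged_diag
            rows[0] = _row_with_overrides(pi, {0: d_first, 1: cross})
            rows[1] = _row_with_overrides(pi, {0: cross, 1: d_second})
        else:
            rows[0] = _row_with_overrides(pi, {0: d_first})
            rows[1] = _row_with_overrides(pi, {1: d_second})
    # implicit iPD rows stay memoryless: no cells are printed for them
    return np.vstack(rows)


@dataclass
class GeneratorParams:
    """Parameters of a synthetic recording session.

    Latency means are linear in the effective duration ``d`` (the foreperiod,
    which in explicit trials also equals the cue duration):
    premature mode ``premature_mean_ms + premature_slope * d`` on the WS
    clock; anticipatory mode ``antic_intercept_ms + antic_slope * d`` on the
    WS clock; visual saccades ``visual_mean_is_ms`` on the IS clock.
    """

    group: str = "CONT"
    medication: str = "NA"
    condition: str = "implicit"
    n_trials: int = 200
    n_blocks: int = 1
    latent_matrix: np.ndarray = None  # type: ignore[assignment]
    premature_mean_ms: float = 250.0
    premature_slope: float = 0.05
    premature_sd_ms: float = 60.0
    antic_intercept_ms: float = 200.0
    antic_slope: float = 0.75
    antic_sd_ms: float = 80.0
    visual_mean_is_ms: float = 319.0
    visual_sd_ms: float = 50.0
    fixation_range_ms: tuple = (750.0, 950.0)
    separation_cutoff_ms: float = 170.0
    enforce_separation: bool = True
    max_visual_latency_ms: float = 1000.0
    second_mode_pressure: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.medication not in MEDICATIONS:
            raise ValueError(f"unknown medication {self.medication!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        if min(self.premature_sd_ms, self.antic_sd_ms, self.visual_sd_ms) <= 0:
            raise ValueError("all latency sds must be > 0")
        if self.latent_matrix is None:
            self.latent_matrix = _default_matrix(self.group, self.medication, self.condition)
        self.latent_matrix = np.asarray(self.latent_matrix, dtype=float)
        if self.latent_matrix.shape != (4, 4):
            raise ValueError("latent_matrix must be 4x4 over (first, second, v, f)")
        if np.any(self.latent_matrix < 0) or np.max(
            np.abs(self.latent_matrix.sum(axis=1) - 1.0)
        ) > 1e-12:
            raise ValueError("latent_matrix rows must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["latent_matrix"] = np.asarray(self.latent_matrix).tolist()
        d["fixation_range_ms"] = list(self.fixation_range_ms)
        return d


def default_params(group: str, medication: str, condition: str, **overrides) -> GeneratorParams:
    """The documented default parameter set for one group x medication x condition.

    Controls take ``medication="NA"``.  Raises on unknown labels and on
    label combinations outside the study design (e.g. CONT with ON).
    """
    if (group, medication, condition) not in _MARGINALS:
        if group not in GROUPS or medication not in MEDICATIONS or condition not in CONDITIONS:
            raise ValueError(f"unknown label in {(group, medication, condition)!r}")
        raise ValueError(
            f"no default configuration for {(group, medication, condition)!r} "
            "(controls are medication='NA'; patients 'ON' or 'OFF')"
        )
    return GeneratorParams(
        group=group,
        medication=medication,
        condition=condition,
        visual_mean_is_ms=_VISUAL_MEAN_IS[(group, condition)],
        **overrides,
    )


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    matrix = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eig(matrix.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def merge_to_three_state(matrix: np.ndarray, pi: Optional[np.ndarray] = None) -> np.ndarray:
    """Merge first/second into ``e``: a 3x3 matrix over (e, v, f).

    Row ``e`` is the ``pi``-weighted average of the first/second rows
    (default weights: the stationary distribution restricted to the two
    early states); columns first+second are summed.
    """
    matrix = np.asarray(matrix, dtype=float)
    if pi is None:
        pi = stationary_distribution(matrix)
    w = pi[:2] / pi[:2].sum()
    col = np.column_stack(
        [matrix[:, 0] + matrix[:, 1], matrix[:, 2], matrix[:, 3]]
    )
    return np.vstack([w[0] * col[0] + w[1] * col[1], col[2], col[3]])


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    low: np.ndarray,
    high: np.ndarray,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw N(mean, sd) elementwise subject to low < x <= high, by redraw."""
    x = rng.normal(mean, sd)
    for _ in range(max_tries):
        bad = (x <= low) | (x > high)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean[bad] if np.ndim(mean) else mean, sd, size=int(bad.sum()))
    raise RuntimeError("rejection sampling failed: bounds too tight for the Gaussian")


def generate_session(
    params: GeneratorParams,
    subject_id: str,
    rng: Optional[np.random.Generator] = None,
) -> TrialTable:
    """Generate one subject's session as a validated trial table.

    The latent state sequence follows ``params.latent_matrix`` from its
    stationary distribution; latencies are drawn from the state-conditional
    Gaussians on the appropriate clock.  ``state3``/``state4`` columns carry
    the realized (ground-truth) labels, which downstream classification
    recomputes from the latencies alone.  Same seed, same table.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    P = params.latent_matrix
    cum = np.cumsum(P, axis=1)
    pi0 = stationary_distribution(P)
    cut = params.separation_cutoff_ms

    frames = []
    per_block = np.full(params.n_blocks, params.n_trials // params.n_blocks)
    per_block[: params.n_trials % params.n_blocks] += 1
    for block, n in enumerate(per_block):
        n = int(n)
        # latent chain
        u = rng.random(n)
        states = np.empty(n, dtype=np.int64)
        states[0] = int(np.searchsorted(np.cumsum(pi0), u[0], side="right"))
        for t in range(1, n):
            states[t] = int(np.searchsorted(cum[states[t - 1]], u[t], side="right"))
        states = np.minimum(states, 3)

        fp = rng.choice(np.asarray(FP_VALUES), size=n)
        d = fp  # effective duration; in explicit trials the cue equals the FP
        side = np.where(rng.random(n) < 0.5, "left", "right")

        mode = np.array([LATENT_STATES[s] for s in states], dtype=object)
        if params.second_mode_pressure > 0:
            # optional duration-dependent transfer of premature draws to the
            # anticipatory mode (used to emulate the cue-increasing second-mode
            # trend; leaves the latent chain untouched when 0)
            p_flip = params.second_mode_pressure * (d - 400.0) / 1500.0
            flip = (mode == "first") & (rng.random(n) < p_flip)
            mode[flip] = "second"

        lat_ws = np.full(n, np.nan)
        lat_is = np.full(n, np.nan)
        hi_ws = fp + cut if params.enforce_separation else np.full(n, np.inf)

        m1 = mode == "first"
        if m1.any():
            mean = params.premature_mean_ms + params.premature_slope * d[m1]
            lat_ws[m1] = _truncated_normal(
                rng, mean, params.premature_sd_ms, np.zeros(m1.sum()), hi_ws[m1]
            )
        m2 = mode == "second"
        if m2.any():
            mean = params.antic_intercept_ms + params.antic_slope * d[m2]
            lat_ws[m2] = _truncated_normal(
                rng, mean, params.antic_sd_ms, np.zeros(m2.sum()), hi_ws[m2]
            )
        mv = mode == "v"
        if mv.any():
            lo = np.full(mv.sum(), cut) if params.enforce_separation else np.full(mv.sum(), -np.inf)
            lat_is[mv] = _truncated_normal(
                rng,
                np.full(mv.sum(), params.visual_mean_is_ms),
                params.visual_sd_ms,
                lo,
                np.full(mv.sum(), params.max_visual_latency_ms),
            )
        early = m1 | m2
        lat_is[early] = lat_ws[early] - fp[early]
        lat_ws[mv] = lat_is[mv] + fp[mv]

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "group": params.group,
                    "medication": params.medication,
                    "condition": params.condition,
                    "block": block,
                    "trial_index": np.arange(1, n + 1),
                    "side": side,
                    "fp_ms": fp,
                    "cue_ms": fp if params.condition == "explicit" else np.nan,
                    "lat_ws_ms": lat_ws,
                    "lat_is_ms": lat_is,
                    "state3": [_STATE3_OF[m] for m in mode],
                    "state4": mode,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return TrialTable(df, {"generator": params.to_dict(), "subject_id": subject_id})


def generate_cohort(
    spec: Sequence[tuple[GeneratorParams, int]],
    master_seed: int = 0,
    subject_ids: Optional[Sequence[Sequence[str]]] = None,
) -> TrialTable:
    """Generate a cohort: concatenated per-subject sessions.

    Per-subject streams are spawned deterministically from ``master_seed``
    via ``numpy.random.SeedSequence`` (a splitmix-style derivation), so the
    table for subject *k* does not change when other entries are added.

    Parameters
    ----------
    spec : sequence of (GeneratorParams, n_subjects)
    master_seed : int
    subject_ids : optional explicit per-entry id lists; defaults to
        ``{group}_{medication}_{cond}_{k:02d}``.
    """
    if not spec:
        raise ValueError("empty cohort spec")
    ss = np.random.SeedSequence(master_seed)
    total = sum(int(n) for _, n in spec)
    children = ss.spawn(total)
    frames = []
    seen: set[tuple] = set()
    k = 0
    for entry, (params, n_subjects) in enumerate(spec):
        for j in range(int(n_subjects)):
            if subject_ids is not None:
                sid = subject_ids[entry][j]
            else:
                sid = f"{params.group}_{params.medication}_{params.condition[:3]}_{j:02d}"
            # a subject may appear in several sessions (conditions/medication)
            # but not twice in the same one
            key = (sid, params.condition, params.medication)
            if key in seen:
                raise ValueError(f"duplicate subject_id {sid!r} for session {key[1:]}")
            seen.add(key)
            rng = np.random.default_rng(children[k])
            frames.append(generate_session(params, sid, rng=rng).data)
            k += 1
    df = pd.concat(frames, ignore_index=True)
    return TrialTable(
        df,
        {
            "master_seed": master_seed,
            "cohort": [(p.to_dict(), int(n)) for p, n in spec],
        },
    )
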