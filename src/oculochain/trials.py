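"""Trial tables: domain types, validation, and TSV input/output.

A *trial* is one repetition of the timed saccade task: a warning stimulus
(WS) is flashed, its offset starts a foreperiod (FP) of 400/900/1400/1900 ms,
and an imperative stimulus (IS) appears at the end of the FP.  Saccade
latency is recorded on two clocks: ``lat_ws_ms`` counts from WS offset and
``lat_is_ms`` from IS onset, so for any recorded saccade
``lat_ws_ms = lat_is_ms + fp_ms`` exactly (a negative ``lat_is_ms`` is a
saccade launched before the imperative stimulus).

The canonical on-disk format is a tab-separated table with a fixed column
order (see :data:`COLUMNS`).  Missing values are empty fields; the
medication level "NA" (controls, who take no L-DOPA) is written as the token
``NONE`` to avoid colliding with a missing-value marker.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "FP_VALUES",
    "GROUPS",
    "MEDICATIONS",
    "CONDITIONS",
    "SIDES",
    "STATES3",
    "STATES4",
    "TrialTable",
    "TrialValidationError",
    "SchemaError",
    "validate_trials",
    "read_trials",
    "write_trials",
]

COLUMNS = [
    "subject_id",
    "group",
    "medication",
    "condition",
    "block",
    "trial_index",
    "side",
    "fp_ms",
    "cue_ms",
    "lat_ws_ms",
    "lat_is_ms",
    "state3",
    "state4",
]

#: The four equiprobable foreperiod durations of the task, ms.
FP_VALUES = (400.0, 900.0, 1400.0, 1900.0)

GROUPS = ("CONT", "iPD")
MEDICATIONS = ("ON", "OFF", "NA")
CONDITIONS = ("implicit", "explicit")
SIDES = ("left", "right")
STATES3 = ("e", "v", "f")
STATES4 = ("first", "second", "v", "f")

_STRING_COLS = ["subject_id", "group", "medication", "condition", "side", "state3", "state4"]
_INT_COLS = ["block", "trial_index"]
_FLOAT_COLS = ["fp_ms", "cue_ms", "lat_ws_ms", "lat_is_ms"]

#: tolerance for the clock identity lat_ws_ms - lat_is_ms = fp_ms
_CLOCK_ATOL = 1e-6

# medication "NA" is written to files as "NONE" so that an empty field can
# unambiguously mean "missing"
_MEDICATION_FILE_TOKEN = {"NA": "NONE"}
_MEDICATION_READ_TOKEN = {"NONE": "NA"}


class SchemaError(ValueError):
    """A trial file is missing required columns or has unparsable fields."""


class TrialValidationError(ValueError):
    """One or more rows violate the Trial invariants.

    Attributes
    ----------
    messages : list of str
        Row-numbered diagnostics (0-based row index within the table).
    """

    def __init__(self, messages):
        self.messages = list(messages)
        preview = "\n".join(self.messages[:20])
        more = "" if len(self.messages) <= 20 else f"\n... and {len(self.messages) - 20} more"
        super().__init__(f"{len(self.messages)} invalid trial row(s):\n{preview}{more}")


@dataclass
class TrialTable:
    """An ordered collection of validated trials.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per trial, columns :data:`COLUMNS`.  Row order preserves the
        within-subject trial sequence.
    provenance : dict
        Free-form metadata: seed, generator parameters or source file path.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "TrialTable":
        return TrialTable(self.data.copy(), dict(self.provenance))


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    for c in _INT_COLS:
        df[c] = df[c].astype(int)
    return df


def validate_trials(df: pd.DataFrame, skip_bad: bool = False) -> pd.DataFrame:
    """Validate a trial frame against the Trial invariants.

    Checks, per row: categorical levels, ``fp_ms`` in the four task values,
    the two latencies jointly present or jointly absent, the clock identity
    ``lat_ws_ms - lat_is_ms = fp_ms``, state labels from the right alphabets
    and ``state3 == 'f'`` exactly when no latency is recorded.  Across rows:
    ``trial_index`` strictly increasing within (subject, condition, block)
    and no duplicate (subject, condition, block, trial_index).

    Parameters
    ----------
    df : pandas.DataFrame
    skip_bad : bool
        If True, invalid rows are dropped with the diagnostics attached to
        the returned frame's ``attrs['dropped']``; if False (default) any
        invalid row raises :class:`TrialValidationError`.

    Returns
    -------
    pandas.DataFrame
        The validated (possibly filtered) frame, row order preserved.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[COLUMNS].copy()

    messages: list[str] = []
    bad = np.zeros(len(df), dtype=bool)

    def flag(mask: np.ndarray, msg: str) -> None:
        for i in np.flatnonzero(mask):
            messages.append(f"row {i}: {msg}")
        bad[:] |= mask

    flag(~df["group"].isin(GROUPS).to_numpy(), "group not in {CONT, iPD}")
    flag(~df["medication"].isin(MEDICATIONS).to_numpy(), "medication not in {ON, OFF, NA}")
    flag(~df["condition"].isin(CONDITIONS).to_numpy(), "condition not in {implicit, explicit}")
    flag(~df["side"].isin(SIDES).to_numpy(), "side not in {left, right}")

    fp = df["fp_ms"].to_numpy(dtype=float)
    fp_ok = np.isin(fp, np.asarray(FP_VALUES))
    flag(~fp_ok, "fp_ms not one of 400/900/1400/1900")

    lat_ws = df["lat_ws_ms"].to_numpy(dtype=float)
    lat_is = df["lat_is_ms"].to_numpy(dtype=float)
    has_ws = ~np.isnan(lat_ws)
    has_is = ~np.isnan(lat_is)
    flag(has_ws != has_is, "lat_ws_ms and lat_is_ms must be jointly present or absent")
    both = has_ws & has_is
    clock_bad = both & (np.abs(lat_ws - lat_is - fp) > _CLOCK_ATOL)
    flag(clock_bad, "clock identity violated: lat_ws_ms - lat_is_ms != fp_ms")

    s3 = df["state3"]
    s3_present = s3.notna() & (s3 != "")
    flag((s3_present & ~s3.isin(STATES3)).to_numpy(), "state3 not in {e, v, f}")
    s4 = df["state4"]
    s4_present = s4.notna() & (s4 != "")
    flag((s4_present & ~s4.isin(STATES4)).to_numpy(), "state4 not in {first, second, v, f}")
    # a failed trial is exactly a trial with no recorded latency
    is_f = (s3 == "f").to_numpy()
    flag(s3_present.to_numpy() & is_f & both, "state3 = f but a latency is recorded")
    flag(s3_present.to_numpy() & ~is_f & ~both, "state3 != f but no latency recorded")

    # sequence invariants within (subject, condition, block)
    if len(df):
        key = df[["subject_id", "condition", "block"]].astype(str).agg("|".join, axis=1)
        for _, idx in df.groupby(key, sort=False).indices.items():
            ti = df["trial_index"].to_numpy()[idx]
            if len(ti) > 1:
                nonmono = np.flatnonzero(np.diff(ti) <= 0)
                for j in nonmono:
                    messages.append(
                        f"row {idx[j + 1]}: trial_index not strictly increasing within "
                        "(subject, condition, block)"
                    )
                    bad[idx[j + 1]] = True

    if messages:
        if not skip_bad:
            raise TrialValidationError(messages)
        df = df.loc[~bad].copy()
        df.attrs["dropped"] = messages
    return df


def read_trials(
    path: Union[str, Path, io.IOBase],
    dialect: str = "tsv",
    skip_bad: bool = False,
) -> TrialTable:
    """Read a trial table from a TSV (or CSV) file and validate it.

    Parameters
    ----------
    path : path or file-like
    dialect : {"tsv", "csv"}
    skip_bad : bool
        Downgrade invalid rows to warnings (dropped rows) instead of failing
        the whole load.

    Raises
    ------
    SchemaError
        Missing columns or non-numeric values in numeric columns.
    TrialValidationError
        Rows violating the Trial invariants (unless ``skip_bad``).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw[COLUMNS].copy()
    for c in _FLOAT_COLS:
        try:
            df[c] = pd.to_numeric(df[c].where(df[c] != "", None), errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric value in column {c!r}: {exc}") from exc
    for c in _INT_COLS:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-integer value in column {c!r}: {exc}") from exc
    df["medication"] = df["medication"].replace(_MEDICATION_READ_TOKEN)
    for c in ("state3", "state4"):
        df[c] = df[c].replace("", np.nan)
    df = validate_trials(df, skip_bad=skip_bad)
    prov = {"path": str(path)} if isinstance(path, (str, Path)) else {}
    return TrialTable(df.reset_index(drop=True), prov)


def write_trials(table: TrialTable, path: Union[str, Path, io.IOBase], dialect: str = "tsv") -> None:
    """Write a validated trial table; missing values become empty fields."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = table.data[COLUMNS].copy() if len(table.data) else _empty_frame()
    df["medication"] = df["medication"].replace(_MEDICATION_FILE_TOKEN)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g", na_rep="")
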