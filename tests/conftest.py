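import numpy as np
import pandas as pd
import pytest

from oculochain.trials import COLUMNS, TrialTable


def table_from_states(states, subject_id="s1", condition="implicit", group="CONT",
                      medication="NA", block=0, start_index=1):
    """Build a small valid trial table whose state3 sequence is ``states``.

    Early trials get lat_is = 100 ms, visual trials 300 ms, failed trials no
    latency; fp alternates over the four task values.
    """
    fps = [400.0, 900.0, 1400.0, 1900.0]
    rows = []
    for i, s in enumerate(states):
        fp = fps[i % 4]
        if s == "f":
            lat_is = np.nan
        elif s == "e":
            lat_is = 100.0
        else:
            lat_is = 300.0
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "medication": medication,
                "condition": condition,
                "block": block,
                "trial_index": start_index + i,
                "side": "left" if i % 2 else "right",
                "fp_ms": fp,
                "cue_ms": fp if condition == "explicit" else np.nan,
                "lat_ws_ms": lat_is + fp if not np.isnan(lat_is) else np.nan,
                "lat_is_ms": lat_is,
                "state3": s,
                "state4": {"e": "first", "v": "v", "f": "f"}[s],
            }
        )
    return TrialTable(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture
def worked_sequence_table():
    """The seven-trial sequence e-e-v-v-f-e-v used as a worked example."""
    return table_from_states(list("eevvfev"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
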