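"""Gaze-behavior and NASA-TLX workload metrics.

The reported gaze metric is the percentage of total task time spent looking
at the navigation monitor instead of the surgical field; the reported
workload is the raw (unweighted) NASA-TLX: the six subscale ratings plus
their unweighted mean, with no pairwise-comparison weighting stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import GazeStream, TLXResponse, TLX_SUBSCALES

__all__ = ["percent_screen_time", "tlx_scores", "gaze_table", "tlx_table"]


def percent_screen_time(stream: GazeStream) -> float:
    """Screen-dwell time as a percentage of total study time.

    Any non-screen time (surgical field, and any gaps a recording device
    would label blink/lost-tracking) counts against the same denominator.
    """
    total = stream.total_duration
    if total <= 0:
        raise ValueError("gaze stream has zero duration")
    screen = sum(end - start for start, end, label in stream.events if label == "screen")
    return 100.0 * screen / total


def tlx_scores(response: TLXResponse) -> dict[str, float]:
    """Raw TLX: the six subscales unchanged plus their unweighted mean."""
    scores = {name: float(getattr(response, name)) for name in TLX_SUBSCALES}
    scores["overall"] = float(np.mean(list(scores.values())))
    return scores


def gaze_table(streams: dict, by_condition: bool = True) -> pd.DataFrame:
    """Per-session and pooled screen-time percentages.

    ``streams`` maps (condition, session key) -> GazeStream.  Pooled
    percentages aggregate screen and total time across a condition's
    sessions (a time ratio), reported alongside the per-session mean since
    the two differ when session durations vary.
    """
    rows = []
    for (condition, key), stream in streams.items():
        screen = sum(e - s for s, e, lab in stream.events if lab == "screen")
        rows.append(
            {
                "condition": condition,
                "session": key,
                "screen_s": screen,
                "total_s": stream.total_duration,
                "pct_screen": percent_screen_time(stream),
            }
        )
    per_session = pd.DataFrame(rows)
    if not by_condition:
        return per_session
    pooled = (
        per_session.groupby("condition", sort=False)
        .apply(
            lambda g: pd.Series(
                {
                    "pct_screen_pooled": 100.0 * g["screen_s"].sum() / g["total_s"].sum(),
                    "pct_screen_mean": g["pct_screen"].mean(),
                    "n_sessions": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return pooled


def tlx_table(responses: dict) -> pd.DataFrame:
    """Tabulate TLX scores; ``responses`` maps (condition, session) -> TLXResponse."""
    rows = []
    for (condition, key), resp in responses.items():
        row = {"condition": condition, "session": key}
        row.update(tlx_scores(resp))
        rows.append(row)
    return pd.DataFrame(rows)
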