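"""Behavioural scoring of the VCPT: omissions, commissions, RT statistics.

A GO response counts as correct only if it falls within the closed
[100, 1000] ms window after S2; a GO trial with no response, or a
response outside the window, is an omission.  Any press on a NOGO trial
is a commission regardless of latency.  RT statistics (mean, median,
sample SD) are computed over correct GO responses only; response-time
variability is the per-subject SD of those RTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import TrialSequence

RESPONSE_WINDOW_MS = (100.0, 1000.0)


@dataclass
class BehaviouralSummary:
    omissions: int
    commissions: int
    rt_mean_ms: float
    rt_median_ms: float
    rt_sd_ms: float
    n_go: int
    n_nogo: int

    def as_dict(self) -> dict:
        return {
            "omissions": self.omissions, "commissions": self.commissions,
            "rt_mean_ms": self.rt_mean_ms, "rt_median_ms": self.rt_median_ms,
            "rt_sd_ms": self.rt_sd_ms, "n_go": self.n_go, "n_nogo": self.n_nogo,
        }


def score_behaviour(sequence: TrialSequence, log: pd.DataFrame) -> BehaviouralSummary:
    """Score a response log against its trial sequence.

    ``log`` carries one row per trial with ``trial_index`` and
    ``response_time_ms`` (NaN for no press, relative to S2 onset).
    """
    by_index = {t.index: t for t in sequence.trials}
    lo, hi = RESPONSE_WINDOW_MS
    omissions = commissions = 0
    rts = []
    seen = set()
    for row in log.itertuples(index=False):
        trial = by_index.get(int(row.trial_index))
        if trial is None:
            raise ValueError(f"response log refers to trial index "
                             f"{row.trial_index} with no scheduled trial")
        seen.add(trial.index)
        rt = float(row.response_time_ms) if pd.notna(row.response_time_ms) else np.nan
        if trial.condition == "GO":
            if np.isnan(rt) or not (lo <= rt <= hi):
                omissions += 1
            else:
                rts.append(rt)
        elif trial.condition == "NOGO":
            if not np.isnan(rt):
                commissions += 1
    # GO trials missing from the log are omissions too
    for t in sequence.trials:
        if t.condition == "GO" and t.index not in seen:
            omissions += 1
    rts = np.array(rts)
    n_go = sum(1 for t in sequence.trials if t.condition == "GO")
    n_nogo = sum(1 for t in sequence.trials if t.condition == "NOGO")
    return BehaviouralSummary(
        omissions=omissions, commissions=commissions,
        rt_mean_ms=float(rts.mean()) if rts.size else np.nan,
        rt_median_ms=float(np.median(rts)) if rts.size else np.nan,
        rt_sd_ms=float(rts.std(ddof=1)) if rts.size > 1 else (0.0 if rts.size else np.nan),
        n_go=n_go, n_nogo=n_nogo)


def behaviour_table(summaries: dict[str, BehaviouralSummary]) -> pd.DataFrame:
    """One row per subject, ready for group comparisons."""
    return pd.DataFrame([{"subject_id": sid, **s.as_dict()}
                         for sid, s in summaries.items()])
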