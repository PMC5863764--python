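"""Behavioral endpoints: retention, TMR benefit, discrimination index.

The behavior table holds one row per subject x item with recall outcomes
at the three test phases (T1 before the offline period, T2 after it, T3
the next day), the cued/non-cued assignment, and the post-study
discrimination response. "Recalled" means the associated image category
(object vs scene) was reported correctly; items that failed the separate
object/scene categorisation check are excluded from all recall scoring.

Retention from Tn to Tm is the proportion of items recalled at Tn that
were also recalled at Tm. The TMR benefit is T2->T3 retention of cued
items minus T2->T3 retention of non-cued items. The discrimination index
is the hit rate on cued items minus the false-alarm rate on non-cued
items in the post-study awareness test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TESTS = {"T1": "t1_correct", "T2": "t2_correct", "T3": "t3_correct"}

REQUIRED_COLUMNS = ("subject", "item_id", "category", "cued",
                    "t1_correct", "t2_correct", "t3_correct",
                    "categorisation_correct", "discrimination_yes")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behavior table lacks columns {sorted(missing)}")
    if table.duplicated(["subject", "item_id"]).any():
        raise ValueError("duplicate subject/item keys in behavior table")
    return table


def retention(table: pd.DataFrame, frm: str = "T2", to: str = "T3",
              cued: bool | None = None) -> float:
    """Proportion of items recalled at ``frm`` also recalled at ``to``.

    Items failing the categorisation check are excluded. Returns NaN when
    the denominator is empty.
    """
    t = _validate(table)
    t = t[t["categorisation_correct"]]
    if cued is not None:
        t = t[t["cued"] == cued]
    base = t[t[_TESTS[frm]]]
    if len(base) == 0:
        logger.warning("retention %s->%s: empty denominator", frm, to)
        return float("nan")
    return float(base[_TESTS[to]].mean())


def tmr_benefit(table: pd.DataFrame) -> pd.Series:
    """Per-subject cued minus non-cued T2->T3 retention.

    Subjects with an undefined retention on either side (zero T2-recalled
    items) are excluded with a log entry.
    """
    _validate(table)
    out = {}
    excluded = 0
    for subj, sub in table.groupby("subject"):
        c = retention(sub, "T2", "T3", cued=True)
        nc = retention(sub, "T2", "T3", cued=False)
        if np.isnan(c) or np.isnan(nc):
            excluded += 1
            continue
        out[subj] = c - nc
    if excluded:
        logger.info("tmr_benefit: %d subject(s) excluded (undefined retention)",
                    excluded)
    return pd.Series(out, name="tmr_benefit")


def discrimination_index(table: pd.DataFrame) -> pd.Series:
    """Per-subject hit rate (cued) minus false-alarm rate (non-cued).

    Only items recalled at T1 were assigned to the cued/non-cued
    conditions, so the index is computed over T1-correct items.
    """
    _validate(table)
    out = {}
    for subj, sub in table.groupby("subject"):
        sub = sub[sub["t1_correct"]]
        cued = sub[sub["cued"]]
        noncued = sub[~sub["cued"]]
        if len(cued) == 0 or len(noncued) == 0:
            out[subj] = float("nan")
            continue
        hits = cued["discrimination_yes"].mean()
        fa = noncued["discrimination_yes"].mean()
        out[subj] = float(hits - fa)
    return pd.Series(out, name="discrimination_index")


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM retention per test transition and cueing condition."""
    rows = []
    for frm, to in (("T1", "T2"), ("T2", "T3")):
        for cued in (True, False):
            vals = [retention(sub, frm, to, cued=cued)
                    for _, sub in table.groupby("subject")]
            vals = np.asarray(vals, float)
            vals = vals[~np.isnan(vals)]
            rows.append({
                "transition": f"{frm}->{to}", "cued": cued,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
                       if vals.size > 1 else float("nan"),
                "n": int(vals.size)})
    return pd.DataFrame(rows)
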