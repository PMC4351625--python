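"""Recovery metrics against planted simulation truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

SITE_KEY = ["chrom", "pos", "strand"]


def dmp_recovery(dmp_table: pd.DataFrame, planted: pd.DataFrame,
                 group: str, context: str) -> dict:
    """Sensitivity and empirical FDR of pairwise DMP calls for one context.

    ``planted`` is the simulator's planted-DMP truth; rows for ``group``
    and ``context`` are the positives.  Sensitivity is computed over
    planted sites that were actually tested (eligible); the empirical FDR
    counts called DMPs at unplanted sites.
    """
    sub = dmp_table[dmp_table["context"] == context]
    truth = planted[(planted["group"] == group) &
                    (planted["context"] == context)]
    truth_keys = set(map(tuple, truth[SITE_KEY].to_numpy()))
    keys = list(map(tuple, sub[SITE_KEY].to_numpy()))
    is_planted = np.array([k in truth_keys for k in keys])
    called = (sub["status"] == "DMP").to_numpy()
    tested = (sub["status"] != "untested").to_numpy()
    n_planted_tested = int((is_planted & tested).sum())
    sensitivity = float((called & is_planted).sum() / n_planted_tested) \
        if n_planted_tested else np.nan
    n_called = int(called.sum())
    fdr = float((called & ~is_planted).sum() / n_called) if n_called else 0.0
    return {"sensitivity": sensitivity, "empirical_fdr": fdr,
            "n_called": n_called, "n_planted_tested": n_planted_tested}


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0]) + 1
    return inter / union


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def dmr_recovery(called: pd.DataFrame, planted: pd.DataFrame) -> dict:
    """Base-level overlap of called significant DMRs with planted truth.

    Recovery is measured per planted region as the Jaccard index between
    the planted interval and the union of overlapping significant calls of
    the same chromosome and context — a run-based candidate definition can
    split one true region across adjacent calls at chance coverage gaps,
    which is boundary noise rather than a missed region.  The false-call
    rate stays per call: the fraction of significant calls that overlap no
    planted region at all.
    """
    sig = called[called["status"] == "significant"] if len(called) else called
    jaccards = []
    for _, t in planted.iterrows():
        hits = [(int(c["start"]), int(c["end"])) for _, c in sig.iterrows()
                if c["chrom"] == t["chrom"] and c["context"] == t["context"]
                and interval_jaccard((t["start"], t["end"]),
                                     (c["start"], c["end"])) > 0]
        if not hits:
            jaccards.append(0.0)
            continue
        union = _merge_intervals(hits + [(int(t["start"]), int(t["end"]))])
        union_len = sum(e - s + 1 for s, e in union)
        inter_len = sum(min(e, t["end"]) - max(s, t["start"]) + 1
                        for s, e in _merge_intervals(hits)
                        if min(e, t["end"]) >= max(s, t["start"]))
        jaccards.append(inter_len / union_len)
    false_calls = 0
    for _, c in sig.iterrows():
        hit = any(c["chrom"] == t["chrom"] and c["context"] == t["context"]
                  and interval_jaccard((t["start"], t["end"]),
                                       (c["start"], c["end"])) > 0
                  for _, t in planted.iterrows())
        false_calls += not hit
    n_calls = len(sig)
    return {
        "jaccards": np.array(jaccards),
        "min_jaccard": float(np.min(jaccards)) if jaccards else np.nan,
        "mean_jaccard": float(np.mean(jaccards)) if jaccards else np.nan,
        "n_calls": int(n_calls),
        "false_call_rate": float(false_calls / n_calls) if n_calls else 0.0,
    }
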