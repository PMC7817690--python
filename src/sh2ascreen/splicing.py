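"""Class-resolved differential splicing on Psi (percent-spliced-in) tables.

Each tested event gets delta_psi (mean Psi of the positive group minus mean
of the negative group, over non-missing values), a one-sided rank-test p in
the direction of delta_psi, and a composite call: up iff p < alpha and
delta_psi > delta; down iff p < alpha and delta_psi < -delta; else none.
For tandem-UTR events Psi is the proximal-site usage fraction, so reduced
proximal poly-A usage appears as a negative delta_psi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import PsiTable
from .stats import mwu_matrix

ALPHA_DEFAULT = 0.05
DELTA_DEFAULT = 0.1
MIN_PER_GROUP_DEFAULT = 5


@dataclass(frozen=True)
class SplicingCall:
    event_id: str
    event_class: str
    delta_psi: float
    p_value: float
    call: str  # up | down | none


class SplicingCallList(list):
    """List of tested :class:`SplicingCall` plus the skipped event ids."""

    def __init__(self, calls=(), untested=()):
        super().__init__(calls)
        self.untested: list[str] = list(untested)


def differential_splicing(
    psi: PsiTable,
    group_pos,
    group_neg,
    alpha: float = ALPHA_DEFAULT,
    delta: float = DELTA_DEFAULT,
    min_per_group: int = MIN_PER_GROUP_DEFAULT,
    use_median: bool = False,
) -> SplicingCallList:
    """Test every event with enough non-missing Psi in both groups.

    Events with fewer than ``min_per_group`` non-missing values in either
    group are skipped and reported in the result's ``untested`` attribute.
    ``use_median`` switches delta_psi from group means to group medians;
    the test itself is always on the full rank distribution.
    """
    group_pos, group_neg = list(group_pos), list(group_neg)
    if not group_pos or not group_neg:
        raise ValidationError("both groups must be non-empty")
    overlap = set(group_pos) & set(group_neg)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    for s in (*group_pos, *group_neg):
        if s not in psi._sample_index:
            raise ValidationError(f"sample {s!r} not in psi table")
    pos_idx = [psi._sample_index[s] for s in group_pos]
    neg_idx = [psi._sample_index[s] for s in group_neg]
    center = np.nanmedian if use_median else np.nanmean

    calls: list[SplicingCall] = []
    untested: list[str] = []
    complete_rows: list[int] = []  # rows with no missing data: batch them
    for i, eid in enumerate(psi.event_ids):
        a = psi.values[i, pos_idx]
        b = psi.values[i, neg_idx]
        if not (np.isnan(a).any() or np.isnan(b).any()):
            complete_rows.append(i)
            continue
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < min_per_group or b.size < min_per_group:
            untested.append(eid)
            continue
        calls.append(_one_event(psi, i, a, b, center, alpha, delta))

    if complete_rows:
        if len(pos_idx) < min_per_group or len(neg_idx) < min_per_group:
            untested.extend(psi.event_ids[i] for i in complete_rows)
        else:
            A = psi.values[np.ix_(complete_rows, pos_idx)]
            B = psi.values[np.ix_(complete_rows, neg_idx)]
            d = center(A, axis=1) - center(B, axis=1)
            _, p_gt = mwu_matrix(A, B, alternative="x_greater")
            _, p_lt = mwu_matrix(A, B, alternative="x_less")
            p = np.where(d >= 0, p_gt, p_lt)
            for i, di, pi in zip(complete_rows, d, p):
                calls.append(
                    SplicingCall(
                        psi.event_ids[i],
                        psi.event_classes[i],
                        float(di),
                        float(pi),
                        _composite_call(float(di), float(pi), alpha, delta),
                    )
                )
    order = {e: i for i, e in enumerate(psi.event_ids)}
    calls.sort(key=lambda c: order[c.event_id])
    return SplicingCallList(calls, untested)


def _one_event(psi, i, a, b, center, alpha, delta) -> SplicingCall:
    d = float(center(a) - center(b))
    _, p = mwu_matrix(
        a[None, :], b[None, :], alternative="x_greater" if d >= 0 else "x_less"
    )
    return SplicingCall(
        psi.event_ids[i], psi.event_classes[i], d, float(p[0]),
        _composite_call(d, float(p[0]), alpha, delta),
    )


def _composite_call(d: float, p: float, alpha: float, delta: float) -> str:
    if p < alpha and d > delta:
        return "up"
    if p < alpha and d < -delta:
        return "down"
    return "none"


def class_tallies(calls: list[SplicingCall], classes: list[str] | None = None) -> pd.DataFrame:
    """Per-event-class counts and percentages of up/down calls.

    Percentages are relative to tested events of the class; a class with no
    tested events reports NaN percentages (undefined, not 0).
    """
    if classes is None:
        seen: dict[str, None] = {}
        for c in calls:
            seen.setdefault(c.event_class)
        classes = list(seen)
    rows = []
    for cls_name in classes:
        of_class = [c for c in calls if c.event_class == cls_name]
        n = len(of_class)
        n_up = sum(c.call == "up" for c in of_class)
        n_down = sum(c.call == "down" for c in of_class)
        rows.append(
            {
                "event_class": cls_name,
                "n_tested": n,
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": 100.0 * n_up / n if n else float("nan"),
                "pct_down": 100.0 * n_down / n if n else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["event_class", "n_tested", "n_up", "n_down", "pct_up", "pct_down"]
    )


def calls_frame(calls: SplicingCallList) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "event_id": [c.event_id for c in calls],
            "event_class": [c.event_class for c in calls],
            "delta_psi": [c.delta_psi for c in calls],
            "p_value": [c.p_value for c in calls],
            "call": [c.call for c in calls],
        }
    )
    return df
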