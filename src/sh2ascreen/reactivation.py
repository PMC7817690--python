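"""Per-sample short-H2A expression status, frequencies and co-expression.

Status thresholds use strict inequalities: TPM > tau_pos is positive,
TPM < tau_neg is negative, anything in [tau_neg, tau_pos] (including the
borders) is intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import AnnotationTable, ExpressionMatrix, SampleTable
from .stats import percentile_rank

TAU_POS_DEFAULT = 1.5
TAU_NEG_DEFAULT = 0.5


@dataclass(frozen=True)
class ReactivationStatus:
    sample_id: str
    paralogue: str
    status: str  # positive | negative | intermediate
    tpm: float


def classify_sh2a_status(
    expr: ExpressionMatrix,
    annotation: AnnotationTable,
    tau_pos: float = TAU_POS_DEFAULT,
    tau_neg: float = TAU_NEG_DEFAULT,
    merge_near_identical: bool = False,
) -> list[ReactivationStatus]:
    """One status record per (sample, paralogue); the partition is exhaustive.

    With ``merge_near_identical`` the H2AFB2/H2AFB3 pair (indistinguishable
    by short-read mapping) is collapsed into a single ``H2AFB2/3`` paralogue
    whose TPM is the per-sample maximum of the two.
    """
    if tau_neg > tau_pos:
        raise ValidationError("tau_neg must not exceed tau_pos")
    sh2a = [g for g in annotation.with_category("sH2A_paralogue") if g.gene_id in expr._gene_index]
    if not sh2a:
        raise ValidationError("no annotated sH2A paralogue gene present in the matrix")

    rows: list[tuple[str, np.ndarray]] = [(g.paralogue, expr.gene_row(g.gene_id)) for g in sh2a]
    if merge_near_identical:
        merged: dict[str, np.ndarray] = {}
        for name, tpm in rows:
            key = "H2AFB2/3" if name in ("H2AFB2", "H2AFB3") else name
            merged[key] = np.maximum(merged[key], tpm) if key in merged else tpm
        rows = list(merged.items())

    out: list[ReactivationStatus] = []
    for name, tpm in rows:
        for s, v in zip(expr.sample_ids, tpm):
            if v > tau_pos:
                status = "positive"
            elif v < tau_neg:
                status = "negative"
            else:
                status = "intermediate"
            out.append(ReactivationStatus(s, name, status, float(v)))
    return out


def any_paralogue_positive(
    statuses: list[ReactivationStatus],
    paralogue_set: set[str] | None = None,
) -> dict[str, bool]:
    """Per-sample flag: true iff at least one paralogue in the set is positive.

    Intermediate status never counts as positive.
    """
    if paralogue_set is not None:
        seen = {st.paralogue for st in statuses}
        missing = set(paralogue_set) - seen
        if missing:
            raise ValidationError(f"statuses do not cover paralogues: {sorted(missing)}")
    out: dict[str, bool] = {}
    for st in statuses:
        if paralogue_set is not None and st.paralogue not in paralogue_set:
            continue
        out[st.sample_id] = out.get(st.sample_id, False) or st.status == "positive"
    return out


def sample_groups(
    statuses: list[ReactivationStatus],
) -> tuple[list[str], list[str], list[str]]:
    """Partition samples into (positive-any, negative-all, intermediate).

    Positive: any paralogue above tau_pos.  Negative: every paralogue below
    tau_neg.  Remaining samples have intermediate short-H2A expression and
    are excluded from differential analyses.
    """
    per_sample: dict[str, list[str]] = {}
    for st in statuses:
        per_sample.setdefault(st.sample_id, []).append(st.status)
    pos, neg, inter = [], [], []
    for s, stats in per_sample.items():
        if "positive" in stats:
            pos.append(s)
        elif all(x == "negative" for x in stats):
            neg.append(s)
        else:
            inter.append(s)
    return pos, neg, inter


def reactivation_frequency(
    statuses: list[ReactivationStatus],
    samples: SampleTable,
    min_group: int = 10,
) -> pd.DataFrame:
    """Per-cancer-type positive-any frequency over all tumors of the type.

    The denominator includes intermediate samples.  ``meets_filter`` flags
    cancer types with at least ``min_group`` positive tumors (the reporting
    filter used for cohort-level displays).
    """
    pos_any = any_paralogue_positive(statuses)
    for s in pos_any:
        samples.cancer_type_of(s)  # raises on unknown samples
    rows = []
    for ct in samples.cancer_type_list():
        tumors = [s for s in samples.samples_of_type(ct, "tumor") if s in pos_any]
        if not tumors:
            continue
        n_pos = sum(pos_any[s] for s in tumors)
        rows.append(
            {
                "cancer_type": ct,
                "n_tumors": len(tumors),
                "n_positive": n_pos,
                "frequency": n_pos / len(tumors),
                "meets_filter": n_pos >= min_group,
            }
        )
    return pd.DataFrame(rows, columns=["cancer_type", "n_tumors", "n_positive",
                                       "frequency", "meets_filter"])


def coexpression_matrix(
    statuses: list[ReactivationStatus],
    paralogue_set: list[str] | None = None,
) -> pd.DataFrame:
    """Binary sample x paralogue matrix over samples positive for any paralogue."""
    if paralogue_set is None:
        seen: dict[str, None] = {}
        for st in statuses:
            seen.setdefault(st.paralogue)
        paralogue_set = list(seen)
    pos_any = any_paralogue_positive(statuses, set(paralogue_set))
    keep = [s for s, flag in pos_any.items() if flag]
    by_key = {(st.sample_id, st.paralogue): st.status for st in statuses}
    data = {
        p: [1 if by_key.get((s, p)) == "positive" else 0 for s in keep]
        for p in paralogue_set
    }
    return pd.DataFrame(data, index=keep, columns=paralogue_set)


def expression_percentile(
    expr: ExpressionMatrix,
    gene_id: str,
    expressed_rule=None,
    sample_ids: list[str] | None = None,
) -> float:
    """Percentile rank of a gene's median TPM among expressed genes.

    ``expressed_rule`` maps a per-gene median TPM to a boolean; the default
    (median > 0 across the chosen samples) is a deliberate choice — the
    source analyses never define "expressed".  The queried gene joins the
    reference set only if it passes the rule itself.
    """
    if expressed_rule is None:
        expressed_rule = lambda med: med > 0.0  # noqa: E731
    cols = (
        expr.values
        if sample_ids is None
        else expr.sample_columns(sample_ids)
    )
    medians = np.median(cols, axis=1)
    gi = expr.gene_index(gene_id)
    expressed = np.array([expressed_rule(m) for m in medians], dtype=bool)
    ref = medians[expressed]
    if ref.size == 0:
        raise ValidationError("no gene passes the expressed rule")
    return percentile_rank(ref, float(medians[gi]))
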