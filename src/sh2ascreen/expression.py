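"""Group differential expression and derived cohort-level statistics.

Includes trimmed-mean-of-M-values (TMM) scaling factors, per-gene rank
tests, paralogue concordance, cross-cancer common gene sets, the composite
testis-antigen (CTA) score, marker-panel comparisons, the X:autosome
transcript ratio, and locus-neighborhood checks.

Conventions chosen where the source analyses are silent: log expression is
log2(TPM + 1); variance and SD use ddof=1; fold changes add a 0.1 TPM
pseudocount to group means; p-values are raw by default with an optional
Benjamini-Hochberg flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .errors import ValidationError
from .model import AnnotationTable, ExpressionMatrix, SampleTable
from .stats import benjamini_hochberg, mann_whitney_u, mwu_matrix

FC_BORDER_DEFAULT = 1.19
ALPHA_DEFAULT = 0.05
FC_PSEUDOCOUNT_DEFAULT = 0.1


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    fold_change: float
    log2_fc: float
    p_value: float
    direction: str  # up | down | none


@dataclass(frozen=True)
class CTAScoreResult:
    sample_id: str
    cancer_type: str
    score: float
    selected_genes: tuple[str, ...]


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# TMM normalization


def _check_groups(expr: ExpressionMatrix, group_pos, group_neg) -> tuple[list[str], list[str]]:
    group_pos, group_neg = list(group_pos), list(group_neg)
    overlap = set(group_pos) & set(group_neg)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    if not group_pos or not group_neg:
        raise ValidationError("both groups must be non-empty")
    for s in (*group_pos, *group_neg):
        expr.sample_index(s)
    return group_pos, group_neg


def tmm_factors(
    expr: ExpressionMatrix,
    reference: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    coding_genes: set[str] | None = None,
) -> dict[str, float]:
    """Per-sample TMM scaling factors.

    M (log2 expression ratio vs the reference sample, after library-size
    normalization) is trimmed by ``trim_m`` on each side and A (average log
    abundance) by ``trim_a``; the factor is 2 to the precision-weighted
    trimmed mean of M.  Genes at zero in either sample are excluded.
    Factors are rescaled to geometric mean 1.

    ``reference="auto"`` picks the sample whose upper-quartile expression
    (relative to library size) is closest to the cohort mean.
    """
    if expr.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    X = expr.values
    if coding_genes is not None:
        rows = [i for i, g in enumerate(expr.gene_ids) if g in coding_genes]
        if not rows:
            raise ValidationError("no coding genes present in the matrix")
        X = X[rows, :]
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValidationError("a sample has zero total expression")
    P = X / lib  # per-sample proportions

    if reference == "auto":
        uq = np.quantile(P, 0.75, axis=0)
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = expr.sample_index(reference)

    factors = np.ones(expr.n_samples)
    for k in range(expr.n_samples):
        if k == ref:
            continue
        mask = (X[:, k] > 0) & (X[:, ref] > 0)
        if mask.sum() < 2:
            raise ValidationError(
                f"fewer than 2 genes nonzero in both {expr.sample_ids[k]!r} "
                f"and the reference"
            )
        pk, pr = P[mask, k], P[mask, ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # delta-method precision weights on M, computed from library-size-
        # normalized proportions so factors are invariant to uniform
        # per-sample rescaling (TPM columns carry no absolute depth)
        v = (1.0 - pk) / pk + (1.0 - pr) / pr
        if np.max(np.abs(m)) < 1e-6:
            factors[k] = 1.0
            continue
        n = int(mask.sum())
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n - math.floor(n * trim_m)
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n - math.floor(n * trim_a)
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not np.any(keep):
            raise ValidationError("trimming removed every gene; lower the trim fractions")
        w = 1.0 / v[keep]
        factors[k] = 2.0 ** (np.sum(m[keep] * w) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return dict(zip(expr.sample_ids, factors))


def apply_tmm(expr: ExpressionMatrix, factors: dict[str, float]) -> ExpressionMatrix:
    """Return a new matrix with each sample divided by its scaling factor."""
    f = np.array([factors[s] for s in expr.sample_ids])
    return ExpressionMatrix(
        list(expr.gene_ids), list(expr.sample_ids), expr.values / f, normalized=True
    )


# ---------------------------------------------------------------------------
# Differential expression


def differential_expression(
    expr: ExpressionMatrix,
    group_pos,
    group_neg,
    alternative: str = "two_sided",
    fc_border: float = FC_BORDER_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    pseudocount: float = FC_PSEUDOCOUNT_DEFAULT,
    adjust: bool = False,
    gene_ids: list[str] | None = None,
) -> list[DEResult]:
    """Per-gene fold change and rank-test p between two sample groups.

    fold_change = (mean TPM_pos + eps) / (mean TPM_neg + eps).  Direction is
    the composite call: up iff fold_change > fc_border and p < alpha; down
    iff fold_change < 1/fc_border and p < alpha; otherwise none.  Samples of
    intermediate short-H2A status must be excluded by the caller.
    """
    group_pos, group_neg = _check_groups(expr, group_pos, group_neg)
    sub = expr if gene_ids is None else expr.subset_genes(gene_ids)
    A = sub.sample_columns(group_pos)
    B = sub.sample_columns(group_neg)
    mean_pos = A.mean(axis=1)
    mean_neg = B.mean(axis=1)
    fc = (mean_pos + pseudocount) / (mean_neg + pseudocount)
    _, p = mwu_matrix(A, B, alternative=alternative)
    p_for_call = benjamini_hochberg(p) if adjust else p
    results = []
    for g, f, pv, pc in zip(sub.gene_ids, fc, p, p_for_call):
        if pc < alpha and f > fc_border:
            direction = "up"
        elif pc < alpha and f < 1.0 / fc_border:
            direction = "down"
        else:
            direction = "none"
        results.append(DEResult(g, float(f), float(np.log2(f)), float(pv), direction))
    return results


def paralogue_concordance(
    de_a: list[DEResult],
    de_b: list[DEResult],
    fc_border: float = FC_BORDER_DEFAULT,
) -> tuple[float, set[str], set[str]]:
    """Pearson r of paired log2 fold-changes plus common up/down gene sets.

    A gene is commonly up if its fold change exceeds ``fc_border`` in both
    comparisons (significance is not required — the border alone defines the
    common sets), and commonly down if below ``1/fc_border`` in both.
    """
    genes_a = [r.gene_id for r in de_a]
    genes_b = [r.gene_id for r in de_b]
    if set(genes_a) != set(genes_b):
        raise ValidationError("comparisons cover different gene universes")
    by_b = {r.gene_id: r for r in de_b}
    pairs = [(r, by_b[r.gene_id]) for r in de_a]
    xs = np.array([a.log2_fc for a, _ in pairs])
    ys = np.array([b.log2_fc for _, b in pairs])
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValidationError("degenerate fold-change vector (zero variance)")
    r = float(pearsonr(xs, ys).statistic)
    common_up = {
        a.gene_id for a, b in pairs if a.fold_change > fc_border and b.fold_change > fc_border
    }
    common_down = {
        a.gene_id
        for a, b in pairs
        if a.fold_change < 1.0 / fc_border and b.fold_change < 1.0 / fc_border
    }
    return r, common_up, common_down


def cross_cancer_common_genes(
    de_by_cancer: dict[str, list[DEResult]],
    min_types: int | None = None,
    allow_conflict: bool = False,
) -> tuple[set[str], set[str]]:
    """Genes consistently up/down across per-cancer-type comparisons.

    Default policy: a gene is commonly up if called up in at least
    ``min_types`` types (default: half of the analyzed types, rounded up)
    and down in none; symmetric for down.  ``allow_conflict`` drops the
    zero-conflict requirement.
    """
    if len(de_by_cancer) < 2:
        raise ValidationError("need at least 2 cancer types")
    if min_types is None:
        min_types = math.ceil(len(de_by_cancer) / 2)
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    genes: set[str] = set()
    for results in de_by_cancer.values():
        for r in results:
            genes.add(r.gene_id)
            if r.direction == "up":
                up_counts[r.gene_id] = up_counts.get(r.gene_id, 0) + 1
            elif r.direction == "down":
                down_counts[r.gene_id] = down_counts.get(r.gene_id, 0) + 1
    up, down = set(), set()
    for g in genes:
        u, d = up_counts.get(g, 0), down_counts.get(g, 0)
        if u >= min_types and (allow_conflict or d == 0):
            up.add(g)
        if d >= min_types and (allow_conflict or u == 0):
            down.add(g)
    return up, down


# ---------------------------------------------------------------------------
# Composite CTA score


def cta_score(
    expr: ExpressionMatrix,
    samples: SampleTable,
    cta_genes,
    k: int = 40,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
    tumor_only: bool = True,
) -> list[CTAScoreResult]:
    """Per-sample composite score over testis-antigen genes.

    Within each cancer type independently: log-transform TPM, rank CTA genes
    by variance of log expression (ddof=1), keep the top ``k`` with positive
    variance, Z-normalize each kept gene across the type's samples, and sum
    the Z-scores per sample.  Scores therefore average exactly 0 within each
    cancer type.
    """
    cta_genes = [g for g in cta_genes if g in expr._gene_index]
    if not cta_genes:
        raise ValidationError("no CTA gene present in the matrix")
    results: list[CTAScoreResult] = []
    for ct in samples.cancer_type_list():
        ids = samples.samples_of_type(ct, "tumor" if tumor_only else None)
        ids = [s for s in ids if s in expr._sample_index]
        if len(ids) < 2:
            raise ValidationError(f"cancer type {ct!r} has fewer than 2 samples")
        L = np.log(expr.subset_genes(cta_genes).sample_columns(ids) + pseudocount)
        L /= np.log(log_base)
        var = L.var(axis=1, ddof=1)
        order = sorted(
            (i for i in range(len(cta_genes)) if var[i] > 0),
            key=lambda i: (-var[i], cta_genes[i]),
        )
        if not order:
            raise ValidationError(f"cancer type {ct!r}: no CTA gene with positive variance")
        sel = order[: min(k, len(order))]
        selected = tuple(cta_genes[i] for i in sel)
        Z = (L[sel, :] - L[sel, :].mean(axis=1, keepdims=True)) / L[sel, :].std(
            axis=1, ddof=1, keepdims=True
        )
        scores = Z.sum(axis=0)
        results.extend(
            CTAScoreResult(s, ct, float(v), selected) for s, v in zip(ids, scores)
        )
    return results


def compare_scores(
    scores: list[CTAScoreResult],
    group_pos,
    group_neg,
    alternative: str = "x_greater",
) -> dict[str, float]:
    """Per-cancer-type rank-test p comparing scores of two sample groups.

    Identical score multisets in the two groups carry no evidence and
    report p = 1 regardless of the alternative.
    """
    group_pos, group_neg = set(group_pos), set(group_neg)
    if group_pos & group_neg:
        raise ValidationError("groups overlap")
    by_type: dict[str, tuple[list[float], list[float]]] = {}
    for r in scores:
        bucket = by_type.setdefault(r.cancer_type, ([], []))
        if r.sample_id in group_pos:
            bucket[0].append(r.score)
        elif r.sample_id in group_neg:
            bucket[1].append(r.score)
    out: dict[str, float] = {}
    for ct, (xs, ys) in by_type.items():
        if not xs or not ys:
            continue
        if sorted(xs) == sorted(ys):
            out[ct] = 1.0
            continue
        _, p = mann_whitney_u(xs, ys, alternative=alternative)
        out[ct] = p
    if not out:
        raise ValidationError("no cancer type has samples in both groups")
    return out


# ---------------------------------------------------------------------------
# Panels, ratios, locus neighborhoods


def marker_panel_comparison(
    expr: ExpressionMatrix,
    panel,
    group_pos,
    group_neg,
    alternative: str = "two_sided",
    **de_kwargs,
) -> list[DEResult]:
    """Differential expression restricted to a named marker panel."""
    panel = [g for g in panel if g in expr._gene_index]
    if not panel:
        return []
    return differential_expression(
        expr, group_pos, group_neg, alternative=alternative, gene_ids=panel, **de_kwargs
    )


def x_autosome_ratio(
    expr: ExpressionMatrix,
    annotation: AnnotationTable,
    group_pos,
    group_neg,
) -> tuple[dict[str, float], float]:
    """Per-sample chrX / autosome total-TPM ratio and a two-sided group test."""
    group_pos, group_neg = _check_groups(expr, group_pos, group_neg)
    x_rows, a_rows = [], []
    for i, g in enumerate(expr.gene_ids):
        if g not in annotation:
            continue
        chrom = annotation.get(g).chromosome
        if chrom == "chrX":
            x_rows.append(i)
        elif chrom not in ("chrY", "chrM"):
            a_rows.append(i)
    if not x_rows or not a_rows:
        raise ValidationError("need annotated genes on chrX and on autosomes")
    x_sum = expr.values[x_rows, :].sum(axis=0)
    a_sum = expr.values[a_rows, :].sum(axis=0)
    if np.any(a_sum == 0):
        raise ValidationError("a sample has zero autosomal expression")
    ratios = dict(zip(expr.sample_ids, x_sum / a_sum))
    _, p = mann_whitney_u(
        [ratios[s] for s in group_pos],
        [ratios[s] for s in group_neg],
        alternative="two_sided",
    )
    return ratios, float(p)


def locus_neighborhood(
    expr: ExpressionMatrix,
    annotation: AnnotationTable,
    focal_gene: str,
    window_bp: int,
    group_pos,
    group_neg,
    **de_kwargs,
) -> tuple[list[DEResult], str]:
    """Differential expression of a focal gene and its genomic neighbors.

    Neighbors are annotated genes on the same chromosome whose span lies
    within ``window_bp`` of the focal gene's span.  Verdict is
    ``locus_restricted`` iff the focal gene is up and no neighbor is up,
    else ``regional``.
    """
    focal = annotation.get(focal_gene)
    neighbors = []
    for g in annotation:
        if g.gene_id == focal_gene or g.chromosome != focal.chromosome:
            continue
        if g.gene_id not in expr._gene_index:
            continue
        gap = max(focal.start - g.end, g.start - focal.end, 0)
        if gap <= window_bp:
            neighbors.append(g.gene_id)
    if not neighbors:
        raise ValidationError(
            f"no annotated neighbor of {focal_gene!r} within {window_bp} bp; "
            "try a larger window"
        )
    results = differential_expression(
        expr, group_pos, group_neg, gene_ids=[focal_gene, *neighbors], **de_kwargs
    )
    by_id = {r.gene_id: r for r in results}
    focal_up = by_id[focal_gene].direction == "up"
    neighbor_up = any(by_id[g].direction == "up" for g in neighbors)
    verdict = "locus_restricted" if focal_up and not neighbor_up else "regional"
    return results, verdict
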