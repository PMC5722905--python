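"""Validation of predicted regulator->target networks.

Implements the standard evaluation toolkit for network inference: ROC and
precision-recall curves per regulator against an experimentally derived gold
standard, recall within a top fraction of the global edge ranking, per-gene
variability profiles (coefficient of variation; within- vs between-series
standard deviation) of predicted target sets, and a functional-cohesion
enrichment score (sum over annotation categories of -log10 hypergeometric
over-representation p-values).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .containers import ExpressionMatrix, GoldStandard, ValidationError

__all__ = [
    "RocResult",
    "PrResult",
    "EnrichmentResult",
    "roc_auc",
    "pr_curve",
    "coefficient_of_variation",
    "within_between_sd",
    "enrichment_score",
    "recall_at_fraction",
    "evaluate_regulators",
]


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positives: int
    n_universe: int


@dataclass
class PrResult:
    average_precision: float
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    n_positives: int
    n_universe: int


@dataclass
class EnrichmentResult:
    pvalues: pd.Series          # per category, raw hypergeometric upper tail
    score: float                # sum of -log10(p) over represented categories
    adjusted_pvalues: pd.Series | None = None


def _labels_scores(scores: pd.Series | dict, gold: GoldStandard, regulator=None):
    s = pd.Series(scores, dtype=float)
    s = s.loc[[t for t in gold.universe if t in s.index]]
    if len(s) != len(gold.universe):
        missing = sorted(set(gold.universe) - set(s.index))
        raise ValidationError(f"scores missing for universe targets: {missing[:5]}")
    pos = gold.positives_for(regulator) if regulator is not None else gold.pairs()
    if regulator is None:
        # single-regulator standards may be given as {reg: targets}
        if len(gold.positives) == 1:
            (regulator,) = gold.positives
            pos = gold.positives_for(regulator)
        else:
            raise ValidationError("specify the regulator to evaluate")
    labels = np.array([1 if t in pos else 0 for t in s.index])
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValidationError(
            f"regulator {regulator!r}: need at least one positive and one "
            f"negative in the universe (got {n_pos} positives of {len(labels)})"
        )
    return labels, s.to_numpy(), regulator


def roc_auc(scores, gold: GoldStandard, regulator=None) -> RocResult:
    """ROC curve and AUC of per-target scores against gold positives.

    The AUC equals the Mann-Whitney statistic: the probability that a random
    positive target outscores a random negative one, ties counting 1/2 — so
    an uninformative all-equal scoring gives exactly 0.5.
    """
    labels, vals, _ = _labels_scores(scores, gold, regulator)
    auc = float(roc_auc_score(labels, vals))
    fpr, tpr, thr = roc_curve(labels, vals)
    return RocResult(
        auc=auc, fpr=fpr, tpr=tpr, thresholds=thr,
        n_positives=int(labels.sum()), n_universe=len(labels),
    )


def pr_curve(scores, gold: GoldStandard, regulator=None) -> PrResult:
    """Precision-recall curve and step-integrated average precision."""
    labels, vals, _ = _labels_scores(scores, gold, regulator)
    ap = float(average_precision_score(labels, vals))
    prec, rec, thr = precision_recall_curve(labels, vals)
    return PrResult(
        average_precision=ap, precision=prec, recall=rec, thresholds=thr,
        n_positives=int(labels.sum()), n_universe=len(labels),
    )


def coefficient_of_variation(expr: ExpressionMatrix, gene_set=None) -> pd.Series:
    """Per-gene CV = sample SD / mean across all samples (ddof=1).

    Genes with zero mean are excluded with a warning rather than returning
    an infinite CV.
    """
    genes = list(gene_set) if gene_set is not None else list(expr.genes)
    vals = expr.values.loc[genes]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-mean gene(s) from CV: "
            f"{list(mean.index[zero])[:5]}",
            stacklevel=2,
        )
    return (sd / mean)[~zero]


def within_between_sd(expr: ExpressionMatrix, gene_set=None) -> pd.DataFrame:
    """Decompose per-gene variability into within- and between-series parts.

    within = mean over series of the SD across that series' samples;
    between = SD of the per-series means.  Shifting one whole series by a
    constant moves only the between component.
    """
    series_ids = expr.series_ids()
    if len(series_ids) < 2:
        raise ValidationError("need at least 2 series for within/between SD")
    genes = list(gene_set) if gene_set is not None else list(expr.genes)
    vals = expr.values.loc[genes]
    series_of = expr.design.loc[vals.columns, "series_id"]
    per_series_sd = vals.T.groupby(series_of.to_numpy()).std(ddof=1)
    if per_series_sd.isna().any().any():
        raise ValidationError("every series needs at least 2 samples")
    per_series_mean = vals.T.groupby(series_of.to_numpy()).mean()
    return pd.DataFrame(
        {
            "within_sd": per_series_sd.mean(axis=0),
            "between_sd": per_series_mean.std(axis=0, ddof=1),
        }
    )


def enrichment_score(
    target_set,
    annotation: dict,
    universe,
    *,
    min_category_size: int = 1,
    adjust: bool = False,
    significance_filter: float | None = None,
) -> EnrichmentResult:
    """Functional-cohesion score of a predicted target set.

    For every annotation category represented in the target set, the
    hypergeometric upper-tail p-value of the overlap between the target set
    and the category, drawn from ``universe``; the enrichment score is the
    sum of -log10(p) over those categories.  A category whose overlap is no
    better than chance contributes ~0.

    ``annotation`` maps gene -> iterable of category labels.  With
    ``adjust=True`` Benjamini-Hochberg adjusted p-values are also reported
    (the score still sums the raw p-values).  ``significance_filter`` keeps
    only categories with p below the cutoff in the score (non-default
    variant).
    """
    universe = list(universe)
    uni = set(universe)
    targets = [t for t in target_set if t in uni]
    stray = set(target_set) - uni
    if stray:
        raise ValidationError(f"target genes outside universe: {sorted(stray)[:5]}")
    if not targets:
        warnings.warn("empty target set: enrichment score 0", stacklevel=2)
        return EnrichmentResult(pvalues=pd.Series(dtype=float), score=0.0)
    cat_members: dict = {}
    for g in universe:
        for c in annotation.get(g, ()):
            cat_members.setdefault(c, set()).add(g)
    tset = set(targets)
    pvals = {}
    for cat, members in sorted(cat_members.items(), key=lambda kv: str(kv[0])):
        k = len(tset & members)
        if k == 0 or len(members) < min_category_size:
            continue
        # P(overlap >= k) drawing |targets| genes from |universe| with |members| marked
        pvals[cat] = float(hypergeom.sf(k - 1, len(uni), len(members), len(tset)))
    p = pd.Series(pvals, dtype=float)
    scored = p if significance_filter is None else p[p < significance_filter]
    score = float((-np.log10(scored)).sum()) if len(scored) else 0.0
    adjusted = None
    if adjust and len(p):
        order = np.argsort(p.to_numpy())
        m = len(p)
        adj = np.empty(m)
        ranked = p.to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = pd.Series(np.clip(adj, 0, 1), index=p.index)
    return EnrichmentResult(pvalues=p, score=score, adjusted_pvalues=adjusted)


def recall_at_fraction(ranked_edges: pd.DataFrame, gold: GoldStandard, fraction: float) -> float:
    """Fraction of gold pairs found in the top ``ceil(fraction * n)`` edges."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    pairs = gold.pairs()
    if not pairs:
        raise ValidationError("gold standard has no positive pairs")
    n_top = math.ceil(fraction * len(ranked_edges))
    top = ranked_edges.head(n_top)
    found = set(zip(top["regulator"], top["target"])) & pairs
    return len(found) / len(pairs)


def evaluate_regulators(scores: pd.DataFrame, gold: GoldStandard) -> pd.DataFrame:
    """Per-regulator AUC and average precision from an edge-score matrix.

    ``scores`` is regulators x targets (self-edges NaN).  For each gold
    regulator present in the matrix, its target scores are evaluated against
    its positives over the gold universe (minus the regulator itself).
    """
    rows = []
    for reg in gold.regulators:
        if reg not in scores.index:
            continue
        s = scores.loc[reg].dropna()
        uni = [t for t in gold.universe if t != reg and t in s.index]
        sub = GoldStandard({reg: gold.positives_for(reg) & set(uni)}, universe=uni)
        roc = roc_auc(s, sub, regulator=reg)
        pr = pr_curve(s, sub, regulator=reg)
        rows.append(
            {
                "regulator": reg,
                "auc": roc.auc,
                "average_precision": pr.average_precision,
                "n_positives": roc.n_positives,
                "n_universe": roc.n_universe,
            }
        )
    if not rows:
        raise ValidationError("no gold-standard regulator present in score matrix")
    return pd.DataFrame(rows).set_index("regulator")
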