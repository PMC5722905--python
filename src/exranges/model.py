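"""Model/Results interface tying the transform and inference stages together.

:class:`GRNModel` is constructed from an expression matrix, a sample design
and a regulator list, with a ``feature`` choice ("expression", "ranges" or
"exranges"); ``fit()`` computes the feature matrix, fits one regression
forest per target and returns a :class:`GRNResults` holding the
regulators x targets edge-score matrix, with evaluation, ranking, summary
and plotting attached.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GoldStandard, StepMatrix, ValidationError
from .evaluation import evaluate_regulators, recall_at_fraction, roc_auc
from .inference import EdgeScoreMatrix, InferenceConfig, infer_network, rank_edges
from .transform import TransformConfig, exranges, ranges

FEATURES = ("expression", "ranges", "exranges")


class GRNModel:
    """Regulator->target network model over time-series expression data.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples values with (series, time) design.
    regulators : sequence of gene ids
        Candidate regulators (must be rows of the matrix).
    feature : {"exranges", "ranges", "expression"}
        Input representation for the per-target forests.  "expression" uses
        the raw sample columns; "ranges"/"exranges" first run the
        rate-significance transform and use step columns.
    transform_config, inference_config : optional
        Stage settings; seeds default from ``seed``.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        regulators,
        *,
        feature: str = "exranges",
        targets=None,
        transform_config: TransformConfig | None = None,
        inference_config: InferenceConfig | None = None,
        seed: int = 0,
    ):
        if feature not in FEATURES:
            raise ValueError(f"feature must be one of {FEATURES}, got {feature!r}")
        self.expression = expression
        self.regulators = list(regulators)
        missing = [r for r in self.regulators if r not in expression.genes]
        if missing:
            raise ValidationError(f"regulators absent from expression matrix: {missing}")
        self.feature = feature
        self.targets = list(targets) if targets is not None else list(expression.genes)
        self.transform_config = transform_config or TransformConfig(seed=seed)
        self.inference_config = inference_config or InferenceConfig(seed=seed)

    @classmethod
    def from_frames(cls, values: pd.DataFrame, design: pd.DataFrame, regulators, **kw):
        """Build from raw DataFrames (genes x samples values, sample design)."""
        return cls(ExpressionMatrix(values, design), regulators, **kw)

    @classmethod
    def from_files(cls, expression_path, design_path, regulators_path, **kw):
        from .io import read_expression, read_gene_list

        expr = read_expression(expression_path, design_path)
        return cls(expr, read_gene_list(regulators_path), **kw)

    # ------------------------------------------------------------------
    def feature_matrix(self) -> pd.DataFrame:
        """The genes x observations table the forests are fitted on."""
        if self.feature == "expression":
            return self.expression.values
        r = ranges(self.expression, self.transform_config)
        if self.feature == "ranges":
            return r.values
        return exranges(self.expression, r).values

    def fit(self) -> "GRNResults":
        features = self.feature_matrix()
        scores = infer_network(
            features, self.regulators, self.targets, self.inference_config
        )
        return GRNResults(self, scores, features)


class GRNResults:
    """Fitted edge scores plus evaluation and reporting utilities."""

    def __init__(self, model: GRNModel, edge_scores: EdgeScoreMatrix,
                 features: pd.DataFrame):
        self.model = model
        self.edge_scores = edge_scores
        self.features = features

    @property
    def scores(self) -> pd.DataFrame:
        return self.edge_scores.scores

    def rank_edges(self, top_fraction=None, top_k=None) -> pd.DataFrame:
        return rank_edges(self.edge_scores, top_fraction=top_fraction, top_k=top_k)

    def top_targets(self, regulator, k: int = 1000) -> list:
        """The regulator's k best-scored targets (ties broken lexically)."""
        s = self.scores.loc[regulator].dropna()
        order = sorted(s.index, key=lambda t: (-s[t], str(t)))
        return order[:k]

    def evaluate(self, gold: GoldStandard) -> pd.DataFrame:
        """Per-regulator ROC AUC and average precision against a gold standard."""
        return evaluate_regulators(self.scores, gold)

    def recall_at_fraction(self, gold: GoldStandard, fraction: float = 0.1) -> float:
        return recall_at_fraction(self.rank_edges(), gold, fraction)

    def summary(self, gold: GoldStandard | None = None, top: int = 10) -> str:
        """Plain-text report: model setup, score distribution, top edges."""
        m = self.model
        n_obs = self.features.shape[1]
        lines = [
            "Gene regulatory network inference",
            "=" * 48,
            f"feature:            {m.feature}",
            f"genes:              {len(m.expression.genes)}",
            f"regulators:         {len(m.regulators)}",
            f"targets:            {len(m.targets)}",
            f"observations:       {n_obs}",
            f"trees per target:   {m.inference_config.n_trees}",
            f"importance:         {m.inference_config.importance}",
            f"seed:               {m.inference_config.seed}",
            "",
            f"top {top} edges (regulator -> target, score):",
        ]
        for _, row in self.rank_edges(top_k=top).iterrows():
            lines.append(f"  {row['regulator']} -> {row['target']}: {row['score']:.4f}")
        if gold is not None:
            ev = self.evaluate(gold)
            lines += [
                "",
                f"mean per-regulator ROC AUC:  {ev['auc'].mean():.4f}",
                f"mean average precision:      {ev['average_precision'].mean():.4f}",
            ]
        return "\n".join(lines)

    def plot_roc(self, gold: GoldStandard, regulators=None, ax=None):
        """ROC curves per regulator (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        regulators = regulators or [r for r in gold.regulators if r in self.scores.index]
        for reg in regulators:
            s = self.scores.loc[reg].dropna()
            uni = [t for t in gold.universe if t != reg and t in s.index]
            sub = GoldStandard({reg: gold.positives_for(reg) & set(uni)}, universe=uni)
            res = roc_auc(s, sub, regulator=reg)
            ax.plot(res.fpr, res.tpr, label=f"{reg} (AUC={res.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=8)
        return ax
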