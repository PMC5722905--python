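"""Rate-change significance features from multi-series time courses.

Pipeline, per gene:

1. **Slopes** — finite-difference rates of change between consecutive samples
   of each series; a cyclic series additionally gets a wrap-around step from
   its last sample back to its first.
2. **Background** — the gene's own slopes, pooled across all series, optionally
   re-drawn by bootstrap (sampling with replacement, default 10,000 draws).
3. **Tail p-value** — the empirical probability, under the background, of a
   slope at least as extreme (smaller tail of the ECDF), with add-one
   smoothing so p is never 0.
4. **RANGES** — ``-log10(p)`` signed by the direction of the change: a large
   positive value marks a significant rise, a large negative value a
   significant fall, and a flat step is exactly 0.
5. **ExRANGES** — RANGES multiplied by the expression level at the step's
   starting sample, so expression preceding a significant change is
   emphasized.

Because each gene is ranked against its *own* slope background, RANGES is
invariant to per-gene rescaling of expression and to a global rescaling of
the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, StepMatrix, ValidationError, step_label

__all__ = [
    "TransformConfig",
    "BackgroundDistribution",
    "compute_slopes",
    "build_background",
    "tail_pvalue",
    "ranges",
    "exranges",
    "ranges_pipeline",
]


@dataclass
class TransformConfig:
    """Settings for the slope-significance transform.

    Parameters
    ----------
    bootstrap : bool
        When True (default) the per-gene background is a bootstrap resample of
        the pooled slopes; when False the pooled slopes themselves are the
        reference multiset ("direct" mode, exactly reproducible by counting).
    bootstrap_reps : int
        Bootstrap draws per gene (default 10,000).
    seed : int
        Root seed; every gene gets an independent substream.
    tail : {"smaller", "literal"}
        "smaller" (default): p is the smaller empirical tail with add-one
        smoothing, so extreme slopes of either sign are significant.
        "literal": the one-sided ECDF value folded onto [0.5, 1], kept only
        for comparison — it caps -log10(p) at ~0.301.
    cyclic : bool or None
        Override the design's per-series cyclic flags (None: use the design).
    """

    bootstrap: bool = True
    bootstrap_reps: int = 10_000
    seed: int = 0
    tail: str = "smaller"
    cyclic: bool | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.tail not in ("smaller", "literal"):
            raise ValueError(f"unknown tail mode {self.tail!r}")


@dataclass
class BackgroundDistribution:
    """Per-gene slope reference multisets, stored sorted for tail counting."""

    genes: pd.Index
    pooled: np.ndarray          # genes x n_steps, sorted per row
    bootstrap_sample: np.ndarray | None = None  # genes x B, sorted per row

    @property
    def reference(self) -> np.ndarray:
        """The multiset tail p-values are counted against."""
        return self.pooled if self.bootstrap_sample is None else self.bootstrap_sample

    def for_gene(self, gene) -> np.ndarray:
        i = self.genes.get_loc(gene)
        return self.reference[i]


def _series_cyclic(expr: ExpressionMatrix, cfg: TransformConfig, series_id) -> bool:
    if cfg.cyclic is not None:
        return cfg.cyclic
    return expr.is_cyclic(series_id)


def compute_slopes(expr: ExpressionMatrix, cfg: TransformConfig | None = None) -> StepMatrix:
    """Finite-difference slopes between consecutive samples of each series.

    The slope of the step from time t to t+1 is attached to the sample at
    time t.  For a cyclic series the wrap step from the last sample back to
    the first uses the series' median within-series time gap as its (positive,
    forward) interval.  Steps never pair samples from different series.
    """
    cfg = cfg or TransformConfig()
    rows = []
    pair_idx: list[tuple[int, int]] = []  # (to, from) sample positions per step
    sample_pos = {s: i for i, s in enumerate(expr.samples)}
    for series_id in expr.series_ids():
        grp = expr.series_samples(series_id)
        if len(grp) < 2:
            raise ValidationError(
                f"series {series_id!r} has {len(grp)} sample(s); at least 2 are "
                "required to compute slopes"
            )
        times = grp["time"].to_numpy()
        ids = grp.index.to_list()
        for i in range(len(grp) - 1):
            rows.append(
                {
                    "series_id": series_id,
                    "from_time": times[i],
                    "to_time": times[i + 1],
                    "from_sample": ids[i],
                    "dt": times[i + 1] - times[i],
                }
            )
            pair_idx.append((sample_pos[ids[i + 1]], sample_pos[ids[i]]))
        if _series_cyclic(expr, cfg, series_id):
            dt_wrap = float(np.median(np.diff(times)))
            rows.append(
                {
                    "series_id": series_id,
                    "from_time": times[-1],
                    "to_time": times[-1] + dt_wrap,
                    "from_sample": ids[-1],
                    "dt": dt_wrap,
                }
            )
            pair_idx.append((sample_pos[ids[0]], sample_pos[ids[-1]]))
    steps = pd.DataFrame(rows)
    steps.index = pd.Index(
        [step_label(r["series_id"], r["from_time"]) for r in rows], name="step"
    )
    x = expr.values.to_numpy(dtype=float)
    to_i = np.array([p[0] for p in pair_idx])
    from_i = np.array([p[1] for p in pair_idx])
    dt = steps["dt"].to_numpy()
    slopes = (x[:, to_i] - x[:, from_i]) / dt
    values = pd.DataFrame(slopes, index=expr.genes, columns=steps.index)
    return StepMatrix(values=values, steps=steps.drop(columns="dt"))


def build_background(
    slopes: StepMatrix, cfg: TransformConfig | None = None
) -> BackgroundDistribution:
    """Pool each gene's slopes across series; optionally bootstrap them.

    Bootstrap draws are i.i.d. with replacement from the pooled multiset,
    one independent seeded substream per gene, so results are reproducible
    and independent of gene evaluation order.
    """
    cfg = cfg or TransformConfig()
    pooled = slopes.values.to_numpy(dtype=float)
    if pooled.shape[1] == 0:
        raise ValidationError("empty slope set: no steps to pool")
    if pooled.shape[1] < 2:
        raise ValidationError("need at least 2 pooled slopes per gene")
    pooled_sorted = np.sort(pooled, axis=1)
    sample = None
    if cfg.bootstrap:
        n_genes, n_steps = pooled.shape
        children = np.random.SeedSequence(cfg.seed).spawn(n_genes)
        sample = np.empty((n_genes, cfg.bootstrap_reps))
        for g in range(n_genes):
            rng = np.random.default_rng(children[g])
            idx = rng.integers(0, n_steps, size=cfg.bootstrap_reps)
            sample[g] = pooled[g, idx]
        sample.sort(axis=1)
    return BackgroundDistribution(
        genes=slopes.genes, pooled=pooled_sorted, bootstrap_sample=sample
    )


def _tail_pvalues_sorted(slopes: np.ndarray, ref_sorted: np.ndarray, tail: str) -> np.ndarray:
    """Tail p-values of each slope in one gene's row against its sorted reference."""
    b = ref_sorted.shape[0]
    n_le = np.searchsorted(ref_sorted, slopes, side="right")
    n_ge = b - np.searchsorted(ref_sorted, slopes, side="left")
    if tail == "smaller":
        return (np.minimum(n_le, n_ge) + 1.0) / (b + 1.0)
    # literal one-sided ECDF folded onto the upper half
    p = n_le / b
    return np.where(p < 0.5, 1.0 - p, p)


def tail_pvalue(slope, background, tail: str = "smaller") -> np.ndarray | float:
    """Empirical tail p-value of ``slope`` against a slope background.

    With ``tail="smaller"`` (default), p is the smaller of the two empirical
    tails with add-one smoothing::

        p = (min(#{b <= slope}, #{b >= slope}) + 1) / (B + 1)

    which is always in (0, 1], so ``-log10(p)`` stays finite.

    ``background`` may be a 1-D array-like of slopes, or a
    :class:`BackgroundDistribution` together with gene-row slopes.
    """
    ref = np.sort(np.asarray(background, dtype=float).ravel())
    if ref.size == 0:
        raise ValidationError("background is empty")
    s = np.asarray(slope, dtype=float)
    p = _tail_pvalues_sorted(np.atleast_1d(s), ref, tail)
    return float(p[0]) if s.ndim == 0 else p


def ranges(expr: ExpressionMatrix, cfg: TransformConfig | None = None) -> StepMatrix:
    """Signed -log10 tail-significance of every expression rate change.

    ``R = -log10(p) * sign(slope)`` per gene and step, with the p-value taken
    against the gene's own pooled (or bootstrapped) slope background.  Flat
    steps give exactly 0.
    """
    cfg = cfg or TransformConfig()
    slopes = compute_slopes(expr, cfg)
    bg = build_background(slopes, cfg)
    s = slopes.values.to_numpy(dtype=float)
    ref = bg.reference
    p = np.empty_like(s)
    for g in range(s.shape[0]):
        p[g] = _tail_pvalues_sorted(s[g], ref[g], cfg.tail)
    r = -np.log10(p) * np.sign(s)
    values = pd.DataFrame(r, index=slopes.genes, columns=slopes.values.columns)
    return StepMatrix(values=values, steps=slopes.steps)


def exranges(expr: ExpressionMatrix, ranges_matrix: StepMatrix) -> StepMatrix:
    """Expression-weighted rate significance: ``E = R * X`` at the from-sample.

    Each step's RANGES value is multiplied by the gene's expression level at
    the sample the step starts from, so the level *preceding* a significant
    change carries the signal.  Columns are steps: the last sample of a
    non-cyclic series has no outgoing step and contributes no column.
    """
    steps = ranges_matrix.steps
    missing = [s for s in steps["from_sample"] if s not in expr.samples]
    if missing:
        raise ValidationError(f"step from-samples absent from expression matrix: {missing}")
    if not ranges_matrix.genes.equals(expr.genes):
        raise ValidationError("gene sets of expression and RANGES matrices differ")
    x = expr.values.loc[:, steps["from_sample"]].to_numpy(dtype=float)
    e = ranges_matrix.values.to_numpy(dtype=float) * x
    values = pd.DataFrame(e, index=expr.genes, columns=ranges_matrix.values.columns)
    return StepMatrix(values=values, steps=steps)


def ranges_pipeline(
    expr: ExpressionMatrix, cfg: TransformConfig | None = None
) -> tuple[StepMatrix, StepMatrix]:
    """Convenience: compute (RANGES, ExRANGES) in one call."""
    r = ranges(expr, cfg)
    return r, exranges(expr, r)
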